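# Synthetic -10 box frequency matrix (ECF11-like toy, consensus TCTGAT).
# Stand-in for a group-specific promoter PSSM; for tests and simulations.
#type=freqs
A	0.11	0.10	0.11	0.10	0.70	0.09
C	0.08	0.69	0.14	0.07	0.10	0.12
G	0.09	0.08	0.08	0.75	0.12	0.08
T	0.72	0.13	0.67	0.08	0.08	0.71
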