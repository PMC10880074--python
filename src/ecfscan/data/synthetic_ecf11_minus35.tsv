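# Synthetic -35 box frequency matrix (ECF11-like toy, consensus GGTACTA).
# Stand-in for a group-specific promoter PSSM; for tests and simulations.
#type=freqs
A	0.12	0.09	0.13	0.72	0.11	0.09	0.70
C	0.08	0.10	0.08	0.12	0.68	0.07	0.12
G	0.71	0.74	0.10	0.07	0.08	0.11	0.10
T	0.09	0.07	0.69	0.09	0.13	0.73	0.08
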