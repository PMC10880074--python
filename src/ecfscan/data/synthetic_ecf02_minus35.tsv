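# Synthetic -35 box frequency matrix (ECF02-like toy, consensus GGAACTT).
# Stand-in for a group-specific promoter PSSM; for tests and simulations.
#type=freqs
A	0.12	0.10	0.68	0.72	0.11	0.10	0.10
C	0.10	0.07	0.08	0.11	0.66	0.07	0.13
G	0.70	0.75	0.10	0.08	0.08	0.09	0.08
T	0.08	0.08	0.14	0.09	0.15	0.74	0.69
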