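# Synthetic -10 box frequency matrix (ECF02-like toy, consensus GTCAAA).
# Stand-in for a group-specific promoter PSSM; for tests and simulations.
#type=freqs
A	0.11	0.08	0.14	0.76	0.71	0.69
C	0.09	0.12	0.67	0.07	0.12	0.11
G	0.73	0.10	0.08	0.09	0.10	0.08
T	0.07	0.70	0.11	0.08	0.07	0.12
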