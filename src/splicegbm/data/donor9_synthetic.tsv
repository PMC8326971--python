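# Synthetic default donor-site frequency matrix (9 nt, Ex-3..Int+6),
# built from the canonical 5'ss consensus MAG|GTRAGT; not estimated from any
# genome.
pos	A	C	G	T
-3	0.33	0.37	0.18	0.12
-2	0.60	0.13	0.12	0.15
-1	0.09	0.04	0.79	0.08
+1	0.01	0.01	0.97	0.01
+2	0.01	0.01	0.01	0.97
+3	0.59	0.03	0.34	0.04
+4	0.71	0.08	0.11	0.10
+5	0.07	0.06	0.82	0.05
+6	0.16	0.17	0.19	0.48
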