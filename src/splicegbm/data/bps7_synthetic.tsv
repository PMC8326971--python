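# Synthetic default branch-point frequency matrix: 7-mer centred on the
# branch adenosine (positions -3..+3 relative to the branch A), built from the
# yUnAy-like human branch-point consensus; not estimated from any genome.
pos	A	C	G	T
-3	0.12	0.36	0.12	0.40
-2	0.09	0.20	0.09	0.62
-1	0.30	0.22	0.20	0.28
0	0.85	0.05	0.05	0.05
+1	0.10	0.41	0.10	0.39
+2	0.24	0.27	0.21	0.28
+3	0.23	0.28	0.20	0.29
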