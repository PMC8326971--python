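# Synthetic default acceptor-site frequency matrix (15 nt, Int-14..Ex+1).
# Built from the canonical 3'ss consensus composition (pyrimidine-rich tract,
# C-biased Int-3, invariant AG at Int-2/Int-1, G-biased Ex+1); not estimated
# from any genome. Re-estimate from an annotation with FrequencyMatrix.from_windows.
pos	A	C	G	T
-14	0.10	0.31	0.08	0.51
-13	0.09	0.32	0.07	0.52
-12	0.08	0.33	0.08	0.51
-11	0.09	0.34	0.07	0.50
-10	0.08	0.35	0.07	0.50
-9	0.08	0.36	0.07	0.49
-8	0.09	0.35	0.06	0.50
-7	0.08	0.37	0.06	0.49
-6	0.07	0.38	0.06	0.49
-5	0.07	0.39	0.06	0.48
-4	0.24	0.28	0.21	0.27
-3	0.04	0.72	0.01	0.23
-2	0.97	0.01	0.01	0.01
-1	0.01	0.01	0.97	0.01
+1	0.25	0.14	0.51	0.10
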