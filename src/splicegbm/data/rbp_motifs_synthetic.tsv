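# Synthetic stand-in motif table for intronic RNA-binding-protein binding
# sites (column 1: motif, column 2: protein family it emulates). Not derived
# from any motif database; supply your own TSV for real analyses.
motif	protein
TTTT	U2AF2-like
TTCTT	U2AF2-like
CTCTCT	PTBP1-like
TCCTC	PTBP1-like
GGGG	HNRNPF-like
TTAGG	HNRNPA1-like
GTAGT	HNRNPA1-like
CACAC	PCBP-like
TGCATG	RBFOX-like
ACTAAC	SF1-like
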