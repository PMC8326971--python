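# Methods

## Problem and scope

`splicegbm` classifies single-nucleotide variants at intronic positions
Int-50..Int-3 upstream of the 3' splice sites of internal coding exons as
splicing-pathogenic or neutral. Int-k counts upstream from the intron's last
base: Int-1 is the G of the canonical AG, Int-2 the A. Variants at
Int-1/Int-2 are mappable (the mapper reports them with an out-of-scope flag)
but never enter datasets or predictions: the canonical-AG problem is
trivial and is deliberately outside the model. First and last exons are
excluded per transcript because they have no upstream acceptor or are not
followed by an intron. Introns shorter than 50 nt yield no acceptor window
and are skipped with a log message — the feature definitions assume a fixed
50-mer, and truncated windows would silently change feature semantics.

Coordinates: GTF and VCF inputs keep their native 1-based conventions;
internal arithmetic is 0-based on the window string, where index `50 − k`
holds Int-k. All window sequences are reported in transcript-sense
orientation, so a '−'-strand gene and its sense-equivalent '+'-strand
construction produce identical features (tested as an invariant).

## Features

Reference and mutated windows are both featurized and deltas
(alt − ref) are emitted, because the known top discriminator — creation of a
cryptic AG — is inherently an allele contrast. The families:

- **AG gain/loss.** Set comparison of AG start positions fully inside
  Int-50..Int-3 between the two windows; the terminal AG never participates.
- **Shapiro–Senapathy percentile.** Window Int-14..Ex+1 (15 nt) for the
  acceptor and Ex-3..Int+6 (9 nt) for the flanking donor — the classical
  definitions; the cited score does not fix a window, so these are package
  choices, configurable through `FrequencyMatrix` inputs. The score is
  monotone in per-position base frequency by construction.
- **Weight-matrix log-odds acceptor strength** over Int-20..Ex+3 (23 nt),
  standing in the slot a maximum-entropy acceptor scorer occupies in the
  feature family. It is pluggable: `train_wmm` fits signal/background
  frequency tables with pseudocount smoothing from any collection of
  23-mers, and a serialized `splicegbm-wmm-v1` JSON model can be swapped in.
  The default model derives its signal from the bundled acceptor matrix
  plus a generic pyrimidine-tract composition, against a uniform background.
- **Branch point.** Best 7-mer centred on a candidate branch A scanning
  Int-44..Int-15, scored by summed log₂ frequency under a branch-point
  matrix; ties break toward the 3' splice site (the more proximal candidate
  is used preferentially in lariat formation). Windows too short to fit the
  motif return an explicit none-result.
- **PPT.** C/T count over Int-25..Int-3, the canonical tract span;
  configurable because the underlying choice is not standardised.
- **Context.** One-hot Int-3 base for each allele, one-hot Ex+1, exon
  length, Int-k.
- **RBP motifs.** Exact-match occurrences (4–10-mers) overlapping the
  variant, compared between alleles as (motif, start) sets. The bundled
  motif table is synthetic (labelled so in the file) and exists to keep the
  feature exercised; supply a real table for real analyses.

The full vector is 34 columns in a fixed, documented order
(`features.feature_names()`); the classifier refuses any vector whose
schema hash differs.

### Bundled matrices

The acceptor/donor/branch-point frequency matrices shipped under
`splicegbm/data/` are synthetic defaults built from the canonical consensus
composition of each element (pyrimidine-rich tract, C-biased Int-3,
invariant AG, MAG|GTRAGT donor, yUnAy-like branch point). They are not
estimates from any genome — the authoritative parameter tables are external
artifacts — and every entry point accepts replacement matrices;
`FrequencyMatrix.from_windows` re-estimates them from any annotation's
acceptor windows in one call.

## Datasets and splits

Dataset rows are (variant, transcript) pairs: a variant inside windows of
several transcripts contributes one row per pair, matching how predictions
are consumed downstream. The genomic part of the key (chrom:pos:ref:alt) is
the atomic unit of splitting — every transcript row of one SNV lands on the
same side of any train/test split and in the same CV fold — so an identical
variant can never appear in both train and test. Any overlap raises
`CircularityError`; this guard is unconditional.

The common-variant filter keeps `0.01 ≤ MAF < 0.50` (half-open); `hi=0.99`
is supported to reproduce the wider selection that admits variants whose
reference base is the minor allele. Pathogenic records bypass the filter
(clinical assertions are not frequency-based). `balance_sample` keeps all
pathogenic records and draws an equal-size uniform sample of commons without
replacement, deterministically per seed.

Folds are stratified by label over unique genomic SNVs (per-class fold
sizes differ by at most one). Stratification is not strictly implied by
"5-fold CV" but is standard practice on balanced data and stabilises
per-fold metrics.

## Classifier

LightGBM binary objective. Defaults: 200 trees, 31 leaves, learning rate
0.1, min_child_samples 20, feature_fraction 0.9, no bagging, no
regularisation — ordinary mid-size-tabular settings. Determinism matters
more here than raw speed, so `deterministic=true`, `force_row_wise=true`,
single thread, and rows sorted by key before fitting; identical
(data, config, seed) triples give bit-identical predictions regardless of
input row order. Hyperparameter search is randomized sampling from a
documented space (`model.SEARCH_SPACE`: num_leaves 8–64, learning rate
0.02–0.3 log-uniform, min_child_samples 5–40, feature/bagging fractions
0.6–1.0, 100–400 trees, L1/L2 1e-8–1 log-uniform), maximizing mean CV AUROC,
deterministic per seed. Feature importances default to total gain — split
counts understate low-cardinality features such as the binary AG-gain flag,
which one split can exhaust — with split counts available via a flag. Ties
rank lexicographically.

The decision threshold is 0.5 and p = 0.5 exactly is called
splicing-affecting (threshold inclusive).

## Evaluation

The seven guideline measures are computed from the confusion matrix with
the standard formulas. Zero-denominator cases return an explicit `None`
("undefined") rather than NaN and are excluded from fold averages, with the
exclusion visible to the caller. Reports round to 3 decimals, half-even,
matching the precision of published benchmark tables. ROC uses the
unique-score threshold sweep with trapezoidal area (equal to the
Mann–Whitney U statistic over score pairs, which the tests verify by brute
force); PR uses right-continuous step integration (average precision) to
avoid the optimistic bias of trapezoidal PR areas. Fold curves are averaged
vertically on a fixed 101-point grid of the x axis with linear
interpolation within folds; the band is the unbiased across-fold standard
deviation. Plotting (`evaluation.plot_curves`) is optional and imports
matplotlib lazily.

## Synthetic cohort

The generator is the package's study-conditions definition, not a
convenience fixture. Each simulated gene (default 40 genes, 5 exons,
exons 90–180 nt, introns 80–220 nt, strands 50/50) carries the full
acceptor architecture in every internal intron: GT donor, one planted
branch-point heptamer (the bundled matrix's consensus, branch A in
Int-35..Int-20), ≥70 % pyrimidine Int-25..Int-3 tract, pyrimidine Int-3,
terminal AG — and no other AG inside Int-50..Int-3, so cryptic-acceptor
creation is fully controlled.

Pathogenic variants (default 400) draw from four effect classes — AG
creation 35 %, PPT purine substitution 25 %, branch-A destruction 20 %,
Int-3 pyrimidine→purine 20 % — mirroring the feature families the model is
expected to rank highly, so importance-recovery tests are meaningful.
Common variants (default 400) are deep substitutions (Int-50..Int-26) or
PPT pyrimidine↔pyrimidine swaps constrained to avoid the branch heptamer
and any AG change; their MAFs are Uniform[0.01, 0.50) and exist only to
exercise the frequency filter.

What passing tests on this cohort do and do not show: the planted lesions
are separable by construction (each pathogenic class leaves a clean
signature in at least one feature), so near-perfect CV performance
demonstrates that mapping, featurization, training and evaluation are wired
correctly end to end — not that comparable accuracy would be reached on
clinical variants, whose effects are weaker, confounded and partially
mislabelled. The label-shuffle control (mean CV AUROC ≈ 0.5) shows the
pipeline cannot manufacture signal from noise.

## Problem sizes and numerical choices

The standard cohort is 40 genes / 400+400 variants; the test suite uses a
10-gene 80+80 cohort for unit-level checks and the full cohort for
end-to-end claims. These sizes give stable statistics (null-control mean
over 20 shuffle seeds stays within [0.43, 0.57]) while a full suite run
remains interactive. Pseudocounts default to 0.5 (Jeffreys-style smoothing)
in all frequency estimation. Frequency-matrix rows must sum to 1 within
1e-9. Undefined metrics are `None` end to end; the sentinel −1 marks "no
scorable branch point" in feature vectors, paired with a 0.0 score so the
two columns are jointly interpretable.

## Known limitations

- Only SNVs; indels are rejected at parse time.
- Acceptor-side only: donor-proximal intronic variants (Int+ positions) are
  out of scope, as are exonic variants.
- The bundled matrices and motif table are synthetic consensus stand-ins;
  quantitative scores on real genomes require user-supplied parameters or
  re-estimation from a real annotation.
- No liftover: the tool trusts that FASTA and GTF refer to the same
  assembly.
- Training-time deduplication across source databases is the caller's
  responsibility; the package deduplicates only exact variant keys.
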