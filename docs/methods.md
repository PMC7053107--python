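# tapscall: methods

## Calling model

TAPS turns 5mC/5hmC into a base that amplifies as T. After amplification and
alignment, a molecule's methylation state at a CpG is visible as the
reference-forward dinucleotide at that site: **TG** if the molecule was
methylated and sequenced from the top strand, **CA** if methylated and
sequenced from the bottom strand (its own C→T conversion appears as G→A on
the forward reference), **CG** if unmethylated. SAM stores SEQ
reference-forward, so classification ignores the alignment's reverse flag.

Per read and site, `classify_site` returns one of
`{TG, CA, CG, TA, OTHER, MISSING}`:

- **MISSING** — either position of the dinucleotide is unaligned (deletion,
  clip, or outside the read's span);
- **OTHER** — an insertion opens between the two read positions (the
  dinucleotide is disrupted), or the bases are not one of the four named
  pairs;
- **TA** — counted separately because a single converted strand cannot
  legitimately produce it: conversion acts on one strand's C, so TA is
  evidence of sequencing error or a variant.

Per site, `call_methylation` aggregates counts and computes

```
ratio = (n_TG + n_CA) / (n_TG + n_CA + n_CG)
```

undefined (NaN) when the denominator is zero. TA is excluded from both the
numerator and denominator. `NN` is defined as **all** informative
(non-missing) observations, and the variant filter flags sites where
`(n_TG + n_CA + n_CG) / NN` is not strictly greater than the threshold
(default 0.8): excess non-canonical dinucleotides at one site indicate a
genetic variant, not methylation. The filter can be disabled for references
where variants are not expected (it matters most for genomes like viral
isolates where the sample diverges from the reference).

The NN fraction cannot see a **homozygous C→T variant**: every read shows TG
in canonical form and the site looks fully methylated. The non-TAPS control
mask closes this gap: calling the same pipeline on unconverted alignments and
masking sites whose control ratio exceeds `control_ratio_max` (default 0.05,
a pragmatic allowance for residual error; there is no principled published
value) or whose control fails the NN filter. Sites missing from the control
are left unmasked and logged.

## Evaluation

- `track_correlation` — Pearson r between two per-site tracks over the
  intersection of sites with depth **strictly greater than** `min_depth`
  (default 8) in *both* tracks (symmetry is a design choice; applying the
  cutoff to only one track would bias the comparison toward the deeper
  assay). Fewer than 3 usable sites raises rather than returning a
  meaningless coefficient.
- `binarize_truth` — a site is labelled methylated iff its truth level is
  strictly above the cutoff (default 0.03, i.e. 3%).
- `roc_auc` — thresholds sweep the distinct predicted ratios (ties grouped at
  one threshold, `sklearn.metrics.roc_curve` with no intermediate dropping);
  AUC by the trapezoidal rule. The test suite checks the curve against the
  Mann–Whitney U identity `AUC = U / (n_pos · n_neg)` as an independent
  oracle.

## Phasing

`build_read_matrix` produces the read × CpG matrix with cells 1 (TG/CA),
0 (CG) and NA (anything else), rows ordered by alignment start then read id,
columns by coordinate; its column-wise (1, 0) counts equal the caller's
(TG+CA, CG) counts by construction, and a test enforces it. `rank_reads`
orders rows by decreasing mean over informative cells in a user-supplied
region (the analysis regions — e.g. CpG island boundaries — are inputs; CGI
prediction is out of scope); reads uninformative in the region go last in
their incoming order, ties break by read id. `site_correlation` is pairwise
Pearson over reads informative at both sites (pairwise-complete, via
`DataFrame.corr`), NA when fewer than `min_pairs` (default 10) complete pairs
exist or a site has zero variance — NA, never 0, so "no evidence" is not
conflated with "no correlation".

## Simulator

The simulator emulates the statistical structure the caller assumes, on a
stated world chosen once:

- **Reference**: 4 kb (the scale of a model amplicon), GC 0.5, i.i.d. bases
  with CpGs planted/stripped to `cpg_enrichment` × the i.i.d. expectation
  (default 1.0, ≈ 250 sites at the defaults).
- **Methylation**: per-site levels from Beta(0.5, 0.5) by default — a
  bimodal pattern with mostly-low and mostly-high sites, the shape CpG
  methylation typically has — or explicit fractions. Per-molecule states are
  independent Bernoulli draws; both strands of a molecule share the state by
  default (maintenance methylation keeps CpGs symmetric; hemimethylation
  frequency is unknown for the motivating data, so symmetry is a flagged
  assumption, not a fact).
- **Conversion**: methylated C → T with `conversion_rate` (default 0.97),
  any unmethylated C → T with `false_conversion_rate` (default 0.005). The
  chemistry is near-quantitative — restriction-digestion assays show complete
  conversion — but no exact rate is published, so near-complete defaults are
  used and both rates stay exposed. False conversion applies to cytosines in
  any context because the chemistry acts per-cytosine; only CpG context is
  scored downstream.
- **Reads**: one molecule per read, log-normal lengths (mean 3000, sd 1500)
  truncated to [100, reference length], uniform start, strand drawn 50/50.
  Substitution/insertion/deletion errors (defaults 0.05/0.03/0.03, the ~10%
  long-read error regime) are applied after conversion and reflected exactly
  in the CIGAR; a leading/trailing deletion is converted to a match so the
  CIGAR span always equals the provenance interval. SAM records are emitted
  reference-forward (FLAG 16 and a `ZS` tag record bottom-strand origin, `ZM`
  the molecule id); the FASTQ carries the strand-of-origin sequence.
- **Determinism**: one RNG stream seeded from `SimConfig.seed`, draws in a
  fixed order; identical configs give byte-identical FASTA/FASTQ/SAM/truth
  files.

The truth tables record both the *intended* per-site level and the
*realized* one (the mean over simulated molecule strands). Evaluation against
simulator truth prefers the realized level: it is the quantity a perfect
caller recovers exactly, whereas the intended level differs from it by
binomial sampling noise.

What the simulator does **not** emulate: basecaller signal artifacts and
homopolymer-biased errors, adapter/barcode structure, chimeras, mapping
ambiguity (it emits truth alignments, so the aligner is bypassed), PCR
duplicates and amplification bias, and 5hmC vs 5mC (TAPS reads their sum). A
green test therefore establishes correctness of the counting, filtering and
phasing logic under the stated error model — not robustness to every real
long-read artifact.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere; output headers say so.
- Strict inequalities follow the stated cutoffs: depth "> 8", truth level
  "> 3%", NN fraction "> 0.8".
- Undefined ratios/correlations are NaN/NA, never silently 0.
- `min_depth` for calling defaults to 1; the depth-8 rule belongs to track
  comparison, not calling.
- Secondary/supplementary alignments are skipped by default; MAPQ is not
  filtered by default (amplicon-style data; both are flags).
- The default read-length filter is pass-through — per-sample length cutoffs
  are experiment-specific and must be user-supplied.
- Empty inputs produce empty outputs (empty record list → header-only
  tables); a reference with no CpG, a region with no site, or single-class
  ROC labels fail loudly.

## Known limitations

- CpH methylation is not called (the conversion chemistry touches it, but
  scoring is CpG-only).
- Per-strand asymmetric methylation is simulated (flag) but reported pooled;
  hemimethylation analysis would need a strand-split caller.
- The control mask threshold and the NN definition are pragmatic defaults,
  exposed as flags, not derived quantities.
- Heterozygous variants produce intermediate NN fractions and may pass the
  filter at low alternate-allele fractions; the acceptance tests document the
  filter's limits rather than hiding them.
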