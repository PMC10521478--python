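# Methods

## Coordinate model

All classification happens in *transcript space*: 0-based half-open
intervals with position 0 at the mature transcript's 5' end.  For
minus-strand genes the 5'-most base is the exon base with the largest
genomic coordinate, so exon order in transcript space is the reverse of
genomic order; `genome_to_transcript` performs this strand-aware projection
when alignments arrive in genomic coordinates.  Keeping a single convention
internally (1-based only at the GTF boundary) eliminates off-by-one drift
between modules.

## Read QC and summaries

Reads are filtered on arithmetic mean per-base Phred quality, default
threshold 7, with reads *below* the threshold removed (a read at exactly 7
is kept).  N50 uses the ascending cumulative-sum convention common in
long-read QC reporting: sort lengths ascending and take the first length at
which the running base total reaches half of all bases (for lengths
500/500/1000 this yields 500).  A brute-force oracle in the test suite pins
this tie convention.

## Coverage rate and integrity

For a read's primary alignment (most matching bases; ties broken by longer
span, then lexicographic transcript id) the coverage rate is the width of
the union of match/mismatch blocks divided by transcript length.  Deletions
split blocks and do not count as covered — the rate reflects RNA physically
present in the read; `bridge_deletions` can merge blocks across small
deletions for robustness analyses.  A read is **intact** iff coverage
strictly exceeds `intact_threshold` (default 0.90).  Sample-level intact
proportions are read-weighted by default; a transcript-weighted variant
(best coverage per transcript) is also reported, since either weighting is
defensible for a sample summary.

## Degradation direction

With end tolerance `δ = max(end_tolerance_min, end_tolerance_fraction · L)`
(defaults 20 nt and 0.10), a fragment covers the 5' terminus iff its start
is ≤ δ and the 3' terminus iff its end is ≥ L − δ.  The four outcomes map
to 3'→5' degradation (5' kept), 5'→3' degradation (3' kept), endodegradation
(neither) and `ambiguous_internal` (both ends covered yet fragmented, which
requires internal alignment gaps).  The 0.10 fraction mirrors the 0.90
intact threshold: a read missing at most 10% at one end is treated as
reaching that end.  Ambiguous reads are excluded from the three-way
proportion denominator and reported separately; `--ambiguous-as endo` folds
them in instead.  Direction semantics are fixed in transcript space, which
is what resolves apparently "reversed" exon numbering for minus-strand
genes.

Geometry note: an endodegraded call is only possible when the fragment fits
strictly between the tolerances, so its coverage is bounded by
`(L − 2δ)/L` (0.8 at the default δ); end-anchored classes can occupy the
high-coverage bins.  `coverage_by_direction` reports the binned (0.1-wide)
coverage histograms per class.

## Read assignment (EM)

Multi-mapping reads are allocated by a standard mixture EM over their
candidate transcripts: abundances initialize uniform over observed
transcripts; the E-step splits each read proportionally to current
abundance; the M-step renormalizes; iteration stops when the max absolute
abundance change is < 1e-8 (cap 1000 iterations).  Expected counts are the
summed responsibilities, so reads are conserved at every iteration and the
log-likelihood is non-decreasing (both asserted in tests against an
independent fixed-point oracle).  `primary_only` mode (the default in the
pipeline, whose simulated inputs are unique-mapping) counts each read once
at its primary alignment.

## Composition and group statistics

* **Dual biotype metrics**: `composition_percentage` is the share of
  *distinct* detected transcripts per biotype, `read_count_ratio` the share
  of read counts; both normalized to 100 over a closed biotype vocabulary
  (protein_coding, retained_intron, lncRNA, nonsense_mediated_decay,
  processed_transcript, misc_RNA, rRNA, other — unknown labels collapse to
  "other" with a warning).
* **Detection** means floored expected count ≥ 1 (counts below 1e-3 are
  treated as numerical zero).  The threshold is configurable; no standard
  exists for EM fractional counts.
* **Intrinsic genes** are those detected in every sample; the reported
  proportion uses the union of detected genes as denominator (the natural
  reading of "of the genes identified"), and a 2×2 chi-square
  ((intrinsic, non-intrinsic) × per-group detected-in-all-samples) compares
  groups, without Yates correction by default.
* **Concordance**: Pearson r between per-sample log10(count+1) vectors
  (transform configurable), optionally restricted to the top-N transcripts
  by mean expression; zero-variance vectors yield missing values rather
  than 0.
* **Degradation machinery screen**: presence of SMG5, PARN, CNOT1 and the
  LSM family (prefix pattern `LSM*`) per sample.

## Inferential statistics

Welch t (default for "unpaired t-test"; pooled-variance flag available),
2×2 chi-square as Σ(O−E)²/E with df 1, Pearson r with
t = r·√((n−2)/(1−r²)), and an additive two-way fixed-effects ANOVA
(group × length-bin, no interaction) on per-sample binned length
proportions (200-nt bins to 2,000 plus overflow).  All statistics are
computed from their closed forms in `stats.py`; scipy supplies only the
t/χ²/F tail probabilities.  Tests verify each procedure against
scipy/statsmodels to 1e-8 on 100 random instances.  Raw p-values are
reported; no multiple-testing correction is applied anywhere.

## Synthetic data: what it emulates, and what it does not

Defaults encode the emulated regime: transcript lengths log-normal
(μ_log 6.2, σ_log 0.8, truncated to [200, 32000] nt — chosen so that the
resulting read population has mean length in the several-hundred-nt range
with N50 ≈ 400–800), biotypes 65% protein-coding with the remainder across
six classes, 1+Poisson(4) exons per transcript, intact probability 0.3066
(per group: Exo 0.3566, MV 0.2566, i.e. a 0.10 gap around that mean), and
direction weights (0.4266, 0.3447, 0.2288) for 3'→5'/endo/5'→3'.  Retained
fraction for fragments is U(0.05, 0.89) — capped below the 0.90 threshold so
noise-free truth-agreement is exact.  Mean quality ~N(11.8, 1.0) with a 2%
low-quality tail that the QC filter removes.  Abundances are log-normal
with 5% of transcripts exclusive per group, and per-sample log-normal noise
that is smaller for exosomes (0.15 vs 0.5), producing the higher
within-exosome concordance the pipeline should detect.

**Cut margins.** By default (`cut_margin_mode="tolerance"`) every lost
terminus loses strictly more than the classifier's δ, and the retained
fraction of endodegraded reads is capped at `(L−2δ−2)/L` so the internal
window fits between the margins.  This makes the generated taxonomy
*identifiable*: without the margin, an endodegraded fragment would
frequently land within δ of a terminus and be (correctly, per the
classifier's semantics) called end-anchored, so no configured mixture could
be recovered.  The margin is therefore part of the generative definition of
the three classes, not a convenience; `cut_margin_mode="minimal"` (lose
≥ 1 nt) exists for studying exactly that boundary leakage.  Optional
Gaussian jitter on emitted alignment ends models aligner end-trimming;
truth always records the pre-jitter interval.

Deliberately not modeled: nanopore error profiles and base-calling,
poly(A)/library chemistry, coverage bias along transcripts, intron-level
mis-splicing.  Consequently, passing truth-recovery tests demonstrates the
*logic* of the classifiers, not their robustness to alignment noise — the
jitter knob and `bridge_deletions` are the entry points for such studies on
real data.

Determinism: every stream is `default_rng([crc32(label), seed])`, so
samples are independent and adding one never perturbs another; fixture
outputs are byte-identical across runs, and a committed golden report
bundle pins the full pipeline at seed 7.

## Problem sizes

The bundled study fixture uses 300 transcripts and 5,000 reads per sample
(6 samples); truth-recovery tests use 10,000 reads per sample, mixture
recovery 20,000 reads, and the null calibration of the group test 100 seeds
at 5,000 reads/sample — sizes at which binomial sampling error (≈ 0.3–0.4
percentage points SD) sits comfortably inside the ±1.5-pp recovery bands.

## Known limitations

* Direction calls assume the annotation's transcript ends are the molecule's
  true termini; retained-intron or alternative-end isoforms misassigned at
  the alignment stage can masquerade as degradation.
* The EM has no alignment-score weighting (candidates count equally), and
  no length normalization — counts estimate read allocation, not molar
  concentration (TPM-style measures are out of scope).
* The two-way ANOVA is designed for balanced group sizes; unbalanced
  designs fall back on weighted-means sums of squares that are not
  type-II-orthogonal.
* `ambiguous_internal` requires split alignment blocks; with single-block
  simulated alignments it never occurs (the class is exercised by unit
  tests with gapped CIGARs).
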