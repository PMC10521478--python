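# evlongread

Analysis pipeline for **long-read (nanopore cDNA) transcriptomes of
extracellular vesicles (EVs)**: per-read transcript coverage-rate scoring,
intact/fragmented classification, RNA degradation-direction inference and
between-subtype (exosome vs microvesicle) heterogeneity statistics — plus a
ground-truth simulator so every stage is testable offline.

## Who this is for

EV RNA cargo is dominated by partial transcripts. Long-read sequencing sees
each molecule end-to-end, which makes two questions answerable per read:

1. **Integrity** — what fraction of the annotated transcript does this read
   cover?  A read with coverage rate
   `c = |union of aligned match blocks| / L` strictly above 0.90 is called
   *intact*, otherwise *fragmented*.
2. **Directionality** — which terminus did a fragment lose?  Working in
   transcript 5'→3' coordinates with end tolerance
   `δ = max(20 nt, 0.10·L)`:
   * keeps the 5' terminus only → **3'→5' degradation** (exonucleolytic loss
     from the 3' end),
   * keeps the 3' terminus only → **5'→3' degradation**,
   * keeps neither → **endodegradation** (internal cleavage),
   * keeps both yet is fragmented → *ambiguous_internal*, reported
     separately.

Around these calls the package provides read QC (mean Phred ≥ 7) and
summaries (mean/median/N50 length), NanoCount-style EM assignment of
multi-mapping reads, dual biotype composition metrics (share of distinct
transcripts vs share of read counts), intrinsic-gene and group-specific
transcript sets, inter-sample Pearson concordance, and Welch-t / chi-square /
two-way-ANOVA comparisons between EV subtypes.

## Worked example

Simulate a 3-exosome + 3-microvesicle study (with ground truth) and run the
full pipeline:

```bash
evlongread simulate --out-dir fixture --seed 7
evlongread run --annotation fixture/annotation.gtf \
    --sample-sheet fixture/sample_sheet.tsv --out-dir report
```

`report/integrity_summary.json` then contains (seed 7, 5,000 reads/sample):

```
"overall_intact_proportion": 0.3048...,
"group_means": {"Exo": 0.3572, "MV": 0.2522},
"welch_t": {"statistic": 7.63..., "p_value": 0.00185, ...}
```

i.e. ~30% of reads are intact overall, exosomes carry a significantly higher
intact fraction than microvesicles (Welch t, p ≈ 0.002) — the generated gap
was 0.10.  `report/degradation_summary.json` reports the direction split of
fragmented reads:

```
"proportions": {"deg_3to5": 0.4243, "endo": 0.3528, "deg_5to3": 0.2229}
```

matching the configured (0.4266, 0.3447, 0.2288) mixture to sampling noise.
The other report files are `read_summary.tsv` (per-sample N50 etc.),
`composition.tsv` (dual biotype metrics), `correlation_matrix.tsv`,
`gene_report.json` (intrinsic/group-specific genes, degradation-machinery
presence), `coverage_by_direction.tsv` and `stats.json`.

Single stages are available as `evlongread integrity|degradation|compose|stats`
on intermediate TSVs.  Exit codes: 0 ok, 2 configuration error, 3 no data,
4 stage failure.

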