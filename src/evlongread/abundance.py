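"""Read-to-transcript assignment and sample-level composition statistics.

``em_assign`` reimplements the standard long-read mixture EM (NanoCount
style): reads that align compatibly to several transcripts are fractionally
allocated in proportion to current abundance estimates until the estimates
stop moving.  The remaining operations turn per-sample count profiles into
the composition, concordance and group-heterogeneity summaries of the
analysis: dual biotype metrics (share of distinct transcripts vs share of
read counts), intrinsic genes present in every sample, group-specific
transcript sets, inter-sample Pearson correlation, and a presence screen for
RNA-degradation machinery genes.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .read_ingest import ReadSummary, TranscriptAlignment, select_primary
from .stats import TestResult, chi_square_2x2
from .transcript_model import KNOWN_BIOTYPES, TranscriptCatalog

logger = logging.getLogger(__name__)

#: Expected counts below this are treated as numerical zero before the
#: presence/absence threshold is applied.
COUNT_FLOOR = 1e-3
#: A transcript/gene counts as detected when its (floored) count reaches this.
DETECTION_THRESHOLD = 1.0

DEGRADATION_MACHINERY_GENES = ("SMG5", "PARN", "CNOT1", "LSM*")


@dataclass
class EMResult:
    counts: dict[str, float]
    n_assigned: int
    n_dropped: int
    n_iterations: int
    log_likelihood: list[float] = field(default_factory=list)


def em_assign(
    compatibility: Mapping[str, Sequence[TranscriptAlignment]],
    mode: str = "em",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> EMResult:
    """Allocate reads to transcripts.

    ``primary_only``: each read contributes 1 to its primary alignment's
    transcript.  ``em``: abundances start uniform over observed transcripts;
    the E-step splits each read over its candidates in proportion to current
    abundance, the M-step renormalizes, iterating until the max absolute
    abundance change drops below ``tol``.  Reads with no candidates are
    dropped and counted.
    """
    if mode not in ("primary_only", "em"):
        raise ValueError(f"unknown mode {mode!r}")
    usable = {rid: cands for rid, cands in compatibility.items() if cands}
    n_dropped = len(compatibility) - len(usable)
    if n_dropped:
        logger.warning("%d reads had no candidate alignments; dropped", n_dropped)
    if mode == "primary_only":
        counts: dict[str, float] = {}
        for cands in usable.values():
            tid = select_primary(cands).transcript_id
            counts[tid] = counts.get(tid, 0.0) + 1.0
        return EMResult(counts, n_assigned=len(usable), n_dropped=n_dropped, n_iterations=0)

    tids = sorted({aln.transcript_id for cands in usable.values() for aln in cands})
    tid_index = {tid: i for i, tid in enumerate(tids)}
    cand_idx = [
        np.fromiter(
            sorted({tid_index[aln.transcript_id] for aln in cands}), dtype=np.intp
        )
        for cands in usable.values()
    ]
    n_tx = len(tids)
    n_reads = len(cand_idx)
    if n_reads == 0:
        return EMResult({}, 0, n_dropped, 0)
    theta = np.full(n_tx, 1.0 / n_tx)
    loglik_trace: list[float] = []
    responsibilities = np.zeros(n_tx)
    iteration = 0
    for iteration in range(1, max_iter + 1):
        responsibilities[:] = 0.0
        loglik = 0.0
        for idx in cand_idx:
            probs = theta[idx]
            total = probs.sum()
            loglik += np.log(total)
            responsibilities[idx] += probs / total
        new_theta = responsibilities / n_reads
        loglik_trace.append(float(loglik))
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < tol:
            break
    counts = {
        tid: float(theta[i] * n_reads) for tid, i in tid_index.items() if theta[i] > 0
    }
    return EMResult(counts, n_assigned=n_reads, n_dropped=n_dropped,
                    n_iterations=iteration, log_likelihood=loglik_trace)


@dataclass
class SampleProfile:
    """Per-sample transcript counts plus read summary; unit of all group comparisons."""

    sample_id: str
    group: str
    counts: dict[str, float]
    read_summary: ReadSummary | None = None

    def detected_transcripts(self, threshold: float = DETECTION_THRESHOLD) -> set[str]:
        return {
            tid
            for tid, c in self.counts.items()
            if (c if c >= COUNT_FLOOR else 0.0) >= threshold
        }

    def detected_genes(
        self, catalog: TranscriptCatalog, threshold: float = DETECTION_THRESHOLD
    ) -> set[str]:
        return {
            catalog.gene_of(tid)
            for tid in self.detected_transcripts(threshold)
            if tid in catalog
        }

    def gene_counts(self, catalog: TranscriptCatalog) -> dict[str, float]:
        out: dict[str, float] = {}
        for tid, c in self.counts.items():
            if tid in catalog:
                gid = catalog.gene_of(tid)
                out[gid] = out.get(gid, 0.0) + c
        return out


def composition(
    profile: SampleProfile,
    catalog: TranscriptCatalog,
    presence_threshold: float = 0.0,
) -> pd.DataFrame:
    """Dual biotype table: percent of distinct transcripts vs percent of reads.

    ``composition_percentage`` counts each detected transcript once (count >
    ``presence_threshold``); ``read_count_ratio`` weights by read counts.
    Every biotype of the closed vocabulary appears as a row (zero when
    absent); each column sums to 100.
    """
    if not profile.counts:
        raise ValueError("empty profile")
    presence = pd.Series(0.0, index=list(KNOWN_BIOTYPES))
    reads = pd.Series(0.0, index=list(KNOWN_BIOTYPES))
    for tid, count in profile.counts.items():
        if tid not in catalog:
            continue
        biotype = catalog[tid].biotype
        if count > presence_threshold:
            presence[biotype] += 1.0
        reads[biotype] += count
    table = pd.DataFrame(
        {
            "composition_percentage": 100.0 * presence / presence.sum(),
            "read_count_ratio": 100.0 * reads / reads.sum(),
        }
    )
    table.index.name = "biotype"
    return table


@dataclass
class IntrinsicResult:
    intrinsic_genes: set[str]
    all_genes: set[str]
    proportion: float
    table: tuple[tuple[int, int], tuple[int, int]] | None
    test: TestResult | None
    notice: str | None = None


def intrinsic_genes(
    profiles: Sequence[SampleProfile],
    catalog: TranscriptCatalog,
    yates: bool = False,
) -> IntrinsicResult:
    """Genes detected in every sample, their share of all detected genes, and
    a 2x2 chi-square comparing the intrinsic share between groups.

    The 2x2 table is (intrinsic, non-intrinsic) x (Exo-detected, MV-detected),
    where per-group detection means present in *all* samples of the group.
    The denominator of ``proportion`` is the union of genes over samples.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 samples")
    per_sample = [p.detected_genes(catalog) for p in profiles]
    intrinsic = set.intersection(*per_sample)
    union = set.union(*per_sample)
    proportion = len(intrinsic) / len(union) if union else float("nan")

    groups = sorted({p.group for p in profiles})
    if len(groups) != 2:
        return IntrinsicResult(
            intrinsic, union, proportion, None, None,
            notice="chi-square skipped: need exactly 2 groups",
        )
    per_group: list[set[str]] = []
    for g in groups:
        sets = [s for p, s in zip(profiles, per_sample) if p.group == g]
        per_group.append(set.intersection(*sets) if sets else set())
    table = (
        (len(intrinsic & per_group[0]), len(intrinsic & per_group[1])),
        (len(per_group[0] - intrinsic), len(per_group[1] - intrinsic)),
    )
    try:
        test = chi_square_2x2(table, yates=yates)
        notice = None
    except ValueError as exc:
        test = None
        notice = f"chi-square skipped: {exc}"
    return IntrinsicResult(intrinsic, union, proportion, table, test, notice)


def _expression_matrix(
    profiles: Sequence[SampleProfile], top_n: int | None = None
) -> pd.DataFrame:
    tids = sorted({tid for p in profiles for tid in p.counts})
    mat = pd.DataFrame(
        {p.sample_id: [p.counts.get(tid, 0.0) for tid in tids] for p in profiles},
        index=tids,
    )
    if top_n is not None:
        top = mat.mean(axis=1).sort_values(ascending=False, kind="stable").index[:top_n]
        mat = mat.loc[top]
    return mat


def correlation_matrix(
    profiles: Sequence[SampleProfile],
    top_n: int | None = None,
    transform: str = "log1p10",
) -> pd.DataFrame:
    """Pairwise Pearson r between sample expression vectors.

    Counts are transformed log10(x+1) by default (``transform="none"`` to
    disable).  With ``top_n``, the matrix is restricted to the top_n
    transcripts by mean expression across all samples.  A zero-variance
    sample yields NaN against every other sample (undefined, not 0).
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    if transform not in ("log1p10", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    mat = _expression_matrix(profiles, top_n)
    values = mat.to_numpy(dtype=float)
    if transform == "log1p10":
        values = np.log10(values + 1.0)
    n_samples = values.shape[1]
    out = np.full((n_samples, n_samples), np.nan)
    zero_var = np.ptp(values, axis=0) == 0  # constant vector: r undefined
    for i in range(n_samples):
        out[i, i] = 1.0
        for j in range(i + 1, n_samples):
            if zero_var[i] or zero_var[j]:
                continue
            r = float(np.corrcoef(values[:, i], values[:, j])[0, 1])
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=mat.columns, columns=mat.columns)


@dataclass
class GroupSpecificSets:
    groups: tuple[str, str]
    unique_transcripts: dict[str, set[str]]
    unique_genes: dict[str, set[str]]
    shared_transcripts: set[str]
    shared_genes: set[str]


def group_specific_sets(
    profiles: Sequence[SampleProfile], catalog: TranscriptCatalog
) -> GroupSpecificSets:
    """Transcripts/genes detected only in one group (>=1 sample of that group,
    0 samples of the other), plus the shared sets."""
    groups = sorted({p.group for p in profiles})
    if len(groups) != 2:
        raise ValueError("need exactly 2 groups")
    det_tx = {
        g: set().union(
            *[p.detected_transcripts() for p in profiles if p.group == g]
        )
        for g in groups
    }
    unique_tx = {
        groups[0]: det_tx[groups[0]] - det_tx[groups[1]],
        groups[1]: det_tx[groups[1]] - det_tx[groups[0]],
    }
    shared_tx = det_tx[groups[0]] & det_tx[groups[1]]

    def genes_of(tids: set[str]) -> set[str]:
        return {catalog.gene_of(t) for t in tids if t in catalog}

    det_genes = {g: genes_of(det_tx[g]) for g in groups}
    unique_genes = {
        groups[0]: det_genes[groups[0]] - det_genes[groups[1]],
        groups[1]: det_genes[groups[1]] - det_genes[groups[0]],
    }
    return GroupSpecificSets(
        groups=(groups[0], groups[1]),
        unique_transcripts=unique_tx,
        unique_genes=unique_genes,
        shared_transcripts=shared_tx,
        shared_genes=det_genes[groups[0]] & det_genes[groups[1]],
    )


def flag_degradation_machinery(
    profiles: Sequence[SampleProfile],
    catalog: TranscriptCatalog,
    gene_list: Iterable[str] = DEGRADATION_MACHINERY_GENES,
) -> pd.DataFrame:
    """Per-sample presence of RNA-degradation machinery genes.

    Patterns ending in ``*`` match gene symbols by prefix (``LSM*`` catches
    the whole LSM assembly-factor family).  Rows are matched gene symbols
    (patterns with no match appear as the pattern itself, all-False).
    """
    patterns = list(gene_list)
    all_genes = sorted({catalog.gene_of(t) for t in catalog.transcripts})
    rows: list[str] = []
    for pattern in patterns:
        matched = fnmatch.filter(all_genes, pattern)
        rows.extend(matched if matched else [pattern])
    rows = sorted(set(rows))
    data = {
        p.sample_id: [gene in p.detected_genes(catalog) for gene in rows]
        for p in profiles
    }
    table = pd.DataFrame(data, index=rows)
    table.index.name = "gene"
    return table
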