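"""Per-read coverage-rate scoring and intact/fragmented classification.

A read's coverage rate is the fraction of its assigned transcript covered by
the union of its alignment match blocks.  A read is *intact* when the
coverage rate strictly exceeds the threshold (default 0.90, i.e. the
"coverage > 90%" criterion); otherwise it is *fragmented*.  Coverage uses
aligned match blocks only — deleted reference bases do not count as covered
unless they were bridged during alignment parsing — so the rate reflects RNA
that is physically present in the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .read_ingest import TranscriptAlignment
from .stats import TestResult, welch_t
from .transcript_model import TranscriptCatalog

logger = logging.getLogger(__name__)

INTACT = "intact"
FRAGMENTED = "fragmented"


@dataclass(frozen=True)
class IntegrityConfig:
    """``intact_threshold`` is strict: coverage must exceed it to be intact."""

    intact_threshold: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.intact_threshold < 1:
            raise ValueError("intact_threshold must be in (0, 1)")


@dataclass(frozen=True)
class IntegrityCall:
    read_id: str
    transcript_id: str
    coverage_rate: float
    label: str


def coverage_rate(aln: TranscriptAlignment, transcript_length: int) -> float:
    """Union width of the alignment's match blocks over transcript length."""
    if transcript_length <= 0:
        raise ValueError("transcript_length must be positive")
    if aln.t_end > transcript_length:
        raise ValueError(
            f"alignment {aln.read_id}->{aln.transcript_id} extends past transcript end"
        )
    covered = 0
    prev_end = -1
    for start, end in aln.blocks:  # blocks are sorted, non-overlapping
        covered += end - max(start, prev_end)
        prev_end = end
    return covered / transcript_length


def classify_integrity(cov: float, cfg: IntegrityConfig = IntegrityConfig()) -> str:
    if not 0 <= cov <= 1:
        raise ValueError(f"coverage rate {cov} outside [0, 1]")
    return INTACT if cov > cfg.intact_threshold else FRAGMENTED


def call_integrity(
    primaries: Mapping[str, TranscriptAlignment],
    catalog: TranscriptCatalog,
    cfg: IntegrityConfig = IntegrityConfig(),
) -> list[IntegrityCall]:
    """One IntegrityCall per read, against its primary transcript."""
    calls = []
    for read_id in primaries:
        aln = primaries[read_id]
        cov = coverage_rate(aln, catalog.length_of(aln.transcript_id))
        calls.append(
            IntegrityCall(read_id, aln.transcript_id, cov, classify_integrity(cov, cfg))
        )
    return calls


def intact_proportion(calls: Sequence[IntegrityCall]) -> float:
    if not calls:
        raise ValueError("no calls")
    return sum(c.label == INTACT for c in calls) / len(calls)


def transcript_weighted_intact_proportion(
    calls: Sequence[IntegrityCall], cfg: IntegrityConfig = IntegrityConfig()
) -> float:
    """Intact share over distinct transcripts, using each transcript's best
    coverage (alternative weighting of the sample-level summary)."""
    if not calls:
        raise ValueError("no calls")
    best: dict[str, float] = {}
    for c in calls:
        if c.coverage_rate > best.get(c.transcript_id, -1.0):
            best[c.transcript_id] = c.coverage_rate
    return sum(cov > cfg.intact_threshold for cov in best.values()) / len(best)


@dataclass
class IntegrityComparison:
    proportions: dict[str, float]
    group_means: dict[str, float]
    test: TestResult | None
    excluded_samples: list[str]
    notice: str | None = None


def intact_proportion_comparison(
    calls_by_sample: Mapping[str, Sequence[IntegrityCall]],
    sample_groups: Mapping[str, str],
) -> IntegrityComparison:
    """Per-sample intact proportions and a two-sided Welch t-test between the
    two groups of proportions.  Samples with zero calls are excluded (and
    listed); the test is skipped with a notice when a group has < 2 usable
    samples."""
    proportions: dict[str, float] = {}
    excluded: list[str] = []
    for sample_id, calls in calls_by_sample.items():
        if not calls:
            excluded.append(sample_id)
            logger.warning("sample %s has no integrity calls; excluded", sample_id)
            continue
        proportions[sample_id] = intact_proportion(calls)
    groups = sorted({sample_groups[s] for s in proportions})
    by_group = {
        g: [proportions[s] for s in proportions if sample_groups[s] == g] for g in groups
    }
    group_means = {g: float(np.mean(v)) for g, v in by_group.items() if v}
    if len(groups) != 2 or any(len(by_group[g]) < 2 for g in groups):
        return IntegrityComparison(
            proportions, group_means, None, excluded,
            notice="t-test skipped: need 2 groups with >= 2 samples each",
        )
    test = welch_t(by_group[groups[0]], by_group[groups[1]])
    return IntegrityComparison(proportions, group_means, test, excluded)
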