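"""Degradation-direction classification of fragmented reads.

Directionality is inferred from which transcript terminus a fragment still
covers, working entirely in transcript 5'→3' coordinates:

* fragment keeps the 5' terminus but not the 3' → progressive loss from the
  3' end, i.e. 3'→5' exonucleolytic degradation (``deg_3to5``);
* fragment keeps the 3' terminus only → 5'→3' degradation (``deg_5to3``);
* fragment keeps neither terminus → internal cleavage, endodegradation
  (``endo``);
* fragment covers both termini yet is below the intact threshold (internal
  gaps) → ``ambiguous_internal``, reported separately rather than folded
  into a mechanism class.

"Covers a terminus" is tolerance-based: a block end within
δ = max(end_tolerance_min, end_tolerance_fraction × transcript length)
of the terminus counts as reaching it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .integrity import IntegrityCall
from .read_ingest import TranscriptAlignment

DEG_3TO5 = "deg_3to5"
DEG_5TO3 = "deg_5to3"
ENDO = "endo"
AMBIGUOUS = "ambiguous_internal"
DIRECTIONS = (DEG_3TO5, ENDO, DEG_5TO3)


@dataclass(frozen=True)
class DegradationConfig:
    end_tolerance_fraction: float = 0.10
    end_tolerance_min: int = 20

    def __post_init__(self) -> None:
        if self.end_tolerance_fraction < 0 or self.end_tolerance_min < 0:
            raise ValueError("tolerances must be non-negative")

    def delta(self, transcript_length: int) -> float:
        d = max(self.end_tolerance_min, self.end_tolerance_fraction * transcript_length)
        if d >= transcript_length / 2:
            raise ValueError(
                f"end tolerance {d} >= half of transcript length {transcript_length}"
            )
        return d


@dataclass(frozen=True)
class DegradationCall:
    read_id: str
    transcript_id: str
    direction: str
    covers_5prime: bool
    covers_3prime: bool


def classify_direction(
    aln: TranscriptAlignment,
    transcript_length: int,
    cfg: DegradationConfig = DegradationConfig(),
    coverage_rate: float | None = None,
    intact_threshold: float = 0.90,
) -> DegradationCall:
    """Direction call for one fragmented read.

    The caller is responsible for passing only fragmented reads; when
    ``coverage_rate`` is supplied it is checked against ``intact_threshold``
    and an intact read raises (contract violation).
    """
    if coverage_rate is not None and coverage_rate > intact_threshold:
        raise ValueError(
            f"read {aln.read_id} is intact (coverage {coverage_rate:.3f}); "
            "direction classification applies to fragmented reads only"
        )
    delta = cfg.delta(transcript_length)
    covers_5 = aln.t_start <= delta
    covers_3 = aln.t_end >= transcript_length - delta
    if covers_5 and not covers_3:
        direction = DEG_3TO5
    elif covers_3 and not covers_5:
        direction = DEG_5TO3
    elif not covers_5 and not covers_3:
        direction = ENDO
    else:
        direction = AMBIGUOUS
    return DegradationCall(aln.read_id, aln.transcript_id, direction, covers_5, covers_3)


@dataclass
class DirectionSummary:
    proportions: dict[str, float] | None
    n_directional: int
    n_ambiguous: int

    def as_dict(self) -> dict:
        return {
            "proportions": self.proportions,
            "n_directional": self.n_directional,
            "n_ambiguous": self.n_ambiguous,
        }


def direction_proportions(
    calls: Sequence[DegradationCall], ambiguous_as: str | None = None
) -> DirectionSummary:
    """Fractions over {3'→5', endo, 5'→3'}.

    Ambiguous (both-ends-covered) calls are excluded from the denominator and
    reported separately; ``ambiguous_as="endo"`` folds them into endo
    instead.  All-ambiguous input yields ``proportions=None``.
    """
    if not calls:
        raise ValueError("no fragmented calls")
    if ambiguous_as not in (None, ENDO):
        raise ValueError(f"ambiguous_as must be None or {ENDO!r}")
    counts = Counter(c.direction for c in calls)
    n_ambiguous = counts.pop(AMBIGUOUS, 0)
    if ambiguous_as == ENDO:
        counts[ENDO] += n_ambiguous
        n_ambiguous = 0
    n_directional = sum(counts.values())
    if n_directional == 0:
        return DirectionSummary(None, 0, n_ambiguous)
    proportions = {d: counts.get(d, 0) / n_directional for d in DIRECTIONS}
    return DirectionSummary(proportions, n_directional, n_ambiguous)


def coverage_by_direction(
    integrity_calls: Sequence[IntegrityCall],
    degradation_calls: Sequence[DegradationCall],
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Histogram of coverage rates per direction (fragmented reads only).

    Rows are coverage bins ``[0.0,0.1), ..., [0.9,1.0]``; columns are the
    direction classes.  Joined on read_id.
    """
    cov_by_read = {c.read_id: c.coverage_rate for c in integrity_calls}
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    labels = [f"[{edges[i]:.1f},{edges[i+1]:.1f})" for i in range(len(edges) - 1)]
    table = pd.DataFrame(
        0, index=labels, columns=list(DIRECTIONS) + [AMBIGUOUS], dtype=int
    )
    for call in degradation_calls:
        cov = cov_by_read.get(call.read_id)
        if cov is None:
            continue
        idx = min(int(cov / bin_width), len(labels) - 1)
        table.iloc[idx, table.columns.get_loc(call.direction)] += 1
    table.index.name = "coverage_bin"
    return table


def call_directions(
    fragmented: Mapping[str, TranscriptAlignment],
    transcript_lengths: Mapping[str, int],
    cfg: DegradationConfig = DegradationConfig(),
) -> list[DegradationCall]:
    """Classify every fragmented primary alignment."""
    return [
        classify_direction(aln, transcript_lengths[aln.transcript_id], cfg)
        for aln in fragmented.values()
    ]
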