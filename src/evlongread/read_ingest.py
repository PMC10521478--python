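"""Read-level QC, summary statistics and alignment ingestion.

Alignments are consumed in *transcript* space, either as PAF rows (the
aligner ran against the transcriptome) or as the package's plain
``alignment-TSV`` dialect::

    read_id <tab> transcript_id <tab> t_len <tab> blocks <tab> matches

where ``blocks`` is ``start-end;start-end;...`` in 0-based half-open
transcript coordinates.  The simulator emits this dialect, so the whole
pipeline is testable without running an aligner.
"""

from __future__ import annotations

import logging
import re
import statistics
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced read: length and mean per-base Phred quality."""

    read_id: str
    length: int
    mean_quality: float


@dataclass(frozen=True)
class QCConfig:
    """Quality filter settings.

    Reads with mean quality *below* ``min_mean_quality`` are removed; a read
    exactly at the threshold is kept.
    """

    min_mean_quality: float = 7.0

    def __post_init__(self) -> None:
        if self.min_mean_quality < 0:
            raise ValueError("min_mean_quality must be >= 0")


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    n_removed: int = 0

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept, "n_removed": self.n_removed}


@dataclass(frozen=True)
class TranscriptAlignment:
    """One read's placement on one transcript (match blocks only).

    ``blocks`` are sorted, non-overlapping transcript intervals covered by
    match/mismatch operations; ``matches`` counts matching bases as reported
    by the aligner.
    """

    read_id: str
    transcript_id: str
    blocks: tuple[tuple[int, int], ...]
    matches: int

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"alignment {self.read_id}->{self.transcript_id}: no blocks")
        prev_end = None
        for start, end in self.blocks:
            if end <= start or start < 0:
                raise ValueError(
                    f"alignment {self.read_id}->{self.transcript_id}: bad block [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"alignment {self.read_id}->{self.transcript_id}: blocks overlap/unsorted"
                )
            prev_end = end

    @property
    def t_start(self) -> int:
        return self.blocks[0][0]

    @property
    def t_end(self) -> int:
        return self.blocks[-1][1]

    @property
    def span(self) -> int:
        return self.t_end - self.t_start

    @property
    def aligned_bases(self) -> int:
        return sum(end - start for start, end in self.blocks)


@dataclass(frozen=True)
class ReadSummary:
    n_reads: int
    mean_length: float
    median_length: float
    n50: int
    max_length: int
    mean_quality: float


def qc_filter(
    reads: Iterable[ReadRecord], cfg: QCConfig = QCConfig()
) -> tuple[list[ReadRecord], FilterReport]:
    """Keep reads with mean quality >= ``cfg.min_mean_quality``."""
    report = FilterReport()
    kept: list[ReadRecord] = []
    for read in reads:
        report.n_input += 1
        if read.mean_quality >= cfg.min_mean_quality:
            kept.append(read)
            report.n_kept += 1
        else:
            report.n_removed += 1
    return kept, report


def n50(lengths: Sequence[int]) -> int:
    """N50 read length.

    Ascending-cumulative convention (as in NanoStat-style long-read
    reporting): sort lengths ascending and return the first length at which
    the running base total reaches half of all bases.  For
    ``[500, 500, 1000]`` this yields 500.
    """
    if not lengths:
        raise ValueError("no reads")
    ordered = sorted(lengths)
    half = sum(ordered) / 2
    total = 0
    for value in ordered:
        total += value
        if total >= half:
            return value
    return ordered[-1]  # pragma: no cover - unreachable


def summarize_reads(reads: Sequence[ReadRecord]) -> ReadSummary:
    if not reads:
        raise ValueError("no reads")
    lengths = [read.length for read in reads]
    return ReadSummary(
        n_reads=len(reads),
        mean_length=statistics.fmean(lengths),
        median_length=float(statistics.median(lengths)),
        n50=n50(lengths),
        max_length=max(lengths),
        mean_quality=statistics.fmean(read.mean_quality for read in reads),
    )


def read_fastq(source: str | IO[str]) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` per FASTQ record (arithmetic-mean Phred)."""
    from Bio import SeqIO

    handle = open(source) if isinstance(source, str) else source
    try:
        for record in SeqIO.parse(handle, "fastq"):
            quals = record.letter_annotations["phred_quality"]
            yield ReadRecord(
                read_id=record.id,
                length=len(record.seq),
                mean_quality=statistics.fmean(quals) if quals else 0.0,
            )
    finally:
        if isinstance(source, str):
            handle.close()


def read_reads_tsv(source: str | IO[str]) -> Iterator[ReadRecord]:
    """Read the plain ``read_id length mean_quality`` table (header required)."""
    handle = open(source) if isinstance(source, str) else source
    try:
        header = next(handle).rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            yield ReadRecord(
                read_id=parts[idx["read_id"]],
                length=int(parts[idx["length"]]),
                mean_quality=float(parts[idx["mean_quality"]]),
            )
    finally:
        if isinstance(source, str):
            handle.close()


def _merge_blocks(
    blocks: list[tuple[int, int]], bridge_deletions: int = 0
) -> tuple[tuple[int, int], ...]:
    merged: list[tuple[int, int]] = []
    for start, end in blocks:
        if merged and start - merged[-1][1] <= bridge_deletions:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return tuple(merged)


def blocks_from_cigar(cigar: str, t_start: int, bridge_deletions: int = 0) -> tuple[tuple[int, int], ...]:
    """Walk a CIGAR string and return target-space match blocks.

    M/=/X consume target and open coverage; D/N consume target and split
    blocks (unless bridged); I/S/H/P consume no target.
    """
    blocks: list[tuple[int, int]] = []
    pos = t_start
    for count_str, op in _CIGAR_RE.findall(cigar):
        count = int(count_str)
        if op in "M=X":
            blocks.append((pos, pos + count))
            pos += count
        elif op in "DN":
            pos += count
    if not blocks:
        raise ValueError(f"CIGAR {cigar!r} has no target-consuming match operations")
    # adjacent M runs (e.g. around insertions) always merge; deletions merge
    # only when bridged
    return _merge_blocks(blocks, bridge_deletions=max(0, bridge_deletions))


def parse_paf(
    source: str | IO[str],
    known_targets: Iterable[str] | None = None,
    bridge_deletions: int = 0,
) -> tuple[list[TranscriptAlignment], FilterReport]:
    """Parse PAF rows into transcript-space alignments.

    With a ``cg:Z`` tag, blocks follow the CIGAR; without one, the alignment
    is a single block ``[t_start, t_end)`` with ``matches`` from column 10.
    Records flagged secondary (``tp:A:S``) are excluded; records whose target
    is absent from ``known_targets`` (when given) are dropped and counted.
    """
    known = set(known_targets) if known_targets is not None else None
    report = FilterReport()
    alignments: list[TranscriptAlignment] = []
    handle = open(source) if isinstance(source, str) else source
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            report.n_input += 1
            parts = line.split("\t")
            if len(parts) < 12:
                logger.warning("PAF line %d: fewer than 12 columns; dropped", lineno)
                report.n_removed += 1
                continue
            qname, tname = parts[0], parts[5]
            tags = parts[12:]
            if any(tag == "tp:A:S" for tag in tags):
                report.n_removed += 1
                continue
            try:
                t_len = int(parts[6])
                t_start, t_end = int(parts[7]), int(parts[8])
                matches = int(parts[9])
            except ValueError:
                logger.warning("PAF line %d: unparsable coordinates; dropped", lineno)
                report.n_removed += 1
                continue
            if t_start < 0 or t_end > t_len or t_end <= t_start:
                logger.warning("PAF line %d: coordinates out of range; dropped", lineno)
                report.n_removed += 1
                continue
            if known is not None and tname not in known:
                report.n_removed += 1
                continue
            cigar = next(
                (tag[5:] for tag in tags if tag.startswith("cg:Z:")), None
            )
            if cigar is not None:
                blocks = blocks_from_cigar(cigar, t_start, bridge_deletions)
            else:
                blocks = ((t_start, t_end),)
            alignments.append(
                TranscriptAlignment(
                    read_id=qname, transcript_id=tname, blocks=blocks, matches=matches
                )
            )
            report.n_kept += 1
    finally:
        if isinstance(source, str):
            handle.close()
    return alignments, report


_TSV_HEADER = ("read_id", "transcript_id", "t_len", "blocks", "matches")


def parse_alignment_tsv(
    source: str | IO[str],
    known_targets: Iterable[str] | None = None,
    bridge_deletions: int = 0,
) -> tuple[list[TranscriptAlignment], FilterReport]:
    """Parse the alignment-TSV dialect (see module docstring)."""
    known = set(known_targets) if known_targets is not None else None
    report = FilterReport()
    alignments: list[TranscriptAlignment] = []
    handle = open(source) if isinstance(source, str) else source
    try:
        header = next(handle).rstrip("\n").split("\t")
        if tuple(header) != _TSV_HEADER:
            raise ValueError(f"alignment-TSV header must be {_TSV_HEADER}, got {tuple(header)}")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            report.n_input += 1
            try:
                read_id, tname, t_len_str, blocks_str, matches_str = line.split("\t")
                t_len = int(t_len_str)
                blocks = tuple(
                    (int(s), int(e))
                    for s, e in (part.split("-") for part in blocks_str.split(";"))
                )
                matches = int(matches_str)
            except ValueError:
                logger.warning("alignment-TSV line %d: malformed; dropped", lineno)
                report.n_removed += 1
                continue
            if known is not None and tname not in known:
                report.n_removed += 1
                continue
            if any(s < 0 or e > t_len for s, e in blocks):
                logger.warning("alignment-TSV line %d: block outside transcript; dropped", lineno)
                report.n_removed += 1
                continue
            if bridge_deletions:
                blocks = _merge_blocks(list(blocks), bridge_deletions)
            alignments.append(
                TranscriptAlignment(
                    read_id=read_id, transcript_id=tname, blocks=blocks, matches=matches
                )
            )
            report.n_kept += 1
    finally:
        if isinstance(source, str):
            handle.close()
    return alignments, report


def write_alignment_tsv(
    alignments: Iterable[TranscriptAlignment],
    stream: IO[str],
    transcript_lengths: dict[str, int],
) -> None:
    stream.write("\t".join(_TSV_HEADER) + "\n")
    for aln in alignments:
        blocks_str = ";".join(f"{s}-{e}" for s, e in aln.blocks)
        stream.write(
            f"{aln.read_id}\t{aln.transcript_id}\t"
            f"{transcript_lengths[aln.transcript_id]}\t{blocks_str}\t{aln.matches}\n"
        )


def select_primary(alignments: Sequence[TranscriptAlignment]) -> TranscriptAlignment:
    """Pick one alignment per read: max matches, then longest span, then
    lexicographically smallest transcript_id."""
    if not alignments:
        raise ValueError("select_primary needs at least one alignment")
    return min(alignments, key=lambda a: (-a.matches, -a.span, a.transcript_id))


def group_by_read(
    alignments: Iterable[TranscriptAlignment],
) -> dict[str, list[TranscriptAlignment]]:
    grouped: dict[str, list[TranscriptAlignment]] = {}
    for aln in alignments:
        grouped.setdefault(aln.read_id, []).append(aln)
    return grouped


def primary_alignments(
    alignments: Iterable[TranscriptAlignment],
) -> dict[str, TranscriptAlignment]:
    """One primary alignment per read (deterministic tie-breaking)."""
    return {rid: select_primary(cands) for rid, cands in group_by_read(alignments).items()}
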