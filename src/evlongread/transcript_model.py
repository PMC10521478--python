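"""Reference transcript structures and strand-aware coordinate conversion.

A :class:`TranscriptModel` is the coordinate authority for every downstream
classification step: integrity and degradation calls are made in *transcript*
space, where position 0 is the 5' end of the mature transcript regardless of
genomic strand.  For minus-strand transcripts the 5'-most base is therefore
the exon base with the *largest* genomic coordinate.

All coordinates are 0-based, half-open.  1-based conventions appear only at
I/O boundaries (GTF).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

#: Closed biotype vocabulary used throughout composition reporting.  Labels
#: outside this set collapse to ``"other"`` (with a warning) so that
#: composition tables always have a stable row set.
KNOWN_BIOTYPES: tuple[str, ...] = (
    "protein_coding",
    "retained_intron",
    "lncRNA",
    "nonsense_mediated_decay",
    "processed_transcript",
    "misc_RNA",
    "rRNA",
    "other",
)

_KNOWN_BIOTYPE_SET = frozenset(KNOWN_BIOTYPES)


def normalize_biotype(label: str | None) -> str:
    """Map a biotype label into the closed vocabulary.

    Missing labels map silently to ``"other"``; unknown labels map to
    ``"other"`` with a warning so annotation problems stay visible.
    """
    if label is None or label == "":
        return "other"
    if label in _KNOWN_BIOTYPE_SET:
        return label
    logger.warning("unknown biotype %r mapped to 'other'", label)
    return "other"


class AnnotationError(ValueError):
    """Raised for unrecoverable annotation problems (duplicates, empty catalog)."""


@dataclass(frozen=True)
class TranscriptModel:
    """One reference transcript: exon structure, biotype and length.

    ``exons`` are genomic intervals (0-based half-open), non-overlapping and
    sorted by genomic start.  ``length`` is the mature transcript length,
    i.e. the sum of exon widths.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    strand: str
    chrom: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: empty/inverted exon [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def exons_5to3(self) -> tuple[tuple[int, int], ...]:
        """Exons ordered along the transcript (5' -> 3')."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))


def genome_to_transcript(
    model: TranscriptModel, g_start: int, g_end: int
) -> tuple[int, int] | None:
    """Project a genomic interval onto transcript coordinates.

    Returns the transcript-space interval (0-based half-open, position 0 at
    the transcript 5' end) spanned by the exonic portion of
    ``[g_start, g_end)``, or ``None`` when the query does not touch any exon.
    The exonic projection of a single genomic interval is always contiguous
    in transcript space (skipped bases are intronic).
    """
    if g_end <= g_start:
        return None
    lo: int | None = None
    hi: int | None = None
    offset = 0
    for start, end in model.exons_5to3:
        width = end - start
        ov_start = max(start, g_start)
        ov_end = min(end, g_end)
        if ov_start < ov_end:
            if model.strand == "+":
                t0 = offset + (ov_start - start)
                t1 = offset + (ov_end - start)
            else:
                t0 = offset + (end - ov_end)
                t1 = offset + (end - ov_start)
            lo = t0 if lo is None else min(lo, t0)
            hi = t1 if hi is None else max(hi, t1)
        offset += width
    if lo is None:
        return None
    return (lo, hi)


@dataclass
class LoadReport:
    """Bookkeeping for :func:`load_annotation`."""

    n_transcripts: int = 0
    n_skipped_records: int = 0
    rejected_sequence_mismatch: list[str] = field(default_factory=list)


@dataclass
class TranscriptCatalog:
    """All reference transcripts, indexed by transcript and by gene."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)
    report: LoadReport = field(default_factory=LoadReport)

    _gene_index: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def add(self, model: TranscriptModel) -> None:
        if model.transcript_id in self.transcripts:
            raise AnnotationError(f"duplicate transcript_id {model.transcript_id!r}")
        self.transcripts[model.transcript_id] = model
        self._gene_index.setdefault(model.gene_id, set()).add(model.transcript_id)

    @property
    def gene_index(self) -> Mapping[str, set[str]]:
        return self._gene_index

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __len__(self) -> int:
        return len(self.transcripts)

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id

    def length_of(self, transcript_id: str) -> int:
        return self.transcripts[transcript_id].length

    def write_gtf(self, stream: IO[str]) -> None:
        """Write the catalog in Ensembl-dialect GTF (exon features only)."""
        for model in self.transcripts.values():
            for i, (start, end) in enumerate(model.exons_5to3, start=1):
                attrs = (
                    f'gene_id "{model.gene_id}"; '
                    f'transcript_id "{model.transcript_id}"; '
                    f'exon_number "{i}"; '
                    f'transcript_biotype "{model.biotype}";'
                )
                stream.write(
                    "\t".join(
                        (
                            model.chrom,
                            "evlongread",
                            "exon",
                            str(start + 1),
                            str(end),
                            ".",
                            model.strand,
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )


def _as_text_lines(source: str | IO[str]) -> Iterator[str]:
    if isinstance(source, str):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def _first_attr(feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            values = feature.attributes[key]
            if values:
                return values[0]
    return None


def load_annotation(
    annotation: str | IO[str],
    sequences: str | IO[str] | None = None,
) -> TranscriptCatalog:
    """Build a :class:`TranscriptCatalog` from Ensembl-dialect GTF text.

    Only ``exon`` features are consumed; each needs ``transcript_id`` and
    ``gene_id`` attributes (``transcript_biotype``/``gene_biotype`` optional,
    defaulting to ``"other"``).  A ``transcript_id`` that reappears with a
    conflicting gene, strand or chromosome, or with overlapping exons, is a
    hard error.  Malformed records are skipped and logged.

    When a transcript FASTA is supplied (records keyed by transcript_id),
    each sequence length must equal the exonic length of its model; mismatches
    reject the transcript with a report entry.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene, strand, chrom, biotype)
    report = LoadReport()

    for lineno, line in enumerate(_as_text_lines(annotation), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) < 9:
            logger.warning("skipping malformed GTF line %d (needs 9 fields)", lineno)
            report.n_skipped_records += 1
            continue
        try:
            feature = feature_from_line(line)
        except Exception:
            logger.warning("skipping malformed GTF line %d", lineno)
            report.n_skipped_records += 1
            continue
        if feature.featuretype != "exon":
            continue
        tid = _first_attr(feature, "transcript_id")
        gid = _first_attr(feature, "gene_id")
        if tid is None or gid is None:
            logger.warning("skipping exon without transcript_id/gene_id at line %d", lineno)
            report.n_skipped_records += 1
            continue
        biotype = normalize_biotype(
            _first_attr(feature, "transcript_biotype", "gene_biotype", "biotype")
        )
        key = (gid, feature.strand, feature.seqid, biotype)
        if tid in meta and meta[tid] != key:
            raise AnnotationError(f"duplicate transcript_id {tid!r} with conflicting definition")
        meta[tid] = key
        exons.setdefault(tid, []).append((feature.start - 1, feature.end))

    catalog = TranscriptCatalog(report=report)
    for tid, exon_list in exons.items():
        gid, strand, chrom, biotype = meta[tid]
        exon_list.sort()
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            biotype=biotype,
            strand=strand,
            chrom=chrom,
            exons=tuple(exon_list),
        )
        catalog.add(model)

    if sequences is not None:
        from Bio import SeqIO

        handle = open(sequences) if isinstance(sequences, str) else sequences
        try:
            for record in SeqIO.parse(handle, "fasta"):
                tid = record.id
                if tid not in catalog.transcripts:
                    continue
                seq = str(record.seq)
                if len(seq) != catalog.transcripts[tid].length:
                    logger.warning(
                        "transcript %s: sequence length %d != model length %d; rejected",
                        tid,
                        len(seq),
                        catalog.transcripts[tid].length,
                    )
                    report.rejected_sequence_mismatch.append(tid)
                    model = catalog.transcripts.pop(tid)
                    catalog._gene_index[model.gene_id].discard(tid)
                    if not catalog._gene_index[model.gene_id]:
                        del catalog._gene_index[model.gene_id]
                    continue
                catalog.sequences[tid] = seq
        finally:
            if isinstance(sequences, str):
                handle.close()

    if not catalog.transcripts:
        raise AnnotationError("empty transcript catalog")
    report.n_transcripts = len(catalog.transcripts)
    return catalog


def catalog_from_models(models: Iterable[TranscriptModel]) -> TranscriptCatalog:
    """Assemble a catalog from in-memory models (simulator entry point)."""
    catalog = TranscriptCatalog()
    for model in models:
        catalog.add(model)
    if not catalog.transcripts:
        raise AnnotationError("empty transcript catalog")
    catalog.report.n_transcripts = len(catalog.transcripts)
    return catalog
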