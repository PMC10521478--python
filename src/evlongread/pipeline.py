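"""End-to-end pipeline: configuration, orchestration and report assembly.

``run_pipeline`` consumes a transcript annotation, per-sample transcript-space
alignments (PAF or alignment-TSV) and a sample sheet, and writes the report
bundle: per-sample read summaries, dual biotype composition tables, the
inter-sample correlation matrix, intrinsic/group-specific gene reports,
intact/fragmented and degradation-direction summaries, and a stats block.
Outputs are deterministic for fixed inputs and all carry the configuration
hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import abundance as ab
from . import degradation as dg
from . import integrity as it
from . import read_ingest as ri
from . import stats as st
from .transcript_model import TranscriptCatalog, load_annotation

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "read_summary.tsv",
    "composition.tsv",
    "correlation_matrix.tsv",
    "gene_report.json",
    "integrity_summary.json",
    "degradation_summary.json",
    "stats.json",
)


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2)."""


class EmptyDataError(RuntimeError):
    """No reads survive ingestion/QC (exit code 3)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 4); names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    annotation: str
    sample_sheet: str
    out_dir: str
    fasta: str | None = None
    qc: ri.QCConfig = field(default_factory=ri.QCConfig)
    integrity: it.IntegrityConfig = field(default_factory=it.IntegrityConfig)
    degradation: dg.DegradationConfig = field(default_factory=dg.DegradationConfig)
    abundance_mode: str = "primary_only"
    correlation_transform: str = "log1p10"
    top_n: int | None = None
    ambiguous_as: str | None = None
    bridge_deletions: int = 0
    length_bin_width: int = 200
    length_overflow_at: int = 2000

    def validate(self) -> None:
        if self.abundance_mode not in ("primary_only", "em"):
            raise ConfigError(f"unknown abundance_mode {self.abundance_mode!r}")
        if self.correlation_transform not in ("log1p10", "none"):
            raise ConfigError(
                f"unknown correlation_transform {self.correlation_transform!r}"
            )
        for label, path in (
            ("annotation", self.annotation),
            ("sample_sheet", self.sample_sheet),
            ("fasta", self.fasta),
        ):
            if path is not None and not Path(path).is_file():
                raise ConfigError(f"{label} path does not exist: {path}")

    def scientific_params(self) -> dict:
        """Parameters that define the analysis (paths excluded) — hashed into
        every output so reports are traceable to their settings."""
        return {
            "min_mean_quality": self.qc.min_mean_quality,
            "intact_threshold": self.integrity.intact_threshold,
            "end_tolerance_fraction": self.degradation.end_tolerance_fraction,
            "end_tolerance_min": self.degradation.end_tolerance_min,
            "abundance_mode": self.abundance_mode,
            "correlation_transform": self.correlation_transform,
            "top_n": self.top_n,
            "ambiguous_as": self.ambiguous_as,
            "bridge_deletions": self.bridge_deletions,
            "length_bin_width": self.length_bin_width,
            "length_overflow_at": self.length_overflow_at,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.scientific_params(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            qc = ri.QCConfig(**raw.pop("qc", {}))
            integ = it.IntegrityConfig(**raw.pop("integrity", {}))
            degr = dg.DegradationConfig(**raw.pop("degradation", {}))
            cfg = cls(qc=qc, integrity=integ, degradation=degr, **raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        return cfg


@dataclass
class SampleData:
    sample_id: str
    group: str
    profile: ab.SampleProfile
    qc_report: ri.FilterReport
    read_lengths: list[int]
    integrity_calls: list[it.IntegrityCall]
    degradation_calls: list[dg.DegradationCall]


@dataclass
class PipelineResult:
    out_dir: Path
    samples: list[SampleData]
    config_hash: str


def _read_sample_sheet(path: str) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group", "alignments"):
        if col not in sheet.columns:
            raise ConfigError(f"sample sheet missing column {col!r}")
    if sheet["sample_id"].duplicated().any():
        raise ConfigError("sample sheet has duplicate sample_id entries")
    return sheet


def _ingest_sample(
    row: Mapping[str, str],
    sheet_dir: Path,
    catalog: TranscriptCatalog,
    config: PipelineConfig,
) -> SampleData:
    sample_id, group = row["sample_id"], row["group"]
    aln_path = sheet_dir / row["alignments"]
    reads_path = (
        sheet_dir / row["reads"]
        if "reads" in row and isinstance(row["reads"], str)
        else None
    )

    if reads_path is not None:
        reader = (
            ri.read_fastq if reads_path.suffix in (".fastq", ".fq") else ri.read_reads_tsv
        )
        kept_reads, qc_report = ri.qc_filter(reader(str(reads_path)), config.qc)
        kept_ids: set[str] | None = {r.read_id for r in kept_reads}
    else:
        kept_reads, qc_report = [], ri.FilterReport()
        kept_ids = None

    parser = ri.parse_paf if aln_path.suffix == ".paf" else ri.parse_alignment_tsv
    alignments, _ = parser(
        str(aln_path),
        known_targets=catalog.transcripts.keys(),
        bridge_deletions=config.bridge_deletions,
    )
    if kept_ids is not None:
        alignments = [a for a in alignments if a.read_id in kept_ids]
    grouped = ri.group_by_read(alignments)
    primaries = {rid: ri.select_primary(cands) for rid, cands in grouped.items()}

    if kept_ids is None:
        # no per-read FASTQ/TSV: fall back to aligned-base lengths, no quality
        kept_reads = [
            ri.ReadRecord(rid, aln.aligned_bases, float("nan"))
            for rid, aln in primaries.items()
        ]
        qc_report = ri.FilterReport(len(kept_reads), len(kept_reads), 0)

    em = ab.em_assign(grouped, mode=config.abundance_mode)
    summary = ri.summarize_reads(kept_reads) if kept_reads else None
    profile = ab.SampleProfile(sample_id, group, em.counts, read_summary=summary)

    integrity_calls = it.call_integrity(primaries, catalog, config.integrity)
    fragmented = {
        c.read_id: primaries[c.read_id]
        for c in integrity_calls
        if c.label == it.FRAGMENTED
    }
    lengths = {tid: catalog.length_of(tid) for tid in {a.transcript_id for a in fragmented.values()}}
    degradation_calls = dg.call_directions(fragmented, lengths, config.degradation)
    return SampleData(
        sample_id=sample_id,
        group=group,
        profile=profile,
        qc_report=qc_report,
        read_lengths=[r.length for r in kept_reads],
        integrity_calls=integrity_calls,
        degradation_calls=degradation_calls,
    )


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_tsv(path: Path, frame: pd.DataFrame, config_hash: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    chash = config.config_hash()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        catalog = load_annotation(config.annotation, config.fasta)
    except Exception as exc:
        raise StageError("load_annotation", exc) from exc

    sheet = _read_sample_sheet(config.sample_sheet)
    sheet_dir = Path(config.sample_sheet).parent

    samples: list[SampleData] = []
    try:
        for _, row in sheet.iterrows():
            samples.append(_ingest_sample(row, sheet_dir, catalog, config))
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError("ingest", exc) from exc

    if all(not s.integrity_calls for s in samples):
        raise EmptyDataError("no reads survived QC and alignment ingestion")

    try:
        _write_reports(samples, catalog, config, out_dir, chash)
    except Exception as exc:
        raise StageError("report", exc) from exc
    return PipelineResult(out_dir, samples, chash)


def _write_reports(
    samples: list[SampleData],
    catalog: TranscriptCatalog,
    config: PipelineConfig,
    out_dir: Path,
    chash: str,
) -> None:
    # per-read call tables
    for s in samples:
        calls = pd.DataFrame(
            [
                (c.read_id, c.transcript_id, c.coverage_rate, c.label)
                for c in s.integrity_calls
            ],
            columns=["read_id", "transcript_id", "coverage_rate", "label"],
        )
        _write_tsv(out_dir / f"{s.sample_id}.integrity_calls.tsv", calls, chash, False)
        dcalls = pd.DataFrame(
            [
                (c.read_id, c.transcript_id, c.direction, c.covers_5prime, c.covers_3prime)
                for c in s.degradation_calls
            ],
            columns=["read_id", "transcript_id", "direction", "covers_5prime", "covers_3prime"],
        )
        _write_tsv(out_dir / f"{s.sample_id}.degradation_calls.tsv", dcalls, chash, False)

    # read summaries
    rows = []
    for s in samples:
        summ = s.profile.read_summary
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "n_input_reads": s.qc_report.n_input,
                "n_qc_removed": s.qc_report.n_removed,
                "n_reads": summ.n_reads if summ else 0,
                "mean_length": summ.mean_length if summ else float("nan"),
                "median_length": summ.median_length if summ else float("nan"),
                "n50": summ.n50 if summ else 0,
                "max_length": summ.max_length if summ else 0,
                "mean_quality": summ.mean_quality if summ else float("nan"),
            }
        )
    _write_tsv(out_dir / "read_summary.tsv", pd.DataFrame(rows), chash, False)

    # composition
    comp_frames = []
    for s in samples:
        table = ab.composition(s.profile, catalog).reset_index()
        table.insert(0, "sample_id", s.sample_id)
        comp_frames.append(table)
    _write_tsv(
        out_dir / "composition.tsv", pd.concat(comp_frames, ignore_index=True), chash, False
    )

    # correlation
    profiles = [s.profile for s in samples]
    corr = ab.correlation_matrix(
        profiles, top_n=config.top_n, transform=config.correlation_transform
    )
    _write_tsv(out_dir / "correlation_matrix.tsv", corr, chash, True)

    # gene-level report
    intrinsic = ab.intrinsic_genes(profiles, catalog)
    group_sets = ab.group_specific_sets(profiles, catalog)
    machinery = ab.flag_degradation_machinery(profiles, catalog)
    gene_report = {
        "config_hash": chash,
        "intrinsic": {
            "n_intrinsic": len(intrinsic.intrinsic_genes),
            "n_union": len(intrinsic.all_genes),
            "proportion": intrinsic.proportion,
            "proportion_denominator": "union_of_detected_genes",
            "table": list(map(list, intrinsic.table)) if intrinsic.table else None,
            "chi_square": intrinsic.test.as_dict() if intrinsic.test else None,
            "notice": intrinsic.notice,
        },
        "group_specific": {
            group: {
                "n_transcripts": len(group_sets.unique_transcripts[group]),
                "n_genes": len(group_sets.unique_genes[group]),
                "transcripts": sorted(group_sets.unique_transcripts[group]),
                "genes": sorted(group_sets.unique_genes[group]),
            }
            for group in group_sets.groups
        },
        "shared": {
            "n_transcripts": len(group_sets.shared_transcripts),
            "n_genes": len(group_sets.shared_genes),
        },
        "degradation_machinery": {
            gene: {sample: bool(machinery.loc[gene, sample]) for sample in machinery.columns}
            for gene in machinery.index
        },
    }
    _write_json(out_dir / "gene_report.json", gene_report)

    # integrity summary
    calls_by_sample = {s.sample_id: s.integrity_calls for s in samples}
    groups_of = {s.sample_id: s.group for s in samples}
    comparison = it.intact_proportion_comparison(calls_by_sample, groups_of)
    integrity_summary = {
        "config_hash": chash,
        "intact_threshold": config.integrity.intact_threshold,
        "per_sample": {
            s.sample_id: {
                "n_reads": len(s.integrity_calls),
                "intact_proportion_read_weighted": comparison.proportions.get(s.sample_id),
                "intact_proportion_transcript_weighted": (
                    it.transcript_weighted_intact_proportion(
                        s.integrity_calls, config.integrity
                    )
                    if s.integrity_calls
                    else None
                ),
            }
            for s in samples
        },
        "group_means": comparison.group_means,
        "overall_intact_proportion": (
            it.intact_proportion([c for s in samples for c in s.integrity_calls])
        ),
        "welch_t": comparison.test.as_dict() if comparison.test else None,
        "excluded_samples": comparison.excluded_samples,
        "notice": comparison.notice,
    }
    _write_json(out_dir / "integrity_summary.json", integrity_summary)

    # degradation summary + coverage-by-direction histogram
    per_sample_dir = {}
    for s in samples:
        if s.degradation_calls:
            summary = dg.direction_proportions(s.degradation_calls, config.ambiguous_as)
            per_sample_dir[s.sample_id] = summary.as_dict()
        else:
            per_sample_dir[s.sample_id] = None
    all_dcalls = [c for s in samples for c in s.degradation_calls]
    overall = dg.direction_proportions(all_dcalls, config.ambiguous_as) if all_dcalls else None
    by_group = {}
    for group in sorted({s.group for s in samples}):
        gcalls = [c for s in samples if s.group == group for c in s.degradation_calls]
        by_group[group] = (
            dg.direction_proportions(gcalls, config.ambiguous_as).as_dict() if gcalls else None
        )
    degradation_summary = {
        "config_hash": chash,
        "end_tolerance_fraction": config.degradation.end_tolerance_fraction,
        "end_tolerance_min": config.degradation.end_tolerance_min,
        "ambiguous_as": config.ambiguous_as,
        "per_sample": per_sample_dir,
        "per_group": by_group,
        "overall": overall.as_dict() if overall else None,
    }
    _write_json(out_dir / "degradation_summary.json", degradation_summary)

    all_icalls = [c for s in samples for c in s.integrity_calls]
    hist = dg.coverage_by_direction(all_icalls, all_dcalls)
    _write_tsv(out_dir / "coverage_by_direction.tsv", hist, chash, True)

    # stats block
    stats_block: dict = {"config_hash": chash}
    anova_rows = []
    for s in samples:
        if not s.read_lengths:
            continue
        props = st.bin_lengths(
            s.read_lengths, config.length_bin_width, config.length_overflow_at
        )
        for bin_label, value in props.items():
            anova_rows.append(
                {"sample": s.sample_id, "group": s.group, "bin": bin_label, "value": value}
            )
    try:
        anova = st.two_way_anova_lengths(pd.DataFrame(anova_rows))
        stats_block["length_distribution_anova"] = anova.as_dict()
    except ValueError as exc:
        stats_block["length_distribution_anova"] = {"notice": str(exc)}
    stats_block["intact_proportion_welch_t"] = (
        comparison.test.as_dict() if comparison.test else {"notice": comparison.notice}
    )
    stats_block["intrinsic_chi_square"] = (
        intrinsic.test.as_dict() if intrinsic.test else {"notice": intrinsic.notice}
    )
    _write_json(out_dir / "stats.json", stats_block)
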