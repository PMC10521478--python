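"""Synthetic transcript catalogs and degraded long-read populations.

The generator emulates the data regime of a nanopore direct-cDNA survey of
extracellular-vesicle RNA: short-ish reads (mean a few hundred nt) drawn
from a biotype mixture dominated by protein-coding transcripts, with roughly
a 30/70 intact/fragmented split and a three-way degradation-direction
mixture of about 43% 3'→5', 34% endo and 23% 5'→3'.  Every read carries a
ground-truth record (intact flag, direction, pre-jitter retained interval),
so each pipeline stage can be scored against truth offline.

Reads are emitted directly as transcript-space alignment records (the
alignment-TSV dialect of :mod:`.read_ingest`) — no external aligner is
needed; FASTQ emission exists for end-to-end runs with a real aligner.

Everything is deterministic given the seed, with an independent stream per
sample keyed on (sample_id, seed) so adding a sample never perturbs others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .transcript_model import TranscriptCatalog, TranscriptModel, catalog_from_models

DEFAULT_BIOTYPE_PROBS: dict[str, float] = {
    "protein_coding": 0.65,
    "retained_intron": 0.12,
    "lncRNA": 0.08,
    "nonsense_mediated_decay": 0.05,
    "processed_transcript": 0.04,
    "misc_RNA": 0.03,
    "rRNA": 0.03,
}

#: Gene symbols assigned to the first few simulated genes so that the
#: degradation-machinery presence screen has something to find.
DEFAULT_MACHINERY_GENES = ("SMG5", "PARN", "CNOT1", "LSM1", "LSM3", "LSM7")


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible generator stream keyed on (label, seed)."""
    return np.random.default_rng([zlib.crc32(label.encode()), seed])


@dataclass
class SimConfig:
    """Generation parameters; the defaults *are* the emulated study regime."""

    # catalog
    n_transcripts: int = 300
    length_log_mean: float = 6.2
    length_log_sd: float = 0.8
    length_min: int = 200
    length_max: int = 32_000
    biotype_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_PROBS)
    )
    exon_poisson_rate: float = 4.0  # exons per transcript = 1 + Poisson(rate)
    shared_gene_prob: float = 0.3  # chance a transcript joins the previous gene
    machinery_genes: tuple[str, ...] = DEFAULT_MACHINERY_GENES

    # read population
    n_reads: int = 5000
    p_intact: float = 0.3066
    direction_weights: tuple[float, float, float] = (0.4266, 0.3447, 0.2288)
    f_min: float = 0.05
    f_max: float = 0.89
    boundary_jitter_sd: float = 0.0
    #: "tolerance": every lost terminus loses strictly more than the
    #: classifier's end tolerance, so generated direction labels are
    #: recoverable; "minimal": lost termini lose >= 1 nt only.
    cut_margin_mode: str = "tolerance"
    end_tolerance_fraction: float = 0.10
    end_tolerance_min: int = 20

    # read quality (post-basecall regime; a small low-quality tail exercises QC)
    quality_mean: float = 11.8
    quality_sd: float = 1.0
    low_quality_fraction: float = 0.02
    low_quality_mean: float = 5.5
    low_quality_sd: float = 0.7

    # abundance model
    abundance_log_sd: float = 1.0
    group_exclusive_fraction: float = 0.05
    sample_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"Exo": 0.15, "MV": 0.5}
    )
    p_intact_by_group: dict[str, float] = field(
        default_factory=lambda: {"Exo": 0.3566, "MV": 0.2566}
    )

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        total = sum(self.biotype_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biotype_probs must sum to 1, got {total}")
        total_w = sum(self.direction_weights)
        if abs(total_w - 1.0) > 1e-3:
            raise ValueError("direction_weights must sum to 1")
        # renormalize away printed-precision slack (e.g. percentages quoted
        # to 2 dp summing to 100.01)
        self.direction_weights = tuple(w / total_w for w in self.direction_weights)
        if not 0 <= self.p_intact <= 1:
            raise ValueError("p_intact must be in [0, 1]")
        if not 0 < self.f_min < self.f_max < 0.90:
            raise ValueError("need 0 < f_min < f_max < intact threshold (0.90)")
        if self.cut_margin_mode not in ("tolerance", "minimal"):
            raise ValueError("cut_margin_mode must be 'tolerance' or 'minimal'")
        if self.length_min < 10 or self.length_max <= self.length_min:
            raise ValueError("bad length truncation bounds")

    def as_dict(self) -> dict:
        return asdict(self)


def simulate_catalog(
    cfg: SimConfig, rng: np.random.Generator
) -> TranscriptCatalog:
    """Deterministic synthetic transcript catalog (with sequences).

    Transcript lengths are log-normal truncated to
    ``[length_min, length_max]``; exon structures tile each transcript;
    genomic placements are laid out consecutively with random intron/gap
    sizes; strands are random.  A fraction of transcripts share a gene with
    their predecessor, giving genes with several isoforms.
    """
    n = cfg.n_transcripts
    lengths = np.zeros(n, dtype=np.int64)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.lognormal(cfg.length_log_mean, cfg.length_log_sd, remaining.size)
        ok = (draw >= cfg.length_min) & (draw <= cfg.length_max)
        lengths[remaining[ok]] = draw[ok].astype(np.int64)
        remaining = remaining[~ok]

    biotype_labels = list(cfg.biotype_probs)
    probs = np.array([cfg.biotype_probs[b] for b in biotype_labels])
    biotypes = rng.choice(len(biotype_labels), size=n, p=probs)
    n_exons = 1 + rng.poisson(cfg.exon_poisson_rate, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    share_prev = rng.random(n) < cfg.shared_gene_prob

    gene_ids: list[str] = []
    gene_counter = 0
    for i in range(n):
        if i > 0 and share_prev[i]:
            gene_ids.append(gene_ids[-1])
        else:
            gene_counter += 1
            if gene_counter <= len(cfg.machinery_genes):
                gene_ids.append(cfg.machinery_genes[gene_counter - 1])
            else:
                gene_ids.append(f"GENE{gene_counter:05d}")

    models = []
    cursors = {f"chr{c}": 0 for c in (1, 2, 3)}
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    for i in range(n):
        length = int(lengths[i])
        k = min(int(n_exons[i]), length)  # every exon >= 1 nt
        if k > 1:
            cuts = np.sort(rng.choice(length - 1, size=k - 1, replace=False) + 1)
        else:
            cuts = np.array([], dtype=np.int64)
        widths = np.diff(np.concatenate(([0], cuts, [length])))
        chrom = f"chr{1 + i % 3}"
        start = cursors[chrom] + int(rng.integers(100, 2000))
        exons = []
        pos = start
        for j, width in enumerate(widths):
            exons.append((pos, pos + int(width)))
            pos += int(width)
            if j < len(widths) - 1:
                pos += int(rng.integers(50, 2001))  # intron
        cursors[chrom] = pos
        tid = f"TX{i + 1:05d}"
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_ids[i],
                biotype=biotype_labels[int(biotypes[i])],
                strand=str(strands[i]),
                chrom=chrom,
                exons=tuple(exons),
            )
        )
        sequences[tid] = "".join(
            bases[rng.integers(0, 4, size=length)]
        )
    catalog = catalog_from_models(models)
    catalog.sequences = sequences
    return catalog


@dataclass
class SampleSim:
    """One simulated sample: emitted reads/alignments plus generative truth."""

    sample_id: str
    group: str
    reads: pd.DataFrame  # read_id, length, mean_quality
    alignments: pd.DataFrame  # read_id, transcript_id, t_len, t_start, t_end, matches
    truth: pd.DataFrame  # read_id, transcript_id, is_intact, direction, keep_start, keep_end


def _population_weights(
    catalog: TranscriptCatalog, cfg: SimConfig, seed: int, group: str
) -> np.ndarray:
    """Group-level expected abundances (shared across samples of a run).

    Drawn from a dedicated stream keyed on the seed only, so every sample of
    a study sees the same population; a ``group_exclusive_fraction`` of
    transcripts is zeroed in the *other* group, producing group-specific
    transcript sets."""
    n = len(catalog)
    rng = _stream(seed, "abundance")
    base = rng.lognormal(0.0, cfg.abundance_log_sd, n)
    k = int(round(cfg.group_exclusive_fraction * n))
    perm = rng.permutation(n)
    exclusive = {"Exo": perm[:k], "MV": perm[k : 2 * k]}
    weights = base.copy()
    for other, idx in exclusive.items():
        if other != group:
            weights[idx] = 0.0
    return weights


def simulate_sample(
    catalog: TranscriptCatalog,
    cfg: SimConfig,
    sample_id: str,
    group: str = "Exo",
    seed: int = 0,
    p_intact: float | None = None,
) -> SampleSim:
    """Generate one sample's degraded read population with ground truth.

    Per read: a transcript is drawn proportional to abundance; with
    probability ``p_intact`` the read is full-length, otherwise a direction
    is drawn from ``direction_weights`` and a retained fraction
    f ~ U(f_min, f_max) decides the kept interval — ``deg_3to5`` keeps
    ``[0, f·L)``, ``deg_5to3`` keeps ``[(1−f)·L, L)``, ``endo`` keeps an
    internal window losing both termini.  In the default
    ``cut_margin_mode="tolerance"`` every lost terminus loses strictly more
    than the classifier's end tolerance δ, so generated labels are exactly
    recoverable; optional Gaussian jitter perturbs the emitted alignment
    ends while truth records the pre-jitter interval.
    """
    rng = _stream(seed, sample_id)
    n = cfg.n_reads
    if p_intact is None:
        p_intact = cfg.p_intact_by_group.get(group, cfg.p_intact)

    tids = np.array(sorted(catalog.transcripts))
    lengths_by_tid = np.array([catalog.length_of(t) for t in tids], dtype=np.int64)
    weights = _population_weights(catalog, cfg, seed, group)
    noise_sd = cfg.sample_noise_sd.get(group, 0.3)
    weights = weights * rng.lognormal(0.0, noise_sd, len(tids))
    if weights.sum() <= 0:
        raise ValueError("degenerate abundance weights")
    probs = weights / weights.sum()

    idx = rng.choice(len(tids), size=n, p=probs)
    L = lengths_by_tid[idx]
    intact = rng.random(n) < p_intact
    direction = np.full(n, "intact", dtype=object)
    n_frag = int((~intact).sum())
    dir_draw = rng.choice(3, size=n_frag, p=np.asarray(cfg.direction_weights))

    if cfg.cut_margin_mode == "tolerance":
        margin = np.floor(
            np.maximum(cfg.end_tolerance_min, cfg.end_tolerance_fraction * L)
        ).astype(np.int64) + 1
    else:
        margin = np.ones(n, dtype=np.int64)

    keep_start = np.zeros(n, dtype=np.int64)
    keep_end = L.copy()

    frag_idx = np.flatnonzero(~intact)
    Lf = L[frag_idx]
    mf = margin[frag_idx]

    # end-anchored fragments: keep length from f ~ U(f_min, f_max)
    f = rng.uniform(cfg.f_min, cfg.f_max, n_frag)
    keep_len = np.clip(np.rint(f * Lf).astype(np.int64), 1, Lf - mf)
    # endodegraded fragments lose both termini: cap the retained fraction and
    # place the window uniformly between the margins
    endo_mask = dir_draw == 1
    cap = (Lf - 2 * mf) / Lf
    f_endo = cfg.f_min + rng.uniform(0.0, 1.0, n_frag) * (
        np.minimum(cfg.f_max, cap) - cfg.f_min
    )
    keep_len = np.where(
        endo_mask,
        np.clip(np.rint(f_endo * Lf).astype(np.int64), 1, Lf - 2 * mf),
        keep_len,
    )
    start = np.zeros(n_frag, dtype=np.int64)
    start[endo_mask] = rng.integers(
        mf[endo_mask], Lf[endo_mask] - keep_len[endo_mask] - mf[endo_mask] + 1
    )
    mask_5to3 = dir_draw == 2
    start[mask_5to3] = Lf[mask_5to3] - keep_len[mask_5to3]

    keep_start[frag_idx] = start
    keep_end[frag_idx] = start + keep_len
    direction[frag_idx] = np.array(["deg_3to5", "endo", "deg_5to3"], dtype=object)[
        dir_draw
    ]

    emit_start, emit_end = keep_start, keep_end
    if cfg.boundary_jitter_sd > 0:
        emit_start = np.clip(
            np.rint(keep_start + rng.normal(0, cfg.boundary_jitter_sd, n)).astype(
                np.int64
            ),
            0,
            L - 1,
        )
        emit_end = np.clip(
            np.rint(keep_end + rng.normal(0, cfg.boundary_jitter_sd, n)).astype(
                np.int64
            ),
            emit_start + 1,
            L,
        )

    lowq = rng.random(n) < cfg.low_quality_fraction
    quality = np.where(
        lowq,
        rng.normal(cfg.low_quality_mean, cfg.low_quality_sd, n),
        rng.normal(cfg.quality_mean, cfg.quality_sd, n),
    )
    quality = np.round(np.maximum(quality, 1.0), 2)

    read_ids = np.array([f"{sample_id}_r{i:06d}" for i in range(n)])
    width = emit_end - emit_start
    reads = pd.DataFrame(
        {"read_id": read_ids, "length": width, "mean_quality": quality}
    )
    alignments = pd.DataFrame(
        {
            "read_id": read_ids,
            "transcript_id": tids[idx],
            "t_len": L,
            "t_start": emit_start,
            "t_end": emit_end,
            "matches": width,
        }
    )
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "transcript_id": tids[idx],
            "is_intact": intact,
            "direction": direction,
            "keep_start": keep_start,
            "keep_end": keep_end,
            "sample_id": sample_id,
        }
    )
    return SampleSim(sample_id, group, reads, alignments, truth)


def write_alignments_tsv(sim: SampleSim, stream: IO[str]) -> None:
    """Emit a sample's alignments in the alignment-TSV dialect."""
    df = sim.alignments
    blocks = df["t_start"].astype(str) + "-" + df["t_end"].astype(str)
    out = pd.DataFrame(
        {
            "read_id": df["read_id"],
            "transcript_id": df["transcript_id"],
            "t_len": df["t_len"],
            "blocks": blocks,
            "matches": df["matches"],
        }
    )
    out.to_csv(stream, sep="\t", index=False)


def write_fastq(sim: SampleSim, catalog: TranscriptCatalog, stream: IO[str]) -> None:
    """Optional FASTQ emission (sequences sliced from the catalog; flat
    per-base quality equal to the read's mean)."""
    df = sim.alignments.merge(sim.reads, on="read_id")
    for row in df.itertuples(index=False):
        seq = catalog.sequences[row.transcript_id][row.t_start : row.t_end]
        qchar = chr(33 + min(93, int(round(row.mean_quality))))
        stream.write(f"@{row.read_id}\n{seq}\n+\n{qchar * len(seq)}\n")


@dataclass
class StudyFixture:
    out_dir: Path
    catalog: TranscriptCatalog
    samples: list[SampleSim]
    manifest: dict


def make_study_fixture(
    out_dir: str | Path,
    seed: int,
    cfg: SimConfig | None = None,
    n_per_group: int = 3,
    groups: tuple[str, str] = ("Exo", "MV"),
    write_fastq_files: bool = False,
) -> StudyFixture:
    """Write a complete 3-exosome + 3-microvesicle study bundle.

    Exosome samples get a higher intact probability and lower inter-sample
    abundance noise than microvesicle samples (the concordance asymmetry the
    pipeline is meant to detect); the manifest records every parameter.
    """
    cfg = cfg or SimConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = simulate_catalog(cfg, _stream(seed, "catalog"))

    with open(out_dir / "annotation.gtf", "w") as fh:
        catalog.write_gtf(fh)
    with open(out_dir / "transcripts.fasta", "w") as fh:
        for tid in sorted(catalog.sequences):
            fh.write(f">{tid}\n{catalog.sequences[tid]}\n")

    samples: list[SampleSim] = []
    sheet_rows = []
    truth_frames = []
    for group in groups:
        for i in range(1, n_per_group + 1):
            sample_id = f"{group}_{i}"
            sim = simulate_sample(catalog, cfg, sample_id, group=group, seed=seed)
            samples.append(sim)
            aln_path = out_dir / f"{sample_id}.alignments.tsv"
            reads_path = out_dir / f"{sample_id}.reads.tsv"
            with open(aln_path, "w") as fh:
                write_alignments_tsv(sim, fh)
            sim.reads.to_csv(reads_path, sep="\t", index=False)
            if write_fastq_files:
                with open(out_dir / f"{sample_id}.fastq", "w") as fh:
                    write_fastq(sim, catalog, fh)
            truth_frames.append(sim.truth)
            sheet_rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "alignments": aln_path.name,
                    "reads": reads_path.name,
                }
            )
    pd.concat(truth_frames, ignore_index=True).to_csv(
        out_dir / "truth.tsv", sep="\t", index=False
    )
    pd.DataFrame(sheet_rows).to_csv(out_dir / "sample_sheet.tsv", sep="\t", index=False)

    manifest = {
        "seed": seed,
        "n_per_group": n_per_group,
        "groups": list(groups),
        "config": cfg.as_dict(),
        "samples": [s.sample_id for s in samples],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return StudyFixture(out_dir, catalog, samples, manifest)
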