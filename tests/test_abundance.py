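"""EM read assignment, composition metrics and group-heterogeneity statistics."""

import io

import numpy as np
import pytest

from evlongread.abundance import (
    SampleProfile,
    composition,
    correlation_matrix,
    em_assign,
    flag_degradation_machinery,
    group_specific_sets,
    intrinsic_genes,
)
from evlongread.read_ingest import TranscriptAlignment
from evlongread.transcript_model import load_annotation


def aln(rid, tid, end=100, matches=None):
    return TranscriptAlignment(rid, tid, ((0, end),), matches if matches is not None else end)


def reference_em(compat, n_iter=20_000):
    """Independent high-precision fixed-point oracle."""
    tids = sorted({t for cands in compat.values() for t in cands})
    theta = {t: 1.0 / len(tids) for t in tids}
    for _ in range(n_iter):
        resp = {t: 0.0 for t in tids}
        for cands in compat.values():
            total = sum(theta[t] for t in cands)
            for t in cands:
                resp[t] += theta[t] / total
        theta = {t: resp[t] / len(compat) for t in tids}
    return {t: theta[t] * len(compat) for t in tids}


class TestEMAssign:
    def test_unique_reads_equal_primary_counts(self):
        compat = {f"r{i}": [aln(f"r{i}", "A" if i < 6 else "B")] for i in range(10)}
        em = em_assign(compat, mode="em")
        direct = em_assign(compat, mode="primary_only")
        assert em.counts == pytest.approx(direct.counts)
        assert em.counts["A"] == pytest.approx(6.0) and em.counts["B"] == pytest.approx(4.0)

    def test_fully_symmetric_instance_splits_evenly(self):
        compat = {
            f"r{i}": [aln(f"r{i}", "A"), aln(f"r{i}", "B")] for i in range(8)
        }
        em = em_assign(compat, mode="em")
        assert em.counts["A"] == pytest.approx(4.0, abs=1e-6)
        assert em.counts["B"] == pytest.approx(4.0, abs=1e-6)

    def test_mixed_instance_matches_fixed_point_oracle(self):
        compat = {}
        for i in range(6):
            compat[f"u{i}"] = {"A"}
        for i in range(2):
            compat[f"v{i}"] = {"B"}
        for i in range(4):
            compat[f"m{i}"] = {"A", "B"}
        compat_alns = {
            rid: [aln(rid, t) for t in sorted(tids)] for rid, tids in compat.items()
        }
        em = em_assign(compat_alns, mode="em", tol=1e-12)
        oracle = reference_em(compat)
        assert em.counts["A"] == pytest.approx(oracle["A"], abs=1e-6)
        assert em.counts["B"] == pytest.approx(oracle["B"], abs=1e-6)

    def test_read_conservation_and_monotone_loglik(self):
        rng = np.random.default_rng(3)
        tids = [f"t{i}" for i in range(5)]
        compat = {}
        for i in range(50):
            k = int(rng.integers(1, 4))
            chosen = rng.choice(tids, size=k, replace=False)
            compat[f"r{i}"] = [aln(f"r{i}", t) for t in chosen]
        em = em_assign(compat, mode="em")
        assert sum(em.counts.values()) == pytest.approx(50.0, abs=1e-6)
        diffs = np.diff(em.log_likelihood)
        assert (diffs >= -1e-10).all()

    def test_empty_candidate_set_dropped_and_counted(self):
        compat = {"r0": [aln("r0", "A")], "r1": []}
        em = em_assign(compat, mode="em")
        assert em.n_dropped == 1 and em.n_assigned == 1


GTF_BIOTYPES = "".join(
    f'chr1\tx\texon\t{i * 1000 + 1}\t{i * 1000 + 100}\t.\t+\t.\t'
    f'gene_id "{g}"; transcript_id "{t}"; transcript_biotype "{b}";\n'
    for i, (t, g, b) in enumerate(
        [
            ("P1", "GP1", "protein_coding"),
            ("P2", "GP2", "protein_coding"),
            ("P3", "GP3", "protein_coding"),
            ("R1", "GR1", "rRNA"),
        ]
    )
)


class TestComposition:
    @pytest.fixture
    def catalog(self):
        return load_annotation(io.StringIO(GTF_BIOTYPES))

    def test_dual_metric_example(self, catalog):
        profile = SampleProfile("s", "Exo", {"P1": 1, "P2": 1, "P3": 1, "R1": 97})
        table = composition(profile, catalog)
        assert table.loc["protein_coding", "composition_percentage"] == pytest.approx(75.0)
        assert table.loc["rRNA", "composition_percentage"] == pytest.approx(25.0)
        assert table.loc["protein_coding", "read_count_ratio"] == pytest.approx(3.0)
        assert table.loc["rRNA", "read_count_ratio"] == pytest.approx(97.0)

    def test_columns_sum_to_100(self, catalog):
        profile = SampleProfile("s", "Exo", {"P1": 3.5, "R1": 11.25, "P2": 0.5})
        table = composition(profile, catalog)
        assert table["composition_percentage"].sum() == pytest.approx(100.0, abs=1e-9)
        assert table["read_count_ratio"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_biotype_is_100(self, catalog):
        table = composition(SampleProfile("s", "Exo", {"P1": 5}), catalog)
        assert table.loc["protein_coding", "composition_percentage"] == pytest.approx(100.0)
        assert table.loc["protein_coding", "read_count_ratio"] == pytest.approx(100.0)

    def test_absent_biotypes_present_as_zero_rows(self, catalog):
        table = composition(SampleProfile("s", "Exo", {"P1": 5}), catalog)
        assert table.loc["lncRNA", "composition_percentage"] == 0.0
        assert "other" in table.index


class TestIntrinsicGenes:
    @pytest.fixture
    def catalog(self):
        return load_annotation(io.StringIO(GTF_BIOTYPES))

    def _profiles(self, catalog, sets, groups=None):
        groups = groups or ["Exo"] * len(sets)
        return [
            SampleProfile(f"s{i}", g, {t: 10.0 for t in tids})
            for i, (tids, g) in enumerate(zip(sets, groups))
        ]

    def test_set_algebra_example(self, catalog):
        profiles = self._profiles(catalog, [{"P1", "P2"}, {"P2", "P3"}, {"P2"}])
        result = intrinsic_genes(profiles, catalog)
        assert result.intrinsic_genes == {"GP2"}
        assert result.proportion == pytest.approx(1 / 3)

    def test_identical_samples_give_proportion_one(self, catalog):
        profiles = self._profiles(catalog, [{"P1", "R1"}] * 3)
        assert intrinsic_genes(profiles, catalog).proportion == pytest.approx(1.0)

    def test_chi_square_wiring(self, catalog):
        profiles = self._profiles(
            catalog,
            [{"P1", "P2"}, {"P1", "P2"}, {"P1", "P3"}, {"P1", "P3"}],
            groups=["Exo", "Exo", "MV", "MV"],
        )
        result = intrinsic_genes(profiles, catalog)
        # intrinsic = {GP1}; Exo detects {GP1,GP2}, MV detects {GP1,GP3}
        assert result.table == ((1, 1), (1, 1))
        assert result.test is not None and result.test.statistic == pytest.approx(0.0)

    def test_single_group_skips_test(self, catalog):
        profiles = self._profiles(catalog, [{"P1"}, {"P1"}])
        result = intrinsic_genes(profiles, catalog)
        assert result.test is None and "skipped" in result.notice


class TestCorrelationMatrix:
    def _profile(self, sid, counts, group="Exo"):
        return SampleProfile(sid, group, counts)

    def test_self_correlation_diagonal(self):
        a = self._profile("a", {"t1": 1, "t2": 10, "t3": 100})
        b = self._profile("b", {"t1": 2, "t2": 5, "t3": 50})
        mat = correlation_matrix([a, b])
        assert mat.loc["a", "a"] == 1.0 and mat.loc["b", "b"] == 1.0

    def test_proportional_counts_on_log_scale(self):
        counts = {"t1": 9, "t2": 99, "t3": 999}
        doubled = {t: (c + 1) ** 2 - 1 for t, c in counts.items()}  # log10 doubles
        mat = correlation_matrix(
            [self._profile("a", counts), self._profile("b", doubled)]
        )
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_variance_reported_missing(self):
        flat = self._profile("flat", {"t1": 5, "t2": 5, "t3": 5})
        var = self._profile("var", {"t1": 1, "t2": 10, "t3": 100})
        mat = correlation_matrix([flat, var])
        assert np.isnan(mat.loc["flat", "var"])

    def test_symmetric_positive_semidefinite(self):
        rng = np.random.default_rng(8)
        profiles = [
            self._profile(f"s{i}", {f"t{j}": float(rng.integers(0, 50)) for j in range(20)})
            for i in range(5)
        ]
        mat = correlation_matrix(profiles).to_numpy()
        assert np.allclose(mat, mat.T)
        assert np.linalg.eigvalsh(mat).min() > -1e-10

    def test_top_n_restricts_to_high_mean_transcripts(self):
        a = self._profile("a", {"hi1": 100, "hi2": 90, "lo": 1})
        b = self._profile("b", {"hi1": 90, "hi2": 100, "lo": 5})
        full = correlation_matrix([a, b])
        top = correlation_matrix([a, b], top_n=2)
        assert top.loc["a", "b"] != pytest.approx(full.loc["a", "b"])


class TestGroupSpecificSets:
    @pytest.fixture
    def catalog(self):
        return load_annotation(io.StringIO(GTF_BIOTYPES))

    def test_disjoint_groups_share_nothing(self, catalog):
        profiles = [
            SampleProfile("e1", "Exo", {"P1": 5}),
            SampleProfile("m1", "MV", {"P2": 5}),
        ]
        sets = group_specific_sets(profiles, catalog)
        assert sets.shared_transcripts == set()
        assert sets.unique_transcripts["Exo"] == {"P1"}

    def test_identical_groups_have_no_unique_sets(self, catalog):
        profiles = [
            SampleProfile("e1", "Exo", {"P1": 5, "P2": 3}),
            SampleProfile("m1", "MV", {"P1": 2, "P2": 9}),
        ]
        sets = group_specific_sets(profiles, catalog)
        assert sets.unique_transcripts == {"Exo": set(), "MV": set()}

    def test_mv_only_transcript_with_gene_rollup(self, catalog):
        profiles = [
            SampleProfile("e1", "Exo", {"P1": 5}),
            SampleProfile("m1", "MV", {"P1": 5}),
            SampleProfile("m2", "MV", {"P1": 1, "R1": 4}),
        ]
        sets = group_specific_sets(profiles, catalog)
        assert sets.unique_transcripts["MV"] == {"R1"}
        assert sets.unique_genes["MV"] == {"GR1"}


class TestMachineryFlags:
    @pytest.fixture
    def catalog(self):
        gtf = GTF_BIOTYPES + "".join(
            f'chr2\tx\texon\t{i * 1000 + 1}\t{i * 1000 + 100}\t.\t+\t.\t'
            f'gene_id "{g}"; transcript_id "T{g}";\n'
            for i, g in enumerate(["PARN", "LSM3", "SMG5"])
        )
        return load_annotation(io.StringIO(gtf))

    def test_direct_and_prefix_matches(self, catalog):
        profile = SampleProfile("s", "Exo", {"TPARN": 5, "TLSM3": 2})
        table = flag_degradation_machinery([profile], catalog)
        assert bool(table.loc["PARN", "s"]) is True
        assert bool(table.loc["LSM3", "s"]) is True  # matched via LSM*
        assert bool(table.loc["SMG5", "s"]) is False

    def test_empty_gene_list_gives_empty_table(self, catalog):
        profile = SampleProfile("s", "Exo", {"TPARN": 5})
        assert flag_degradation_machinery([profile], catalog, gene_list=[]).empty
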