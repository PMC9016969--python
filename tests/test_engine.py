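"""emqtl_engine: filters, proximity mapping, screen, gates and emTF calling."""

import numpy as np
import pandas as pd
import pytest

from emqtlkit.core_io import (
    CohortBundle,
    CpGManifest,
    GenomicInterval,
    SampleMatrix,
    TFBSCollection,
)
from emqtlkit.engine import (
    bonferroni_flag,
    call_emtfs,
    iqr_filter,
    map_cpgs_to_tfbs,
    mwu_proximity_enrichment,
    partition_sign,
    proximal_fraction,
    screen_cohort,
    select_candidates,
    spearman_screen,
)


def beta_matrix(rows: dict[str, list[float]], samples=None) -> SampleMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.columns = samples or [f"S{i+1}" for i in range(df.shape[1])]
    return SampleMatrix(df, kind="methylation")


class TestIqrFilter:
    def test_constant_row_dropped(self):
        m = iqr_filter(beta_matrix({"cg1": [0.5, 0.5, 0.5, 0.5]}))
        assert m.row_ids == []

    def test_boundary_exactly_threshold_dropped(self):
        # type-7 quartiles of (0.40, 0.45, 0.50, 0.55): Q1=0.4375, Q3=0.5375, IQR=0.1
        m = iqr_filter(beta_matrix({"cg1": [0.40, 0.45, 0.50, 0.55]}))
        assert m.row_ids == []

    def test_type7_quartiles_keep(self):
        # Q1 = 0.175, Q3 = 0.825 under linear interpolation => IQR 0.65
        m = iqr_filter(beta_matrix({"cg1": [0.1, 0.2, 0.8, 0.9]}))
        assert m.row_ids == ["cg1"]
        q1, q3 = np.percentile([0.1, 0.2, 0.8, 0.9], [25, 75])
        assert (q1, q3) == (pytest.approx(0.175), pytest.approx(0.825))


class TestProximityMap:
    def test_window_boundary_inclusive(self, toy_manifest, toy_tfbs):
        prox = map_cpgs_to_tfbs(toy_manifest, toy_tfbs, window=200)
        # cgA at 900 is exactly 200 bp from [1100,1110); cgB at 899 is 201 bp
        assert prox["FOXA1"].tolist() == [True, False, True, False]
        assert prox["GATA3"].tolist() == [False, False, False, True]

    def test_matches_all_pairs_brute_force(self, rng):
        positions = rng.integers(0, 20_000, size=500)
        manifest = CpGManifest(
            pd.DataFrame(
                {"chrom": "chr1", "pos": positions},
                index=pd.Index([f"cg{i}" for i in range(500)], name="probe_id"),
            )
        )
        intervals = [
            GenomicInterval("chr1", s := int(rng.integers(0, 20_000)), s + int(rng.integers(5, 25)))
            for _ in range(200)
        ]
        tfbs = TFBSCollection({"TFX": intervals})
        got = map_cpgs_to_tfbs(manifest, tfbs, window=200)["TFX"]
        expected = np.array(
            [any(iv.distance_to(int(q)) <= 200 for iv in intervals) for q in positions]
        )
        np.testing.assert_array_equal(got, expected)

    def test_monotone_in_window(self, toy_manifest, toy_tfbs):
        small = map_cpgs_to_tfbs(toy_manifest, toy_tfbs, window=100)
        large = map_cpgs_to_tfbs(toy_manifest, toy_tfbs, window=500)
        for tf in small:
            assert not np.any(small[tf] & ~large[tf])


def tiny_cohort() -> CohortBundle:
    samples = [f"S{i}" for i in range(5)]
    expr = SampleMatrix(
        pd.DataFrame([[1, 2, 3, 4, 5]], index=["TF1"], columns=samples, dtype=float),
        kind="expression",
    )
    meth = beta_matrix(
        {
            "cgNeg": [0.9, 0.7, 0.5, 0.3, 0.1],
            "cgConst": [0.4, 0.4, 0.4, 0.4, 0.4],
            "cgNoise": [0.2, 0.8, 0.1, 0.9, 0.5],
        },
        samples=samples,
    )
    return CohortBundle(name="T", expression=expr, methylation=meth)


class TestSpearmanScreen:
    def test_perfect_antimonotone_and_degenerate(self):
        table = spearman_screen(tiny_cohort(), ["TF1"], ["cgNeg", "cgConst", "cgNoise"])
        assert table.rho[0, 0] == pytest.approx(-1.0)
        assert np.isnan(table.rho[0, 1])
        table = bonferroni_flag(table, alpha=0.01)
        assert table.significant[0, 0]
        assert not table.significant[0, 1]  # undefined never significant

    def test_missing_tf_raises(self):
        with pytest.raises(KeyError, match="TF9"):
            spearman_screen(tiny_cohort(), ["TF9"], ["cgNeg"])


class TestBonferroni:
    def _table(self, p_values):
        cohort = tiny_cohort()
        table = spearman_screen(cohort, ["TF1"], ["cgNeg", "cgNoise"])
        table.p_raw = np.asarray([p_values], dtype=float)
        table.rho = np.full_like(table.p_raw, -0.5)
        return table

    def test_threshold_arithmetic(self):
        table = bonferroni_flag(self._table([1e-9, 2e-8]), alpha=0.01, family_size=10**6)
        assert table.significant.tolist() == [[True, False]]

    def test_family_must_be_positive(self):
        with pytest.raises(ValueError):
            bonferroni_flag(self._table([0.5, 0.5]), family_size=0)

    def test_count_matches_recount(self, rng):
        table = self._table([0.0, 0.0])
        table.p_raw = rng.uniform(size=(1, 2)) * 1e-6
        table = bonferroni_flag(table, alpha=0.01, family_size=1000)
        recount = int((table.p_raw < 0.01 / 1000).sum())
        assert int(table.significant.sum()) == recount

    def test_raising_alpha_never_shrinks(self):
        table = self._table([1e-9, 2e-8])
        lo = bonferroni_flag(table, alpha=0.001, family_size=10**6).significant.copy()
        hi = bonferroni_flag(table, alpha=0.05, family_size=10**6).significant.copy()
        assert not np.any(lo & ~hi)


class TestFractionAndMwu:
    def _screen(self):
        samples = [f"S{i}" for i in range(8)]
        rng = np.random.default_rng(3)
        expr = SampleMatrix(
            pd.DataFrame(rng.normal(5, 1, size=(1, 8)) ** 2, index=["TF1"], columns=samples),
            kind="expression",
        )
        meth = beta_matrix({f"cg{i}": rng.uniform(0, 1, 8).tolist() for i in range(10)}, samples)
        table = spearman_screen(
            CohortBundle(name="T", expression=expr, methylation=meth), ["TF1"], meth.row_ids
        )
        return table

    def test_fraction_arithmetic(self):
        table = self._screen()
        table.significant = np.zeros((1, 10), dtype=bool)
        table.significant[0, :4] = True  # 4 significant
        prox = {"TF1": np.array([True] * 10)}
        stats = proximal_fraction(table, prox)
        assert stats.loc["TF1", "fraction"] == pytest.approx(0.4)

    def test_zero_significant_fraction(self):
        table = self._screen()
        table.significant = np.zeros((1, 10), dtype=bool)
        stats = proximal_fraction(table, {"TF1": np.array([True] * 10)})
        assert stats.loc["TF1", "fraction"] == 0.0

    def test_no_proximal_excluded(self):
        table = self._screen()
        table.significant = np.zeros((1, 10), dtype=bool)
        stats = proximal_fraction(table, {"TF1": np.array([False] * 10)})
        assert np.isnan(stats.loc["TF1", "fraction"])

    def test_mwu_worked_example(self):
        table = self._screen()
        table.rho = np.array([[0.9, 0.8, 0.7, 0.1, 0.2, 0.3, 0.4, np.nan, np.nan, np.nan]])
        prox = {"TF1": np.array([True] * 3 + [False] * 7)}
        p = mwu_proximity_enrichment(table, prox, "TF1")
        assert p == pytest.approx(1 / 35, abs=1e-15)


def _mock_screen(cohort, fractions, n_sig, mwu_p, n_proximal=100):
    """Build a CohortScreen-like object with prescribed per-TF statistics."""
    from emqtlkit.engine import CohortScreen, EmqtlTable

    tfs = [f"TF{i+1:02d}" for i in range(len(fractions))]
    n_cpgs = 5
    table = EmqtlTable(
        cohort=cohort,
        tfs=tfs,
        cpgs=[f"cg{i}" for i in range(n_cpgs)],
        rho=np.full((len(tfs), n_cpgs), -0.5),
        p_raw=np.full((len(tfs), n_cpgs), 1e-12),
        n_samples=10,
    )
    table.significant = np.ones((len(tfs), n_cpgs), dtype=bool)
    stats = pd.DataFrame(
        {
            "n_proximal": n_proximal,
            "n_proximal_significant": [int(f * n_proximal) for f in fractions],
            "fraction": fractions,
            "n_significant_total": n_sig,
            "mwu_p": mwu_p,
        },
        index=pd.Index(tfs, name="tf"),
    )
    return CohortScreen(
        cohort=cohort,
        table=table,
        proximity={tf: np.ones(n_cpgs, dtype=bool) for tf in tfs},
        stats=stats,
    )


class TestSelectCandidates:
    def test_percentile_cutoff_type7(self):
        fractions = [0.01 * k for k in range(1, 41)]
        screen = _mock_screen("A", fractions, n_sig=10_000, mwu_p=1e-10)
        pairs, cutoff = select_candidates([screen], percentile=95, min_sig=5000, mwu_alpha=0.01)
        # type-7 quantile of 0.01..0.40 at 0.95: h = 39*0.95 = 37.05 -> 0.3805
        assert cutoff == pytest.approx(0.3805)
        kept = pairs[pairs["passed_percentile"]].index.get_level_values("tf").tolist()
        assert len(kept) == 2  # only 0.39 and 0.40 clear the cutoff

    def test_min_sig_boundary(self):
        screen = _mock_screen("A", [0.5, 0.5], n_sig=[4999, 5000], mwu_p=1e-10)
        pairs, _ = select_candidates([screen], percentile=50, min_sig=5000)
        assert pairs["passed_min_sig"].tolist() == [False, True]

    def test_identical_fractions_all_pass_gate2(self):
        screen = _mock_screen("A", [0.3] * 6, n_sig=10_000, mwu_p=1e-10)
        pairs, _ = select_candidates([screen], percentile=95, min_sig=5000)
        assert pairs["passed_percentile"].all()

    def test_percentile_validated(self):
        screen = _mock_screen("A", [0.3], n_sig=10_000, mwu_p=1e-10)
        with pytest.raises(ValueError, match="percentile"):
            select_candidates([screen], percentile=100)


class TestCallEmtfs:
    def test_recurrence_rule(self):
        a = _mock_screen("A", [0.9, 0.8, 0.0], n_sig=[9000, 9000, 0], mwu_p=[1e-10, 1e-10, 0.9])
        b = _mock_screen("B", [0.9, 0.0, 0.0], n_sig=[9000, 0, 0], mwu_p=[1e-10, 0.9, 0.9])
        callset = call_emtfs([a, b], percentile=50, min_sig=5000, min_cohorts=2)
        assert callset.emtfs == ["TF01"]  # TF02 is candidate in A only

    def test_single_cohort_empty_with_warning(self, caplog):
        a = _mock_screen("A", [0.9], n_sig=9000, mwu_p=1e-10)
        with caplog.at_level("WARNING"):
            callset = call_emtfs([a], percentile=50, min_sig=5000, min_cohorts=2)
        assert callset.emtfs == []
        assert "min_cohorts" in caplog.text


class TestPartitionSign:
    def test_proportions_relative_to_proximal(self):
        neg, pos, pneg, ppos = partition_sign(np.array([-0.5, -0.4, 0.3]), n_proximal=10)
        assert neg.sum() == 2 and pos.sum() == 1
        assert pneg == pytest.approx(0.2)
        assert ppos == pytest.approx(0.1)

    def test_all_negative(self):
        _, _, pneg, ppos = partition_sign(np.array([-0.5, -0.4]), n_proximal=4)
        assert ppos == 0.0 and pneg == pytest.approx(0.5)

    def test_zero_rho_guarded(self):
        with pytest.raises(AssertionError):
            partition_sign(np.array([0.0, -0.4]), n_proximal=4)


class TestScreenCohortEndToEnd:
    def test_small_study_planted_tfs_rank_top(self, small_study):
        cohort = small_study.cohorts[0]
        screen = screen_cohort(
            cohort.bundle,
            small_study.genome.manifest,
            small_study.genome.tfbs,
            tf_list=small_study.config.tf_names,
        )
        stats = screen.stats.dropna(subset=["fraction"])
        top2 = stats["fraction"].nlargest(2).index.tolist()
        assert set(top2) == {"TF01", "TF02"}
        # planted pairs clear the MWU gate by many orders of magnitude
        assert (stats.loc[top2, "mwu_p"] < 1e-10).all()
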