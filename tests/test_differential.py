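"""Normalization, dispersion, NB Wald testing and selection rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ballatac import differential as diff
from ballatac import regions as rg
from ballatac import synthetic_data as sd
from ballatac.io_formats import NormalizationError

from conftest import make_counts


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_counts([[5, 5, 5], [9, 9, 9], [2, 2, 2]])
        assert np.allclose(diff.size_factors(cm), 1.0)

    def test_scale_equivariance(self):
        base = np.array([[5, 5, 5], [9, 9, 9], [30, 30, 30]])
        doubled = base.copy()
        doubled[:, 1] *= 2
        s = diff.size_factors(make_counts(doubled))
        assert s.iloc[1] / s.iloc[0] == pytest.approx(2.0)
        assert s.iloc[2] == pytest.approx(s.iloc[0])

    def test_hand_computed_median_of_ratios(self):
        # rows have geometric means 4, 6, 10; column ratios are exactly (0.5, 1, 2)
        cm = make_counts([[2, 4, 8], [3, 6, 12], [5, 10, 20]])
        s = diff.size_factors(cm)
        assert np.allclose(s / s.iloc[1], [0.5, 1.0, 2.0])

    def test_no_reference_row_raises_with_fallback_hint(self):
        cm = make_counts([[0, 5, 5], [9, 0, 9]])
        with pytest.raises(NormalizationError, match="pseudo_reference"):
            diff.size_factors(cm)
        s = diff.size_factors(cm, pseudo_reference=True)
        assert (s > 0).all()


class TestStabilize:
    def test_closed_forms(self):
        cm = make_counts([[0, 7]], sample_ids=["a", "b"])
        v = diff.stabilize(cm, pd.Series([1.0, 1.0], index=["a", "b"]))
        assert v.iloc[0, 0] == 0.0
        assert v.iloc[0, 1] == pytest.approx(3.0)  # log2(7 + 1)

    def test_zscore_rows_standardized(self):
        rng = np.random.default_rng(0)
        cm = make_counts(rng.poisson(30, size=(5, 8)))
        v = diff.stabilize(cm, np.ones(8), zscore=True)
        assert np.allclose(v.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(v.std(axis=1, ddof=0), 1.0, atol=1e-12)


class TestDispersion:
    def test_poisson_rows_near_zero_dispersion(self):
        rng = np.random.default_rng(1)
        cm = make_counts(rng.poisson(50, size=(50, 200)))
        q = cm.counts.to_numpy(dtype=float)
        m, v = q.mean(1), q.var(1, ddof=1)
        raw = np.maximum((v - m) / m**2, diff.ALPHA_MIN)
        assert np.median(raw) < 0.05  # moment estimate itself is near zero

    def test_nb_dispersion_recovered_within_30pct(self):
        rng = np.random.default_rng(2)
        alpha_true, mu = 0.5, 60.0
        r = 1 / alpha_true
        cm = make_counts(rng.negative_binomial(r, r / (r + mu), size=(300, 50)))
        est = diff.estimate_dispersion(cm, np.ones(50))
        assert abs(est.mean() - alpha_true) / alpha_true < 0.3

    def test_constant_rows_collapse_to_floor(self):
        cm = make_counts(np.full((5, 10), 7))
        est = diff.estimate_dispersion(cm, np.ones(10))
        assert (est <= 1e-6).all()


def _two_group_design(n_per):
    samples = pd.DataFrame(index=pd.Index([f"s{j}" for j in range(2 * n_per)], name="sample_id"))
    ind = np.r_[np.ones(n_per), np.zeros(n_per)]
    return diff.build_design(samples, ind)


class TestNbWald:
    def test_identical_groups_give_zero_lfc_unit_p(self):
        cm = make_counts(np.full((3, 8), 20))
        res = diff.nb_wald(cm, np.ones(8), np.full(3, 0.1), _two_group_design(4))
        assert np.allclose(res["log2FC"], 0.0, atol=1e-8)
        assert np.allclose(res["pvalue"], 1.0, atol=1e-6)

    def test_contrast_swap_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(3)
        cm = make_counts(rng.poisson([40] * 5 + [90] * 5, size=(20, 10)))
        design = _two_group_design(5)
        flipped = design.copy()
        flipped["group"] = 1.0 - flipped["group"]
        a = diff.nb_wald(cm, np.ones(10), np.full(20, 0.15), design)
        b = diff.nb_wald(cm, np.ones(10), np.full(20, 0.15), flipped)
        assert np.allclose(a["log2FC"], -b["log2FC"], atol=1e-6)
        assert np.allclose(a["pvalue"], b["pvalue"], atol=1e-8)

    def test_planted_fold_change_recovered(self):
        # effects in a minority of regions so normalization stays anchored
        rng = np.random.default_rng(4)
        n_regions, n_planted, alpha = 300, 40, 0.2
        r = 1 / alpha
        mu = np.full((n_regions, 20), 50.0)
        mu[:n_planted, :10] *= 4.0  # true log2FC = 2
        cm = make_counts(rng.negative_binomial(r, r / (r + mu)))
        sf = diff.size_factors(cm)
        disp = diff.estimate_dispersion(cm, sf, groups=["a"] * 10 + ["b"] * 10)
        res = diff.nb_wald(cm, sf, disp, _two_group_design(10))
        planted = res["log2FC"].iloc[:n_planted]
        assert 1.6 <= planted.median() <= 2.4
        assert np.median(np.abs(planted - 2.0)) < 0.3
        assert abs(res["log2FC"].iloc[n_planted:].median()) < 0.2

    def test_sample_order_relabeling_leaves_p_invariant(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(30, size=(10, 12))
        design = _two_group_design(6)
        res1 = diff.nb_wald(make_counts(counts), np.ones(12), np.full(10, 0.1), design)
        perm = rng.permutation(12)
        res2 = diff.nb_wald(
            make_counts(counts[:, perm]),
            np.ones(12),
            np.full(10, 0.1),
            design.iloc[perm].reset_index(drop=True).set_index(design.index[perm]),
        )
        assert np.allclose(res1["pvalue"], res2["pvalue"], atol=1e-8)


class TestOneVsRestAndExclusivity:
    def test_threshold_gates(self):
        res = pd.DataFrame(
            {"log2FC": [1.5, 0.8, -1.2], "padj": [0.01, 0.04, 0.2]},
            index=["r1", "r2", "r3"],
        )
        sig = (res["padj"] < 0.05) & (res["log2FC"].abs() >= 1.0)
        assert list(sig) == [True, False, False]

    def test_singleton_subtype_skipped(self):
        rng = np.random.default_rng(6)
        cm = make_counts(
            rng.poisson(40, size=(30, 5)),
            sample_ids=[f"s{j}" for j in range(5)],
            groups=["A", "A", "B", "B", "C"],
        )
        res = diff.one_vs_rest(cm)
        assert set(res) == {"A", "B"}  # C has one sample

    def test_covariate_column_accepted(self):
        rng = np.random.default_rng(7)
        cm = make_counts(
            rng.poisson(40, size=(30, 8)),
            groups=["A"] * 4 + ["B"] * 4,
        )
        cm.samples["tss_enrichment"] = rng.normal(8, 1, size=8)
        res = diff.one_vs_rest(cm, covariates=["tss_enrichment"])
        assert set(res) == {"A", "B"}

    def test_exclusivity_manual_scan(self):
        # 8 regions x 3 subtypes with hand-picked significance pattern
        regions = [f"r{i}" for i in range(8)]
        sig = {
            "X": ["r0", "r2", "r5"],
            "Y": ["r1", "r2", "r6"],
            "Z": ["r2", "r7"],
        }
        per = {}
        for st in sig:
            frame = pd.DataFrame(
                {"log2FC": 1.5, "padj": 0.01, "significant": [r in sig[st] for r in regions]},
                index=regions,
            )
            per[st] = frame
        cat = diff.exclusivity_filter(per)
        # r2 significant in all three -> dropped; the rest kept once
        assert sorted(cat.index) == ["r0", "r1", "r5", "r6", "r7"]
        assert cat.at["r6", "subtype"] == "Y"
        assert (cat["direction"] == "enriched").all()

    def test_depleted_direction_recorded(self):
        per = {"X": pd.DataFrame({"log2FC": [-2.0], "padj": [0.001], "significant": [True]}, index=["r0"])}
        assert diff.exclusivity_filter(per).at["r0", "direction"] == "depleted"


class TestProgenitorLoci:
    def test_staircase_recovery_without_exclusivity(self):
        cm, truth = sd.simulate_progenitors(n_regions=600, n_per_stage=10, n_ball=0, seed=9)
        windows = sd._region_catalog(600, width=250, spacing=1000)
        loci = diff.progenitor_identity_loci(cm, windows=windows)
        planted = set().union(*(truth[st] for st in truth))
        got = set(loci.ids)
        recall = len(got & planted) / len(planted)
        assert recall >= 0.85
        # no exclusivity: each locus appears exactly once even if multi-stage
        assert len(loci.ids) == len(set(loci.ids))


class TestBallVsProb:
    def test_directional_split_and_sign_symmetry(self):
        rng = np.random.default_rng(10)
        mu = np.full((60, 10), 40.0)
        mu[:10, :5] *= 5.0   # enriched in the case group
        mu[10:20, 5:] *= 5.0  # enriched in controls
        cm = make_counts(
            rng.poisson(mu),
            groups=["B-ALL"] * 5 + ["Pro-B"] * 5,
            group_col="group",
        )
        res = diff.ball_vs_prob(cm)
        assert (res["case_enriched"]["log2FC"] > 0).all()
        assert (res["control_enriched"]["log2FC"] < 0).all()
        assert len(res["case_enriched"]) >= 8
        assert len(res["control_enriched"]) >= 8


class TestDegProximityKs:
    def test_identical_lists_null(self):
        das = rg.RegionSet([("chr1", 1000 * i, 1000 * i + 100) for i in range(5)])
        tss = [("chr1", 200 * i) for i in range(10)]
        out = diff.deg_proximity_ks(das, tss, tss)
        assert out["D"] == 0.0
        assert out["pvalue"] == 1.0

    def test_maximal_separation(self):
        das = rg.RegionSet([("chr1", 0, 10)])
        deg = [("chr1", 5)] * 8                 # distance 0
        bg = [("chr1", 1_000_005)] * 8          # distance 1e6
        out = diff.deg_proximity_ks(das, deg, bg)
        assert out["D"] == 1.0

    def test_statistic_equals_brute_force_sup_ecdf(self):
        rng = np.random.default_rng(11)
        das = rg.RegionSet([("chr1", int(p), int(p) + 50) for p in rng.integers(0, 100_000, 15)])
        deg = [("chr1", int(p)) for p in rng.integers(0, 100_000, 20)]
        bg = [("chr1", int(p)) for p in rng.integers(0, 100_000, 20)]
        out = diff.deg_proximity_ks(das, deg, bg)

        mids = np.sort([iv.midpoint for iv in das])

        def dist(pos):
            return np.abs(mids - pos).min()

        d1 = np.sort([dist(p) for _, p in deg])
        d2 = np.sort([dist(p) for _, p in bg])
        grid = np.unique(np.r_[d1, d2])
        ecdf1 = np.searchsorted(d1, grid, side="right") / len(d1)
        ecdf2 = np.searchsorted(d2, grid, side="right") / len(d2)
        assert out["D"] == pytest.approx(np.abs(ecdf1 - ecdf2).max())

    def test_empty_das_rejected(self):
        with pytest.raises(ValueError):
            diff.deg_proximity_ks(rg.RegionSet([]), [("chr1", 1)], [("chr1", 2)])
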