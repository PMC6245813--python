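import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import mirtisect as mt
from mirtisect.qp_pipeline import _fit_single


def _two_group(target_counts, rest_counts):
    y = np.concatenate([np.asarray(target_counts, float), np.asarray(rest_counts, float)])
    ind = np.concatenate([
        np.ones(len(target_counts), bool), np.zeros(len(rest_counts), bool)
    ])
    return y, ind


def statsmodels_oracle(y, ind):
    """Independent IRLS quasi-Poisson fit: coefficient, dispersion, t-based p."""
    X = sm.add_constant(ind.astype(float))
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
    p = 2 * stats.t.sf(abs(fit.params[1] / fit.bse[1]), fit.df_resid)
    return fit.params[1], fit.scale, p


class TestFitOneVsRest:
    def test_strong_enrichment_detected(self):
        y, ind = _two_group([1000, 1100, 900], [10, 12, 9, 11])
        r = _fit_single(y, ind, "m", "liver")
        assert r.p_value < 0.01
        assert r.direction_positive

    def test_flat_data_not_significant(self):
        y, ind = _two_group([10, 11, 12, 10], [10, 11, 12, 10])
        r = _fit_single(y, ind, "m", "liver")
        assert abs(r.coefficient) < 0.05
        assert r.p_value > 0.5

    def test_swap_flips_sign_keeps_p(self):
        y, ind = _two_group([50, 60, 70], [5, 6, 7, 8])
        a = _fit_single(y, ind, "m", "t")
        b = _fit_single(y, ~ind, "m", "t")
        assert a.coefficient == pytest.approx(-b.coefficient, rel=1e-9)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)
        assert a.direction_positive != b.direction_positive

    def test_matches_independent_irls_oracle(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(20):
            n_t = int(rng.integers(3, 8))
            n_r = int(rng.integers(5, 30))
            y, ind = _two_group(
                rng.poisson(rng.uniform(5, 2000), n_t),
                rng.poisson(rng.uniform(5, 2000), n_r),
            )
            r = _fit_single(y, ind, "m", "t")
            coef, disp, p = statsmodels_oracle(y, ind)
            worst = max(worst, abs(r.coefficient - coef), abs(r.p_value - p),
                        abs(r.dispersion - disp))
        assert worst < 1e-6

    def test_all_zero_mirna_flagged(self):
        y, ind = _two_group([0, 0, 0], [0, 0, 0, 0])
        r = _fit_single(y, ind, "m", "t")
        assert r.p_value == 1.0 and r.coefficient == 0.0
        assert "all_zero" in r.flags

    def test_separation_capped_and_flagged(self):
        y, ind = _two_group([100, 120, 90], [0, 0, 0, 0])
        r = _fit_single(y, ind, "m", "t")
        assert r.coefficient == pytest.approx(700.0)
        assert "separation" in r.flags
        assert r.direction_positive

    def test_too_few_samples_is_error(self):
        y, ind = _two_group([5], [1, 2, 3])
        with pytest.raises(ValueError, match="2 samples"):
            _fit_single(y, ind, "m", "t")

    def test_wrapper_resolves_groups(self, small_atlas):
        counts, sheet, _, truth = small_atlas
        pm = mt.per_million_ceil(counts)
        planted = truth.df.iloc[0]
        r = mt.fit_one_vs_rest(pm, sheet, planted.target, planted.mirna_id)
        assert r.p_value < 1e-6 and r.direction_positive
        with pytest.raises(ValueError, match="unknown tissue"):
            mt.fit_one_vs_rest(pm, sheet, "spleen", planted.mirna_id)


class TestDetectTE:
    def _result(self, p, positive):
        return mt.QuasiPoissonResult("m", "liver", 1.0 if positive else -1.0,
                                     1.0, p, positive)

    def test_rule_and_boundary(self):
        assert len(mt.detect_te_qp([self._result(0.01, True)])) == 1
        assert mt.detect_te_qp([self._result(0.01, False)]) == []
        assert mt.detect_te_qp([self._result(0.05, True)]) == []  # strict <

    def test_bh_adjustment_is_more_conservative(self):
        results = [self._result(p, True) for p in np.linspace(0.001, 0.2, 50)]
        nominal = mt.detect_te_qp(results, alpha=0.05)
        adjusted = mt.detect_te_qp(results, alpha=0.05, adjust=True)
        assert {c.mirna_id for c in adjusted} <= {c.mirna_id for c in nominal}
        assert len(adjusted) <= len(nominal)


class TestDetectTS:
    def _te(self, mirna, target="liver"):
        return mt.EnrichmentCall(mirna, "quasipoisson", "TE", target, 1.0, p_value=0.001)

    def test_published_liver_excess_fires(self, table4_means):
        ts = mt.detect_ts_qp([self._te("rno-miR-122-5p")], table4_means, percent_points=90)
        assert [c.mirna_id for c in ts] == ["rno-miR-122-5p"]
        # 100 * (69427.419 - 1.574) / 69427.419
        assert ts[0].score == pytest.approx(99.99773, abs=1e-3)

    @pytest.mark.parametrize("mode", ["excess", "share"])
    def test_published_near_tie_fails_both_modes(self, table4_means, mode):
        ts = mt.detect_ts_qp([self._te("rno-miR-101b-3p")], table4_means,
                             percent_points=90, mode=mode)
        assert ts == []

    def test_exclusive_expression_is_ts(self):
        means = mt.GroupMeanMatrix(
            pd.DataFrame([[50.0, 0.0, 0.0]], index=["m"],
                         columns=["liver", "heart", "brain"]), "tissue")
        ts = mt.detect_ts_qp([self._te("m")], means)
        assert len(ts) == 1 and ts[0].score == pytest.approx(100.0)

    def test_zero_target_mean_not_ts(self):
        means = mt.GroupMeanMatrix(
            pd.DataFrame([[0.0, 5.0]], index=["m"], columns=["liver", "heart"]),
            "tissue")
        with pytest.warns(UserWarning, match="zero target mean"):
            assert mt.detect_ts_qp([self._te("m")], means) == []

    def test_ts_subset_of_te(self, small_atlas):
        counts, sheet, _, _ = small_atlas
        pm = mt.per_million_ceil(counts)
        means = mt.group_means(mt.tmm_normalize(counts), sheet, "tissue")
        results = mt.fit_all_one_vs_rest(pm, sheet, "liver")
        te = mt.detect_te_qp(results)
        ts = mt.detect_ts_qp(te, means)
        assert {c.mirna_id for c in ts} <= {c.mirna_id for c in te}


class TestDetectOS:
    def test_planted_organ_exclusive_found(self):
        design = mt.AtlasDesign(
            n_mirnas=40, planted=[mt.PlantedEffect(0, "Brain", 50.0, "OS")], seed=5)
        counts, sheet, _, truth = mt.generate_atlas(design)
        pm = mt.per_million_ceil(counts)
        calls = mt.detect_os_qp(pm, sheet, "Brain", alpha=0.05)
        assert truth.df.mirna_id.iloc[0] in {c.mirna_id for c in calls}
        assert all(c.status == "OS" for c in calls)

    def test_single_brain_tissue_gives_weaker_organ_than_tissue_signal(self):
        design = mt.AtlasDesign(
            n_mirnas=40, planted=[mt.PlantedEffect(0, "cerebrum", 50.0, "TS")], seed=5)
        counts, sheet, _, truth = mt.generate_atlas(design)
        pm = mt.per_million_ceil(counts)
        mid = truth.df.mirna_id.iloc[0]
        tissue_fit = mt.fit_one_vs_rest(pm, sheet, "cerebrum", mid, level="tissue")
        organ_fit = mt.fit_one_vs_rest(pm, sheet, "Brain", mid, level="organ")
        assert organ_fit.coefficient < tissue_fit.coefficient

    def test_unknown_organ_is_error(self, small_atlas):
        counts, sheet, _, _ = small_atlas
        with pytest.raises(ValueError, match="organ"):
            mt.detect_os_qp(mt.per_million_ceil(counts), sheet, "Gallbladder")


class TestCalibration:
    def test_type_one_error_and_power(self):
        """Null type-I error near nominal and near-total power at 10x, under
        negative-binomial noise with 23 groups of 5 samples (one vs rest)."""
        rng = np.random.default_rng(11)
        n_groups, n_per = 23, 5
        n = n_groups * n_per
        ind = np.zeros(n, bool)
        ind[:n_per] = True
        pvals = np.array([
            _fit_single(rng.negative_binomial(5, 5 / 105, n).astype(float),
                        ind, "m", "t").p_value
            for _ in range(1000)
        ])
        assert 0.03 <= (pvals < 0.05).mean() <= 0.07
        hits = 0
        for _ in range(200):
            mu = np.full(n, 100.0)
            mu[ind] = 1000.0
            y = rng.negative_binomial(5, 5 / (5 + mu)).astype(float)
            r = _fit_single(y, ind, "m", "t")
            hits += r.p_value < 0.05 and r.direction_positive
        assert hits / 200 >= 0.95

    def test_dispersion_estimate_tracks_noise_model(self):
        rng = np.random.default_rng(13)
        n = 115
        ind = np.zeros(n, bool)
        ind[:5] = True
        disp_pois = np.mean([
            _fit_single(rng.poisson(100, n).astype(float), ind, "m", "t").dispersion
            for _ in range(200)
        ])
        disp_nb = np.mean([
            _fit_single(rng.negative_binomial(2, 2 / 102, n).astype(float),
                        ind, "m", "t").dispersion
            for _ in range(200)
        ])
        assert disp_pois == pytest.approx(1.0, abs=0.2)
        assert disp_nb > 1.5
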