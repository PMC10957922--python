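import math

import numpy as np
import pandas as pd
import pytest

from spatialsr.association import (
    benjamini_hochberg,
    bootstrap_roc_compare,
    differential_test,
    logistic_roc,
    loo_deviance,
    loo_deviance_compare,
    median_distance_test,
    rank_auc,
    residual_deviance,
    trapezoid_auc,
)
from spatialsr.data_model import CohortLabels
from spatialsr.nlme import WeibullFit
from spatialsr.weibull import WeibullParams


def labels_for(n_resp, n_non):
    sids = [f"r{i}" for i in range(n_resp)] + [f"n{i}" for i in range(n_non)]
    resp = ["responder"] * n_resp + ["non_responder"] * n_non
    return sids, CohortLabels.from_dataframe(
        pd.DataFrame({"sample_id": sids, "response": resp})
    )


def brute_force_bh(p):
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = min(p[i] * n / (rank_idx + 1), prev)
        q[i] = val
        prev = val
    return q


class TestBenjaminiHochberg:
    def test_hand_worked_family_of_three(self):
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.04]))
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_matches_step_up_definition_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(benjamini_hochberg(p), brute_force_bh(p), atol=1e-12)

    def test_null_fdr_control(self):
        rng = np.random.default_rng(5)
        frac = []
        for _ in range(200):
            p = rng.uniform(size=50)
            q = benjamini_hochberg(p)
            frac.append(np.mean(q < 0.10))
        assert np.mean(frac) <= 0.10


class TestDifferentialTest:
    def test_identical_groups_give_p_one(self):
        sids, lab = labels_for(3, 3)
        m = pd.DataFrame({"shape.cd8_t.cancer": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}, index=sids)
        out = differential_test(m, lab)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)
        assert out.iloc[0]["fold_change"] == pytest.approx(0.0)

    def test_log_scale_for_scale_metric(self):
        sids, lab = labels_for(3, 3)
        m = pd.DataFrame({"scale.cd8_t.cancer": [1.0, 2.0, 4.0, 4.0, 8.0, 16.0]}, index=sids)
        out = differential_test(m, lab)
        row = out.iloc[0]
        assert row["scale"] == "log"
        # fold change = difference of log means = -log 4
        assert row["fold_change"] == pytest.approx(-math.log(4.0))

    def test_small_group_skipped(self):
        sids, lab = labels_for(1, 3)
        m = pd.DataFrame({"shape.x.y": [1.0, 2.0, 3.0, 4.0]}, index=sids)
        out = differential_test(m, lab)
        assert len(out) == 0

    def test_fdr_within_family(self):
        sids, lab = labels_for(4, 4)
        rng = np.random.default_rng(2)
        m = pd.DataFrame(
            {f"shape.t{i}.cancer": rng.normal(size=8) for i in range(5)}
            | {f"density.t{i}.tumor": rng.uniform(1, 10, size=8) for i in range(5)},
            index=sids,
        )
        out = differential_test(m, lab)
        assert set(out["family"]) == {"shape", "density"}
        for fam in ("shape", "density"):
            sub = out[out["family"] == fam]
            assert np.allclose(
                sub["fdr"], brute_force_bh(sub["p_value"].to_numpy()), atol=1e-12
            )


class TestMedianDistanceTest:
    def _fit(self, medians_resp, medians_non):
        fit = WeibullFit(from_type="cd8_t", to_type="cancer")
        # shape 1: median = scale·ln2, so scale = median/ln2
        for i, mdn in enumerate(medians_resp):
            fit.per_sample[f"r{i}"] = WeibullParams(1.0, mdn / math.log(2))
        for i, mdn in enumerate(medians_non):
            fit.per_sample[f"n{i}"] = WeibullParams(1.0, mdn / math.log(2))
        return fit

    def test_exact_p_for_separated_groups(self):
        # [1,2,3] vs [4,5,6]: U = 0, exact two-sided p = 2/C(6,3)·1 = 0.1
        _, lab = labels_for(3, 3)
        fit = self._fit([1, 2, 3], [4, 5, 6])
        out = median_distance_test(fit, lab)
        assert out["p_value"] == pytest.approx(0.1)
        assert out["median_responder"] == pytest.approx(2.0)

    def test_identical_groups_p_one(self):
        _, lab = labels_for(3, 3)
        fit = self._fit([2, 4, 8], [2, 4, 8])
        out = median_distance_test(fit, lab)
        assert out["p_value"] >= 0.99

    def test_per_sample_medians_follow_definition(self):
        _, lab = labels_for(3, 3)
        fit = WeibullFit(from_type="a", to_type="b")
        rng = np.random.default_rng(1)
        for s in ["r0", "r1", "r2", "n0", "n1", "n2"]:
            fit.per_sample[s] = WeibullParams(rng.uniform(1, 9), rng.uniform(2, 400))
        out = median_distance_test(fit, lab)
        for s, p in fit.per_sample.items():
            assert out["per_sample_medians"][s] == pytest.approx(
                p.scale * math.log(2) ** (1 / p.shape)
            )


class TestRocMachinery:
    def test_rank_auc_equals_trapezoid(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(6, 60)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # ties included
            assert rank_auc(scores, y) == pytest.approx(trapezoid_auc(scores, y), abs=1e-12)

    def test_perfect_ordering_gives_auc_one(self):
        sids, lab = labels_for(5, 5)
        feats = pd.DataFrame({"f": [1, 2, 3, 4, 5, -5, -4, -3, -2, -1]}, index=sids, dtype=float)
        roc = logistic_roc(feats, lab, n_boot=50, seed=0)
        assert roc.auc == 1.0

    def test_binary_feature_identical_to_labels(self):
        sids, lab = labels_for(5, 5)
        feats = pd.DataFrame({"f": [1] * 5 + [0] * 5}, index=sids, dtype=float)
        roc = logistic_roc(feats, lab, n_boot=100, seed=0)
        assert roc.auc == 1.0
        assert roc.ci_low == 1.0 and roc.ci_high == 1.0
        assert roc.separable

    def test_null_feature_auc_near_half(self):
        rng = np.random.default_rng(11)
        sids, lab = labels_for(100, 100)
        feats = pd.DataFrame({"f": rng.normal(size=200)}, index=sids)
        roc = logistic_roc(feats, lab, n_boot=50, seed=1)
        assert 0.4 <= roc.auc <= 0.6

    def test_seed_reproducible(self):
        rng = np.random.default_rng(4)
        sids, lab = labels_for(8, 8)
        feats = pd.DataFrame({"f": rng.normal(size=16)}, index=sids)
        r1 = logistic_roc(feats, lab, seed=99)
        r2 = logistic_roc(feats, lab, seed=99)
        assert np.array_equal(r1.replicate_aucs, r2.replicate_aucs)


class TestBootstrapRocCompare:
    def _rocs(self, seed=0):
        rng = np.random.default_rng(seed)
        sids, lab = labels_for(10, 10)
        strong = pd.DataFrame(
            {"f": np.r_[rng.normal(3, 1, 10), rng.normal(0, 1, 10)]}, index=sids
        )
        noise = pd.DataFrame({"f": rng.normal(size=20)}, index=sids)
        return (
            logistic_roc(strong, lab, n_boot=50, seed=1),
            logistic_roc(noise, lab, n_boot=50, seed=1),
        )

    def test_self_comparison_is_null(self):
        a, _ = self._rocs()
        p = bootstrap_roc_compare(a, a, n_boot=100, seed=5)
        assert p > 0.4

    def test_strong_beats_noise(self):
        a, b = self._rocs()
        p = bootstrap_roc_compare(a, b, n_boot=200, seed=5)
        assert p < 0.01

    def test_reversed_direction(self):
        a, b = self._rocs()
        p = bootstrap_roc_compare(b, a, n_boot=200, seed=5)
        assert p > 0.5


class TestLooDeviance:
    def test_null_deviance_closed_form(self):
        # intercept-only model, 14 responders vs 10 non-responders
        y = np.array([1] * 14 + [0] * 10)
        mu = np.full(24, 14 / 24)
        expected = -2 * (14 * math.log(14 / 24) + 10 * math.log(10 / 24))
        assert residual_deviance(y, mu) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(32.60, abs=0.005)

    def test_perfect_separator_near_zero_deviance(self):
        sids, lab = labels_for(5, 5)
        feats = pd.DataFrame({"f": [1.0] * 5 + [0.0] * 5}, index=sids)
        devs = loo_deviance(feats, lab)
        assert np.all(devs < 1e-3)

    def test_identical_feature_sets_p_one(self):
        rng = np.random.default_rng(6)
        sids, lab = labels_for(6, 6)
        feats = pd.DataFrame({"f": rng.normal(size=12)}, index=sids)
        out = loo_deviance_compare(feats, feats.copy(), lab)
        assert out["p_value"] == pytest.approx(1.0)
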