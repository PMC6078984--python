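"""Statistical layer: exact/asymptotic tests, FDR, adjusted models, survival."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bcpgenomics.stats import (
    adjusted_association, bh_fdr, cox_fit, fisher_exact, km_logrank,
    mann_whitney, spearman,
)


class TestMannWhitney:
    def test_exact_enumeration_oracle(self):
        """[1,2,3] vs [4,5,6]: enumerate all C(6,3)=20 group assignments."""
        from itertools import combinations

        pooled = [1, 2, 3, 4, 5, 6]
        obs_u = sum(1 for x in [1, 2, 3] for y in [4, 5, 6] if x > y)
        null_u = []
        for idx in combinations(range(6), 3):
            x = [pooled[i] for i in idx]
            y = [pooled[i] for i in range(6) if i not in idx]
            null_u.append(sum(1 for a in x for b in y if a > b))
        null_u = np.array(null_u)
        # two-sided exact p: doubling the smaller tail
        p_exact = 2 * min(
            np.mean(null_u <= obs_u), np.mean(null_u >= obs_u)
        )
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(p_exact) == pytest.approx(0.1)
        assert res.statistic == 0.0

    def test_identical_groups_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p >= 0.99

    def test_symmetry_under_group_swap(self):
        a, b = [1.0, 5.0, 2.0, 8.0], [3.0, 9.0, 4.0]
        assert mann_whitney(a, b).p == pytest.approx(mann_whitney(b, a).p)

    def test_type_one_error_calibration(self):
        """Null rejection rate at alpha=0.05 stays within 0.05 +/- 0.01."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 5000
        for _ in range(reps):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            if mann_whitney(x, y).p < 0.05 - 1e-12:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFisher:
    def test_diagonal_two_by_two(self):
        assert fisher_exact([[1, 0], [0, 1]]).p == pytest.approx(1.0)

    def test_msh2_deletion_table(self):
        """The MSH2-deletion contingency (5/15 vs 1/38 deleted)."""
        res = fisher_exact([[5, 10], [1, 37]])
        # independent oracle: sum hypergeometric probabilities <= observed
        obs_p = sps.hypergeom.pmf(5, 53, 6, 15)
        total = sum(
            sps.hypergeom.pmf(k, 53, 6, 15)
            for k in range(0, 7)
            if sps.hypergeom.pmf(k, 53, 6, 15) <= obs_p * (1 + 1e-9)
        )
        assert res.p == pytest.approx(total, rel=1e-6)
        assert res.p < 0.05

    def test_extreme_table(self):
        from math import comb

        res = fisher_exact([[10, 0], [0, 10]])
        assert res.p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [1, 2]])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(20.0)
        assert spearman(x, x**3).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_null_rho_small(self):
        rng = np.random.default_rng(3)
        inside = 0
        for _ in range(200):
            x, y = rng.uniform(size=1000), rng.uniform(size=1000)
            if abs(spearman(x, y).statistic) < 0.08:
                inside += 1
        assert inside >= 0.95 * 200

    def test_small_sample_permutation_path(self):
        res = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert 0 < res.p <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestBhFdr:
    def test_hand_computed_step_up(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_order_restored_and_monotone_in_ranks(self):
        p = [0.04, 0.001, 0.9, 0.02]
        out = bh_fdr(p)
        assert np.argsort(out).tolist() == np.argsort(p).tolist()

    def test_idempotent_on_flat_sets(self):
        flat = [0.2, 0.2, 0.2]
        assert np.allclose(bh_fdr(bh_fdr(flat)), bh_fdr(flat))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestAdjustedAssociation:
    @staticmethod
    def _covs(rng, n):
        return pd.DataFrame(
            {
                "age_at_diagnosis": rng.normal(40, 5, n),
                "diagnosis_year": rng.uniform(1996, 2010, n),
                "pathological_stage": rng.choice([1.0, 2.0, 3.0], n),
                "subtype_ihc": rng.choice(["LumA", "LumB", "HER2", "TNBC"], n),
            }
        )

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            covs = self._covs(rng, 500)
            group = rng.integers(0, 2, 500)
            outcome = rng.normal(size=500) + 0.3 * covs["pathological_stage"]
            ps.append(adjusted_association(outcome, group, covs).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_saturated_effect(self):
        rng = np.random.default_rng(1)
        covs = self._covs(rng, 200)
        group = rng.integers(0, 2, 200)
        res = adjusted_association(group.astype(float), group, covs, kind="linear")
        assert res.p < 1e-10

    def test_logistic_lr_path(self):
        rng = np.random.default_rng(2)
        covs = self._covs(rng, 400)
        group = rng.integers(0, 2, 400)
        logit = -0.5 + 1.2 * group
        y = rng.random(400) < 1 / (1 + np.exp(-logit))
        res = adjusted_association(y.astype(float), group, covs, kind="logistic")
        assert res.test == "adjusted_logistic"
        assert res.p < 0.01


class TestSurvival:
    def test_km_no_censoring(self):
        fit = km_logrank([2.0, 2.0, 2.0], [1, 1, 1], ["g", "g", "g"])
        assert fit.median_survival["g"] == pytest.approx(2.0)
        assert fit.km_curves["g"]["survival"].iloc[-1] == pytest.approx(0.0)

    def test_identical_groups_logrank(self):
        t = [1.0, 2.0, 3.0, 4.0] * 2
        e = [1, 1, 0, 1] * 2
        g = ["a"] * 4 + ["b"] * 4
        fit = km_logrank(t, e, g)
        assert fit.logrank_p == pytest.approx(1.0)

    def test_exponential_median_ratio(self):
        rng = np.random.default_rng(11)
        t1 = rng.exponential(1.0, 500)
        t2 = rng.exponential(2.0, 500)
        fit = km_logrank(
            np.concatenate([t1, t2]), np.ones(1000, dtype=int),
            np.array(["fast"] * 500 + ["slow"] * 500),
        )
        ratio = fit.median_survival["slow"] / fit.median_survival["fast"]
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            km_logrank([1.0, 2.0], [0, 0], ["a", "a"])

    def test_cox_parameter_recovery(self):
        rng = np.random.default_rng(21)
        x = rng.integers(0, 2, 2000)
        t = rng.exponential(1.0 / (0.5 * np.exp(np.log(2.0) * x)))
        fit = cox_fit(t, np.ones(2000, dtype=int), pd.DataFrame({"x": x.astype(float)}))
        hr = fit.cox_summary.loc["x", "hr"]
        assert 1.8 <= hr <= 2.2
        lo, hi = fit.cox_summary.loc["x", ["hr_ci_low", "hr_ci_high"]]
        assert lo < hr < hi

    def test_cox_hr_inverts_under_label_swap(self):
        rng = np.random.default_rng(22)
        x = rng.integers(0, 2, 800).astype(float)
        t = rng.exponential(1.0 / np.exp(0.5 * x))
        e = np.ones(800, dtype=int)
        hr1 = cox_fit(t, e, pd.DataFrame({"x": x})).cox_summary.loc["x", "hr"]
        hr2 = cox_fit(t, e, pd.DataFrame({"x": 1.0 - x})).cox_summary.loc["x", "hr"]
        assert hr1 == pytest.approx(1.0 / hr2, rel=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1.0, 2.0], [1, 1], pd.DataFrame({"x": [1.0, 1.0]}))
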