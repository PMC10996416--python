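"""Sensitivity/specificity, exact binomial intervals, Cohen's kappa."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cxragree import (
    ConfusionTable,
    UndefinedKappaError,
    clopper_pearson,
    cohens_kappa,
    confusion_from_calls,
    kappa_interval,
    prevalence,
    sensitivity,
    specificity,
)
from cxragree.accuracy_stats import kappa_variance

from conftest import make_dataset

tables = st.builds(
    ConfusionTable,
    tp=st.integers(0, 50),
    fp=st.integers(0, 50),
    fn=st.integers(0, 50),
    tn=st.integers(1, 50),
)


def cp_grid_oracle(k, n, level=0.95, grid=20001):
    """Brute-force Clopper-Pearson: invert binomial tail probabilities on a grid."""
    alpha = 1 - level
    ps = np.linspace(0, 1, grid)
    upper_tail = 1 - stats.binom.cdf(k - 1, n, ps)  # P[X >= k]
    lower_tail = stats.binom.cdf(k, n, ps)  # P[X <= k]
    lower = 0.0 if k == 0 else ps[upper_tail >= alpha / 2].min()
    upper = 1.0 if k == n else ps[lower_tail >= alpha / 2].max()
    return lower, upper


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [
            (57, 172, 0.262, 0.407),
            (3, 27, 0.024, 0.292),
        ],
    )
    def test_published_interval_endpoints(self, k, n, lo, hi):
        ci = clopper_pearson(k, n)
        assert round(ci.lower, 3) == lo
        assert round(ci.upper, 3) == hi

    def test_boundary_cases(self):
        assert clopper_pearson(0, 10).lower == 0.0
        assert clopper_pearson(10, 10).upper == 1.0

    @pytest.mark.parametrize("k,n", [(0, 7), (1, 9), (5, 12), (12, 12), (40, 100)])
    def test_matches_grid_inversion_oracle(self, k, n):
        ci = clopper_pearson(k, n)
        lo, hi = cp_grid_oracle(k, n)
        assert ci.lower == pytest.approx(lo, abs=1e-4)
        assert ci.upper == pytest.approx(hi, abs=1e-4)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(3, 27), (57, 172), (0, 5), (1404, 1404)]:
            lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
            ci = clopper_pearson(k, n)
            assert ci.lower == pytest.approx(float(lo), abs=1e-12)
            assert ci.upper == pytest.approx(float(hi), abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 3)
        with pytest.raises(ValueError):
            clopper_pearson(-1, 3)
        with pytest.raises(ValueError):
            clopper_pearson(1, 3, level=1.0)

    def test_coverage_is_conservative(self):
        """Exact intervals cover the true p at >= the nominal rate."""
        rng = np.random.default_rng(7)
        reps = 2000
        for n in (20, 172):
            for p in (0.12, 0.33, 0.9):
                ks = rng.binomial(n, p, size=reps)
                covered = 0
                for k in np.unique(ks):
                    ci = clopper_pearson(int(k), n)
                    if ci.lower <= p <= ci.upper:
                        covered += int((ks == k).sum())
                se = np.sqrt(0.95 * 0.05 / reps)
                assert covered / reps >= 0.95 - 2 * se


class TestOperatingPoints:
    def test_published_sensitivity_specificity(self):
        ct = ConfusionTable(tp=57, fp=8, fn=115, tn=1224)
        assert round(100 * sensitivity(ct).point, 1) == 33.1
        assert round(100 * specificity(ct).point, 1) == 99.4
        ct = ConfusionTable(tp=143, fp=75, fn=205, tn=977)
        assert round(100 * specificity(ct).point, 1) == 92.9

    def test_degenerate_rates(self):
        assert sensitivity(ConfusionTable(tp=0, fp=1, fn=5, tn=1)).point == 0.0
        assert sensitivity(ConfusionTable(tp=7, fp=1, fn=0, tn=1)).point == 1.0
        assert specificity(ConfusionTable(tp=1, fp=0, fn=1, tn=3)).point == 1.0
        with pytest.raises(ValueError):
            sensitivity(ConfusionTable(tp=0, fp=2, fn=0, tn=3))

    def test_published_prevalence(self):
        ct = ConfusionTable(tp=57, fp=8, fn=115, tn=1224)
        assert round(100 * prevalence(ct).point, 1) == 12.3
        ct = ConfusionTable(tp=113, fp=13, fn=236, tn=1042)
        assert round(100 * prevalence(ct).point, 1) == 24.9

    @given(tables)
    def test_point_inside_interval(self, ct):
        if ct.truth_positives >= 1:
            ci = sensitivity(ct)
            assert ci.lower <= ci.point <= ci.upper
        if ct.truth_negatives >= 1:
            ci = specificity(ct)
            assert ci.lower <= ci.point <= ci.upper


class TestCohensKappa:
    @pytest.mark.parametrize(
        "ct,expected",
        [
            (ConfusionTable(tp=57, fp=8, fn=115, tn=1224), 0.44),
            (ConfusionTable(tp=21, fp=2, fn=10, tn=1371), 0.77),
        ],
    )
    def test_published_values(self, ct, expected):
        assert round(cohens_kappa(ct).kappa, 2) == expected

    def test_chance_and_perfect_agreement(self):
        est = cohens_kappa(ConfusionTable(tp=1, fp=1, fn=1, tn=1))
        assert est.kappa == 0.0 and est.p_o == est.p_e == 0.5
        assert cohens_kappa(ConfusionTable(tp=4, fp=0, fn=0, tn=9)).kappa == 1.0

    def test_degenerate_table_raises(self):
        with pytest.raises(UndefinedKappaError):
            cohens_kappa(ConfusionTable(tp=5, fp=0, fn=0, tn=0))
        with pytest.raises(UndefinedKappaError):
            cohens_kappa(ConfusionTable(tp=0, fp=0, fn=0, tn=7))

    @given(tables)
    def test_kappa_bounded(self, ct):
        try:
            k = cohens_kappa(ct).kappa
        except UndefinedKappaError:
            return
        assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12

    @given(tables)
    def test_label_swap_invariance(self, ct):
        """Swapping positive<->negative for both reader and truth leaves kappa unchanged."""
        swapped = ConfusionTable(tp=ct.tn, fp=ct.fn, fn=ct.fp, tn=ct.tp)
        try:
            k1 = cohens_kappa(ct).kappa
        except UndefinedKappaError:
            with pytest.raises(UndefinedKappaError):
                cohens_kappa(swapped)
            return
        assert cohens_kappa(swapped).kappa == pytest.approx(k1, abs=1e-12)

    def test_matches_sklearn_from_call_vectors(self, toy_dataset):
        """Kappa from the 2x2 tally equals kappa computed on raw call vectors."""
        from sklearn.metrics import cohen_kappa_score

        ct = confusion_from_calls(toy_dataset, "radiologist", "pneumothorax")
        sub = toy_dataset.finding_frame("pneumothorax")
        oracle = cohen_kappa_score(
            sub["truth"].astype(int), sub["radiologist"].astype(int)
        )
        assert cohens_kappa(ct).kappa == pytest.approx(oracle, abs=1e-12)

    def test_matches_statsmodels_on_study_scale(self):
        import statsmodels.stats.inter_rater as ir

        ct = ConfusionTable(tp=143, fp=75, fn=205, tn=977)
        res = ir.cohens_kappa(np.array([[ct.tp, ct.fn], [ct.fp, ct.tn]]))
        assert cohens_kappa(ct).kappa == pytest.approx(res.kappa, abs=1e-12)
        assert kappa_variance(ct) == pytest.approx(res.var_kappa, rel=1e-9)


class TestKappaInterval:
    def test_perfect_agreement_bootstrap_interval(self):
        ct = ConfusionTable(tp=6, fp=0, fn=0, tn=14)
        est = kappa_interval(ct, method="bootstrap", n_boot=500, seed=3)
        assert est.ci == (1.0, 1.0)

    def test_bootstrap_deterministic_under_seed(self):
        ct = ConfusionTable(tp=57, fp=8, fn=115, tn=1224)
        a = kappa_interval(ct, method="bootstrap", n_boot=1000, seed=42)
        b = kappa_interval(ct, method="bootstrap", n_boot=1000, seed=42)
        assert a.ci == b.ci

    def test_analytic_close_to_bootstrap_at_study_scale(self):
        """Large-sample and percentile-bootstrap bounds agree within 0.02 at n=1400."""
        ct = ConfusionTable(tp=67, fp=2, fn=104, tn=1227)
        analytic = kappa_interval(ct, method="analytic")
        boot = kappa_interval(ct, method="bootstrap", n_boot=20_000, seed=9)
        assert analytic.ci[0] == pytest.approx(boot.ci[0], abs=0.02)
        assert analytic.ci[1] == pytest.approx(boot.ci[1], abs=0.02)

    def test_interval_contains_point(self):
        ct = ConfusionTable(tp=43, fp=3, fn=36, tn=1322)
        for method in ("analytic", "bootstrap"):
            est = kappa_interval(ct, method=method, n_boot=2000, seed=1)
            assert est.ci[0] <= est.kappa <= est.ci[1]
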