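"""Accuracy of one reader against the reference standard.

Sensitivity, specificity and prevalence are binomial proportions and carry
exact Clopper-Pearson confidence intervals.  Chance-corrected agreement with
the reference standard is Cohen's kappa,

    kappa = (p_o - p_e) / (1 - p_e),

with observed agreement p_o = (tp + tn) / n and chance-expected agreement
p_e computed from the marginals.  Kappa intervals are available analytically
(large-sample variance, Fleiss-Cohen-Everitt) or by a percentile bootstrap
of the 2x2 table (multinomial case resampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import ConfusionTable

__all__ = [
    "BinomialCI",
    "KappaEstimate",
    "UndefinedKappaError",
    "clopper_pearson",
    "sensitivity",
    "specificity",
    "prevalence",
    "cohens_kappa",
    "kappa_interval",
]


class UndefinedKappaError(ValueError):
    """Kappa is undefined: chance agreement p_e = 1 (both margins constant)."""

    def __init__(self, table: ConfusionTable):
        self.table = table
        super().__init__(
            f"Cohen's kappa undefined for degenerate table {table}: p_e = 1"
        )


@dataclass(frozen=True)
class BinomialCI:
    """A binomial proportion k/n with an exact equal-tailed interval."""

    point: float
    lower: float
    upper: float
    level: float
    k: int
    n: int

    def __str__(self) -> str:  # display convention: percentages at 1 dp
        return (
            f"{100 * self.point:.1f}% "
            f"({100 * self.lower:.1f}-{100 * self.upper:.1f})"
        )


@dataclass(frozen=True)
class KappaEstimate:
    """Cohen's kappa with its agreement components and optional interval."""

    kappa: float
    p_o: float
    p_e: float
    ci: tuple[float, float] | None = None
    level: float | None = None
    method: str | None = None

    def __str__(self) -> str:  # display convention: kappa at 2 dp
        s = f"{self.kappa:.2f}"
        if self.ci is not None:
            s += f" ({self.ci[0]:.2f}-{self.ci[1]:.2f})"
        return s


def clopper_pearson(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact equal-tailed binomial interval for k successes in n trials.

    The lower bound inverts the upper binomial tail (it is the p for which
    P[X >= k] = alpha/2), the upper bound the lower tail; both are beta
    quantiles.  The interval is conservative: coverage is at least the
    nominal level for every true p.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"require 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return BinomialCI(point=k / n, lower=lower, upper=upper, level=level, k=k, n=n)


def sensitivity(ct: ConfusionTable, level: float = 0.95) -> BinomialCI:
    """True-positive rate tp/(tp+fn) with exact interval."""
    if ct.truth_positives < 1:
        raise ValueError("sensitivity undefined: no truth-positive cases")
    return clopper_pearson(ct.tp, ct.truth_positives, level)


def specificity(ct: ConfusionTable, level: float = 0.95) -> BinomialCI:
    """True-negative rate tn/(tn+fp) with exact interval."""
    if ct.truth_negatives < 1:
        raise ValueError("specificity undefined: no truth-negative cases")
    return clopper_pearson(ct.tn, ct.truth_negatives, level)


def prevalence(ct: ConfusionTable, level: float = 0.95) -> BinomialCI:
    """Proportion of truth-positive cases (tp+fn)/n with exact interval."""
    return clopper_pearson(ct.truth_positives, ct.n, level)


def _kappa_terms(tp, fp, fn, tn):
    """(p_o, p_e) -- vectorised over array inputs."""
    n = tp + fp + fn + tn
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    return p_o, p_e


def cohens_kappa(ct: ConfusionTable) -> KappaEstimate:
    """Cohen's kappa between a reader and the reference standard.

    Raises :class:`UndefinedKappaError` when both margins are constant
    (p_e = 1); no substitute value is returned, since silently mapping the
    degenerate case to 0 or 1 corrupts bootstrap distributions.
    """
    p_o, p_e = _kappa_terms(ct.tp, ct.fp, ct.fn, ct.tn)
    if p_e >= 1.0:
        raise UndefinedKappaError(ct)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaEstimate(kappa=float(kappa), p_o=float(p_o), p_e=float(p_e))


def kappa_variance(ct: ConfusionTable) -> float:
    """Large-sample variance of Cohen's kappa (Fleiss-Cohen-Everitt).

    For cell proportions p_ij with row margins p_i. (reader) and column
    margins p_.j (truth):

        var = [ sum_i p_ii ((1-p_e) - (p_.i + p_i.)(1-p_o))^2
                + (1-p_o)^2 sum_{i!=j} p_ij (p_.i + p_j.)^2
                - (p_o p_e - 2 p_e + p_o)^2 ] / (n (1-p_e)^4)
    """
    n = ct.n
    # agreement table with rows = reader call, cols = truth label
    p = np.array([[ct.tp, ct.fp], [ct.fn, ct.tn]]) / n
    row = p.sum(axis=1)  # reader margins
    col = p.sum(axis=0)  # truth margins
    p_o = p[0, 0] + p[1, 1]
    p_e = row @ col
    if p_e >= 1.0:
        raise UndefinedKappaError(ct)
    term1 = sum(
        p[i, i] * ((1 - p_e) - (col[i] + row[i]) * (1 - p_o)) ** 2 for i in range(2)
    )
    term2 = (1 - p_o) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    term3 = (p_o * p_e - 2 * p_e + p_o) ** 2
    return float((term1 + term2 - term3) / (n * (1 - p_e) ** 4))


def kappa_interval(
    ct: ConfusionTable,
    method: str = "analytic",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = None,
) -> KappaEstimate:
    """Cohen's kappa with a confidence interval.

    ``analytic`` uses the large-sample standard error (fast, deterministic);
    ``bootstrap`` a percentile interval over ``n_boot`` multinomial
    resamples of the n cases, reproducible under ``seed``.  Bounds are
    clipped to [-1, 1].
    """
    if ct.n < 2:
        raise ValueError("kappa interval requires n >= 2")
    est = cohens_kappa(ct)
    if method == "analytic":
        se = math.sqrt(kappa_variance(ct))
        z = stats.norm.ppf(0.5 + level / 2)
        lo, hi = est.kappa - z * se, est.kappa + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        probs = np.array([ct.tp, ct.fp, ct.fn, ct.tn]) / ct.n
        draws = rng.multinomial(ct.n, probs, size=n_boot).T
        p_o, p_e = _kappa_terms(*draws)
        with np.errstate(divide="ignore", invalid="ignore"):
            kappas = np.where(p_e < 1.0, (p_o - p_e) / (1.0 - p_e), np.nan)
        kappas = kappas[~np.isnan(kappas)]
        if kappas.size == 0:
            raise UndefinedKappaError(ct)
        alpha = 1.0 - level
        lo, hi = np.quantile(kappas, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown method {method!r}; use 'analytic' or 'bootstrap'")
    lo, hi = max(-1.0, float(lo)), min(1.0, float(hi))
    return KappaEstimate(
        kappa=est.kappa, p_o=est.p_o, p_e=est.p_e,
        ci=(lo, hi), level=level, method=method,
    )
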