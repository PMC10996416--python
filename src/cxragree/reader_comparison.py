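"""Paired inference between two readers sharing a reference standard.

The central tool is a paired case bootstrap for the difference in Cohen's
kappa: cases are the resampling unit and both readers' calls travel with
their case, so the resampled distribution of kappa_B - kappa_A reflects the
within-case correlation of the readers.  The companion "hybrid" reader is
the OR-rule combination: a finding is called present when either constituent
reader calls it present.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accuracy_stats import (
    BinomialCI,
    UndefinedKappaError,
    _kappa_terms,
    sensitivity,
    specificity,
)
from .data_model import ConfusionTable, DatasetError, ReaderCall, StudyDataset

__all__ = [
    "KappaComparison",
    "HybridResult",
    "paired_bootstrap_kappa_diff",
    "hybrid_or",
    "compare_all",
    "finding_seed",
]

MAX_DEGENERATE_FRACTION = 0.10


@dataclass(frozen=True)
class KappaComparison:
    """Bootstrap distribution summary of kappa_B - kappa_A."""

    delta_median: float
    delta_lower: float
    delta_upper: float
    p_value: float
    n_boot: int
    seed: int
    n_degenerate: int
    level: float = 0.95
    n_cases: int = 0


@dataclass(frozen=True)
class HybridResult:
    """OR-rule combined reader scored against the reference standard."""

    combined_calls: pd.Series  # indexed by case_id; Int8 with NA = unavailable
    confusion: ConfusionTable
    sensitivity: BinomialCI
    specificity: BinomialCI


def _paired_arrays(
    ds: StudyDataset, reader_a: str, reader_b: str, finding: str, case_policy: str
):
    ds.require_reader(reader_a)
    ds.require_reader(reader_b)
    sub = ds.finding_frame(finding)
    a, b = sub[reader_a], sub[reader_b]
    truth = sub["truth"].to_numpy(dtype=np.int64)
    if case_policy == "intersection":
        mask = (a.notna() & b.notna()).to_numpy()
        truth = truth[mask]
        a_codes = a[mask].astype(int).to_numpy() + 2 * truth
        b_codes = b[mask].astype(int).to_numpy() + 2 * truth
    elif case_policy == "per_reader":
        # code 4 marks an unavailable call; such cases still resample but
        # drop out of that reader's 2x2 counts, reproducing the marginal
        # denominators (e.g. 1404 vs 1400 in the motivating study)
        a_codes = np.where(a.isna(), 4, a.fillna(0).astype(int).to_numpy() + 2 * truth)
        b_codes = np.where(b.isna(), 4, b.fillna(0).astype(int).to_numpy() + 2 * truth)
    else:
        raise ValueError(f"unknown case_policy {case_policy!r}")
    return np.asarray(a_codes, dtype=np.int64), np.asarray(b_codes, dtype=np.int64)


def _kappa_from_code_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorised kappa from per-replicate cell counts.

    ``counts`` has shape (n_boot, 4) in code order
    (truth0/call0=tn, truth0/call1=fp, truth1/call0=fn, truth1/call1=tp);
    degenerate replicates (p_e = 1 or empty) come back NaN.
    """
    tn, fp, fn, tp = counts[:, 0], counts[:, 1], counts[:, 2], counts[:, 3]
    n = tn + fp + fn + tp
    with np.errstate(divide="ignore", invalid="ignore"):
        p_o, p_e = _kappa_terms(tp, fp, fn, tn)
        kappa = np.where((n > 0) & (p_e < 1.0), (p_o - p_e) / (1.0 - p_e), np.nan)
    return kappa


def _replicate_counts(codes: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cell counts per bootstrap replicate via offset bincount."""
    n_boot = idx.shape[0]
    cells = codes[idx]  # (n_boot, n) values in 0..4
    offset = 5 * np.arange(n_boot, dtype=np.int64)[:, None]
    flat = (cells + offset).ravel()
    counts = np.bincount(flat, minlength=5 * n_boot).reshape(n_boot, 5)
    return counts[:, :4]  # column 4 = unavailable, excluded from the 2x2


def paired_bootstrap_kappa_diff(
    ds: StudyDataset,
    reader_a: str,
    reader_b: str,
    finding: str,
    n_boot: int = 10_000,
    seed: int = 0,
    case_policy: str = "intersection",
    level: float = 0.95,
) -> KappaComparison:
    """Paired bootstrap for the difference in Cohen's kappa (B minus A).

    Cases are resampled with replacement, preserving both readers' calls
    within each case; kappa_B - kappa_A is computed per replicate.  Returns
    the bootstrap median, the equal-tailed percentile interval and a
    two-sided p-value by interval inversion:

        p = 2 * min(frac(delta <= 0), frac(delta >= 0)),  clamped to
        [1/n_boot, 1],

    so p <= alpha exactly when the (1-alpha) percentile interval excludes 0.
    Replicates with an undefined kappa are dropped from the percentiles and
    counted in ``n_degenerate``; more than 10% degenerate is an error.
    Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    a_codes, b_codes = _paired_arrays(ds, reader_a, reader_b, finding, case_policy)
    n = a_codes.size
    if n < 2:
        raise DatasetError(
            f"need >= 2 cases for finding {finding!r} under policy {case_policy!r}, got {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    kappa_a = _kappa_from_code_counts(_replicate_counts(a_codes, idx))
    kappa_b = _kappa_from_code_counts(_replicate_counts(b_codes, idx))
    delta = kappa_b - kappa_a
    ok = ~np.isnan(delta)
    n_degenerate = int(n_boot - ok.sum())
    if n_degenerate == n_boot:
        raise UndefinedKappaError(
            ConfusionTable(tp=0, fp=0, fn=0, tn=max(n, 1))
        )
    if n_degenerate > MAX_DEGENERATE_FRACTION * n_boot:
        raise DatasetError(
            f"{n_degenerate}/{n_boot} bootstrap replicates have undefined kappa; "
            "the table is too sparse for a percentile bootstrap"
        )
    delta = delta[ok]
    alpha = 1.0 - level
    lo, med, hi = np.quantile(delta, [alpha / 2, 0.5, 1 - alpha / 2])
    frac_le = np.mean(delta <= 0)
    frac_ge = np.mean(delta >= 0)
    p = min(1.0, max(1.0 / n_boot, 2.0 * min(frac_le, frac_ge)))
    return KappaComparison(
        delta_median=float(med),
        delta_lower=float(lo),
        delta_upper=float(hi),
        p_value=float(p),
        n_boot=n_boot,
        seed=seed,
        n_degenerate=n_degenerate,
        level=level,
        n_cases=n,
    )


def hybrid_or(
    ds: StudyDataset,
    reader_a: str,
    reader_b: str,
    finding: str,
    unavailable_policy: str = "drop",
) -> HybridResult:
    """OR-rule combined reader: positive if either reader calls positive.

    When one reader's call is unavailable the available reader decides; when
    both are unavailable the combined call is unavailable and the usual
    ``unavailable_policy`` (drop / count_negative) applies when tallying.
    """
    ds.require_reader(reader_a)
    ds.require_reader(reader_b)
    sub = ds.finding_frame(finding)
    a, b = sub[reader_a], sub[reader_b]
    either_pos = ((a.fillna(0) == 1) | (b.fillna(0) == 1)).to_numpy()
    both_unavail = (a.isna() & b.isna()).to_numpy()
    combined = pd.Series(either_pos.astype("int8"), index=sub.index, dtype="Int8")
    combined[both_unavail] = pd.NA

    tmp = sub[["case_id", "finding", "truth"]].copy()
    tmp["hybrid"] = combined
    combined = combined.set_axis(pd.Index(sub["case_id"], name="case_id"))
    hybrid_ds = StudyDataset(tmp, readers=["hybrid"], findings=[finding])
    from .data_model import confusion_from_calls

    ct = confusion_from_calls(hybrid_ds, "hybrid", finding, unavailable_policy)
    return HybridResult(
        combined_calls=combined,
        confusion=ct,
        sensitivity=sensitivity(ct),
        specificity=specificity(ct),
    )


def finding_seed(base_seed: int, finding: str) -> int:
    """Deterministic per-finding seed, independent of finding order."""
    ss = np.random.SeedSequence([int(base_seed), zlib.crc32(finding.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))


def compare_all(
    ds: StudyDataset,
    reader_a: str,
    reader_b: str,
    n_boot: int = 10_000,
    seed: int = 0,
    case_policy: str = "intersection",
    unavailable_policy: str = "drop",
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-finding kappa comparison plus hybrid reader, one row per finding.

    Each finding draws from its own deterministic seed stream derived from
    ``seed`` and the finding name, so results do not depend on finding
    order.  Per-finding failures are reported in the ``error`` column rather
    than aborting the whole table.
    """
    rows = []
    for finding in ds.findings:
        row: dict = {"finding": finding, "error": None}
        fseed = finding_seed(seed, finding)
        try:
            cmp_ = paired_bootstrap_kappa_diff(
                ds, reader_a, reader_b, finding,
                n_boot=n_boot, seed=fseed, case_policy=case_policy, level=level,
            )
            hyb = hybrid_or(ds, reader_a, reader_b, finding, unavailable_policy)
            row.update(
                delta_median=cmp_.delta_median,
                delta_lower=cmp_.delta_lower,
                delta_upper=cmp_.delta_upper,
                p_value=cmp_.p_value,
                n_boot=cmp_.n_boot,
                seed=cmp_.seed,
                n_degenerate=cmp_.n_degenerate,
                hybrid_sensitivity=hyb.sensitivity.point,
                hybrid_specificity=hyb.specificity.point,
            )
        except (DatasetError, UndefinedKappaError, ValueError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
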