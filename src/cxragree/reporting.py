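"""Report generation: per-finding accuracy, comparison and hybrid tables.

Mirrors the layout of a reader-study report: a prevalence table, a
per-reader accuracy table (sensitivity, specificity, Cohen's kappa with
intervals), a paired-comparison table (bootstrap delta kappa with p-values)
and a hybrid-reader table.  Tables are emitted both as CSV (for machines)
and as a markdown report (for eyeballing); all seeds and policies are
recorded in the bundle metadata so every number is traceable.

Percentages are displayed on the 0-100 scale at 1 decimal place and kappa
at 2 decimal places; computation is at full precision throughout.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from . import __version__
from .accuracy_stats import (
    UndefinedKappaError,
    cohens_kappa,
    kappa_interval,
    prevalence,
    sensitivity,
    specificity,
)
from .data_model import (
    ConfusionTable,
    StudyDataset,
    confusion_from_calls,
    study_confusion_tables,
)
from .reader_comparison import compare_all

__all__ = ["ReportBundle", "roc_auc", "run_pipeline", "accuracy_table_from_confusions"]


@dataclass
class ReportBundle:
    """All tables of one analysis run plus full provenance metadata."""

    prevalence_table: pd.DataFrame
    accuracy_table: pd.DataFrame
    comparison_table: pd.DataFrame | None
    hybrid_table: pd.DataFrame | None
    roc_table: pd.DataFrame | None
    metadata: dict = field(default_factory=dict)


def roc_auc(scores, truth) -> tuple[float, pd.DataFrame]:
    """AUC and ROC points for continuous scores against binary truth.

    AUC is the probability that a random truth-positive case outscores a
    random truth-negative one, ties counted half (the Mann-Whitney
    statistic).  The ROC point sequence is monotone in both coordinates,
    starting at (0,0) and ending at (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have identical shape")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    classes = np.unique(truth)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            f"need at least one positive and one negative case, got classes {classes}"
        )
    auc = float(roc_auc_score(truth, scores))
    fpr, tpr, thresholds = roc_curve(truth, scores)
    pts = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    # roc_curve starts at an artificial threshold = max(score)+1; force the
    # documented (0,0) ... (1,1) envelope explicitly
    if not (pts.iloc[0][["fpr", "tpr"]] == 0).all():
        pts = pd.concat(
            [pd.DataFrame([{"fpr": 0.0, "tpr": 0.0, "threshold": np.inf}]), pts],
            ignore_index=True,
        )
    if not (pts.iloc[-1][["fpr", "tpr"]] == 1).all():
        pts = pd.concat(
            [pts, pd.DataFrame([{"fpr": 1.0, "tpr": 1.0, "threshold": -np.inf}])],
            ignore_index=True,
        )
    return auc, pts


def _accuracy_row(finding: str, reader: str, ct: ConfusionTable, level: float) -> dict:
    se = sensitivity(ct, level)
    sp = specificity(ct, level)
    row = {
        "finding": finding,
        "reader": reader,
        "n": ct.n,
        "tp": ct.tp, "fp": ct.fp, "fn": ct.fn, "tn": ct.tn,
        "sensitivity": se.point, "sensitivity_lower": se.lower, "sensitivity_upper": se.upper,
        "specificity": sp.point, "specificity_lower": sp.lower, "specificity_upper": sp.upper,
    }
    try:
        kap = kappa_interval(ct, method="analytic", level=level)
        row.update(kappa=kap.kappa, kappa_lower=kap.ci[0], kappa_upper=kap.ci[1])
    except UndefinedKappaError:
        row.update(kappa=np.nan, kappa_lower=np.nan, kappa_upper=np.nan)
    return row


def accuracy_table_from_confusions(
    tables: dict[tuple[str, str], ConfusionTable], level: float = 0.95
) -> pd.DataFrame:
    """Accuracy table straight from (finding, reader) -> 2x2 counts."""
    return pd.DataFrame(
        [_accuracy_row(f, r, ct, level) for (f, r), ct in tables.items()]
    )


def _prevalence_table(tables: dict[tuple[str, str], ConfusionTable]) -> pd.DataFrame:
    rows = []
    seen = set()
    for (finding, reader), ct in tables.items():
        if finding in seen:
            continue
        seen.add(finding)
        pr = prevalence(ct)
        rows.append(
            {"finding": finding, "n_positive": ct.truth_positives, "n": ct.n,
             "prevalence": pr.point}
        )
    return pd.DataFrame(rows)


def _fmt_pct(x: float) -> str:
    return f"{100 * x:.1f}"


def _fmt_kappa(x: float) -> str:
    return "NA" if pd.isna(x) else f"{x:.2f}"


def _markdown_table(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "|".join(["---"] * len(cols)) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines)


def _markdown_report(bundle: ReportBundle) -> str:
    md = ["# Reader agreement report", ""]
    meta = bundle.metadata
    md += [
        f"- package: cxragree {meta.get('version')}",
        f"- input: {meta.get('input')}",
        f"- seed: {meta.get('seed')}  n_boot: {meta.get('n_boot')}",
        f"- policies: unavailable={meta.get('unavailable_policy')}, "
        f"case={meta.get('case_policy')}, level={meta.get('level')}",
        "",
        "## Prevalence",
        "",
    ]
    prev = bundle.prevalence_table.copy()
    prev["prevalence %"] = prev["prevalence"].map(_fmt_pct)
    md.append(_markdown_table(prev[["finding", "n_positive", "n", "prevalence %"]]))

    md += ["", "## Accuracy vs reference standard", ""]
    acc = bundle.accuracy_table.copy()
    acc["sensitivity % (CI)"] = acc.apply(
        lambda r: f"{_fmt_pct(r['sensitivity'])} "
        f"({_fmt_pct(r['sensitivity_lower'])}-{_fmt_pct(r['sensitivity_upper'])})",
        axis=1,
    )
    acc["specificity % (CI)"] = acc.apply(
        lambda r: f"{_fmt_pct(r['specificity'])} "
        f"({_fmt_pct(r['specificity_lower'])}-{_fmt_pct(r['specificity_upper'])})",
        axis=1,
    )
    acc["kappa (CI)"] = acc.apply(
        lambda r: _fmt_kappa(r["kappa"])
        if pd.isna(r["kappa"])
        else f"{_fmt_kappa(r['kappa'])} "
        f"({_fmt_kappa(r['kappa_lower'])}-{_fmt_kappa(r['kappa_upper'])})",
        axis=1,
    )
    md.append(
        _markdown_table(
            acc[["finding", "reader", "tp", "fp", "fn", "tn",
                 "sensitivity % (CI)", "specificity % (CI)", "kappa (CI)"]]
        )
    )

    if bundle.comparison_table is not None:
        md += ["", "## Paired bootstrap: difference in Cohen's kappa", ""]
        cmp_ = bundle.comparison_table.copy()
        for c in ("delta_median", "delta_lower", "delta_upper"):
            cmp_[c] = cmp_[c].map(lambda v: "NA" if pd.isna(v) else f"{v:.3f}")
        cmp_["p_value"] = cmp_["p_value"].map(
            lambda v: "NA" if pd.isna(v) else f"{v:.4f}"
        )
        md.append(
            _markdown_table(
                cmp_[["finding", "delta_median", "delta_lower", "delta_upper",
                      "p_value", "n_degenerate", "error"]]
            )
        )
    if bundle.hybrid_table is not None:
        md += ["", "## Hybrid (OR-rule) reader", ""]
        hyb = bundle.hybrid_table.copy()
        for c in ("sensitivity", "specificity"):
            hyb[f"{c} %"] = hyb[c].map(lambda v: "NA" if pd.isna(v) else _fmt_pct(v))
        md.append(
            _markdown_table(
                hyb[["finding", "tp", "fp", "fn", "tn", "sensitivity %", "specificity %"]]
            )
        )
    if bundle.roc_table is not None:
        md += ["", "## ROC / AUC (score-bearing readers)", ""]
        roc = bundle.roc_table.copy()
        roc["auc"] = roc["auc"].map(lambda v: f"{v:.3f}")
        md.append(_markdown_table(roc[["finding", "reader", "auc", "n"]]))
    md.append("")
    return "\n".join(md)


def _hybrid_table(ds, reader_a, reader_b, unavailable_policy) -> pd.DataFrame:
    from .reader_comparison import hybrid_or

    rows = []
    for finding in ds.findings:
        row = {"finding": finding}
        try:
            h = hybrid_or(ds, reader_a, reader_b, finding, unavailable_policy)
            row.update(
                tp=h.confusion.tp, fp=h.confusion.fp, fn=h.confusion.fn, tn=h.confusion.tn,
                sensitivity=h.sensitivity.point, sensitivity_lower=h.sensitivity.lower,
                sensitivity_upper=h.sensitivity.upper,
                specificity=h.specificity.point, specificity_lower=h.specificity.lower,
                specificity_upper=h.specificity.upper, error=None,
            )
        except Exception as exc:  # annotate, don't abort
            row.update(error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def _roc_table(ds: StudyDataset) -> pd.DataFrame | None:
    rows = []
    for reader in ds.readers:
        col = f"{reader}_score"
        if col not in ds.frame.columns:
            continue
        for finding in ds.findings:
            sub = ds.finding_frame(finding)
            mask = sub[col].notna()
            if mask.sum() == 0:
                continue
            truth = sub.loc[mask, "truth"].to_numpy()
            if len(np.unique(truth)) < 2:
                continue
            auc, _ = roc_auc(sub.loc[mask, col].to_numpy(), truth)
            rows.append({"finding": finding, "reader": reader, "auc": auc,
                         "n": int(mask.sum())})
    return pd.DataFrame(rows) if rows else None


def run_pipeline(
    input_csv=None,
    fixture: bool = False,
    sim_config=None,
    outdir=None,
    reader_a: str = "radiologist",
    reader_b: str = "ai",
    n_boot: int = 10_000,
    seed: int = 0,
    case_policy: str = "intersection",
    unavailable_policy: str = "drop",
    level: float = 0.95,
    quiet: bool = False,
) -> ReportBundle:
    """End-to-end analysis from exactly one input source.

    Sources: a per-case CSV (``input_csv``), the packaged trauma-study
    confusion tables (``fixture=True``; marginal tables only, so paired
    comparison and hybrid tables are unavailable), or a
    :class:`~cxragree.synthetic_data.SimulationConfig` (``sim_config``).
    Writes ``accuracy_table.csv``, ``comparison_table.csv``,
    ``hybrid_table.csv``, ``prevalence_table.csv`` and ``report.md`` under
    ``outdir`` when given.  Identical inputs and seed produce byte-identical
    reports.
    """
    sources = sum(x is not None and x is not False for x in (input_csv, fixture, sim_config))
    if sources != 1:
        raise ValueError("exactly one of input_csv / fixture / sim_config is required")

    def log(msg):
        if not quiet:
            print(f"[cxragree] {msg}", file=sys.stderr)

    metadata = {
        "version": __version__,
        "seed": seed,
        "n_boot": n_boot,
        "case_policy": case_policy,
        "unavailable_policy": unavailable_policy,
        "level": level,
        "reader_a": reader_a,
        "reader_b": reader_b,
    }

    if fixture:
        metadata["input"] = "packaged study confusion tables"
        log("loading packaged study confusion tables")
        tables = study_confusion_tables()
        bundle = ReportBundle(
            prevalence_table=_prevalence_table(tables),
            accuracy_table=accuracy_table_from_confusions(tables, level),
            comparison_table=None,
            hybrid_table=None,
            roc_table=None,
            metadata=metadata,
        )
    else:
        if sim_config is not None:
            from .synthetic_data import SimulationConfig, simulate_dataset

            if isinstance(sim_config, dict):
                sim_config = SimulationConfig.from_dict(sim_config)
            ds = simulate_dataset(sim_config)
            metadata["input"] = f"simulation(seed={sim_config.seed})"
            log(f"simulated dataset: {ds.n_cases} cases, findings={ds.findings}")
        else:
            from .data_model import read_dataset

            ds = read_dataset(input_csv)
            metadata["input"] = str(input_csv)
            log(f"read {len(ds)} records from {input_csv}")
        tables = {}
        for finding in ds.findings:
            for reader in ds.readers:
                tables[(finding, reader)] = confusion_from_calls(
                    ds, reader, finding, unavailable_policy
                )
        log(f"bootstrap comparison: n_boot={n_boot}, seed={seed}, policy={case_policy}")
        comparison = compare_all(
            ds, reader_a, reader_b, n_boot=n_boot, seed=seed,
            case_policy=case_policy, unavailable_policy=unavailable_policy, level=level,
        )
        bundle = ReportBundle(
            prevalence_table=_prevalence_table(tables),
            accuracy_table=accuracy_table_from_confusions(tables, level),
            comparison_table=comparison,
            hybrid_table=_hybrid_table(ds, reader_a, reader_b, unavailable_policy),
            roc_table=_roc_table(ds),
            metadata=metadata,
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bundle.prevalence_table.to_csv(outdir / "prevalence_table.csv", index=False)
        bundle.accuracy_table.to_csv(outdir / "accuracy_table.csv", index=False)
        if bundle.comparison_table is not None:
            bundle.comparison_table.to_csv(outdir / "comparison_table.csv", index=False)
        if bundle.hybrid_table is not None:
            bundle.hybrid_table.to_csv(outdir / "hybrid_table.csv", index=False)
        if bundle.roc_table is not None:
            bundle.roc_table.to_csv(outdir / "roc_table.csv", index=False)
        (outdir / "report.md").write_text(_markdown_report(bundle), encoding="utf-8")
        log(f"wrote report to {outdir}")
    return bundle
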