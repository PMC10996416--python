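"""Per-case, per-finding data structures for paired-reader studies.

A study compares one or more *readers* (a human radiologist, an algorithm)
against a reference standard ("ground truth", here the report of a
contemporaneous CT) on a cohort of cases, for a set of binary findings.
Data live in long format: one row per (case, finding), with one call column
per reader.  A reader call can be positive, negative, or *unavailable* --
the last models an algorithm failing to produce output for a case, which in
the motivating trauma chest-radiograph study happened for 4 of 1404
radiographs.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "ReaderCall",
    "CaseRecord",
    "StudyDataset",
    "ConfusionTable",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "confusion_from_calls",
    "study_confusion_tables",
    "STUDY_FINDINGS",
    "STUDY_READERS",
]

RESERVED_COLUMNS = ("case_id", "finding", "truth")
SCORE_SUFFIX = "_score"


class DatasetError(ValueError):
    """Raised for structurally invalid study data."""


class ReaderCall(enum.Enum):
    """A single reader's call on one case for one finding."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNAVAILABLE = "unavailable"

    @classmethod
    def from_cell(cls, cell) -> "ReaderCall":
        if cell is None or pd.isna(cell):
            return cls.UNAVAILABLE
        return cls.POSITIVE if int(cell) == 1 else cls.NEGATIVE

    def to_cell(self):
        if self is ReaderCall.UNAVAILABLE:
            return pd.NA
        return 1 if self is ReaderCall.POSITIVE else 0


@dataclass(frozen=True)
class CaseRecord:
    """One case x one finding: truth label plus every reader's call."""

    case_id: str
    finding: str
    truth: int
    calls: Mapping[str, ReaderCall]
    scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.truth not in (0, 1):
            raise DatasetError(
                f"truth must be 0/1 (case {self.case_id!r}, finding "
                f"{self.finding!r}); the reference standard is never missing"
            )


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of one reader's calls against the reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise DatasetError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise DatasetError("confusion table must contain at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def truth_positives(self) -> int:
        return self.tp + self.fn

    @property
    def truth_negatives(self) -> int:
        return self.tn + self.fp

    @property
    def called_positives(self) -> int:
        return self.tp + self.fp

    def as_array(self):
        import numpy as np

        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


class StudyDataset:
    """A rectangular cohort in long format.

    Internally a pandas DataFrame with columns ``case_id``, ``finding``,
    ``truth``, one nullable-integer column per reader (1 positive, 0
    negative, NA unavailable) and optional ``<reader>_score`` columns.
    """

    def __init__(self, frame: pd.DataFrame, readers: list[str], findings: list[str]):
        self.frame = frame.reset_index(drop=True)
        self.readers = list(readers)
        self.findings = list(findings)
        self._validate()

    def _validate(self):
        df = self.frame
        for col in RESERVED_COLUMNS:
            if col not in df.columns:
                raise DatasetError(f"missing required column {col!r}")
        if not self.readers:
            raise DatasetError("at least one reader column is required")
        for r in self.readers:
            if r not in df.columns:
                raise DatasetError(f"reader column {r!r} missing from frame")
        if df["truth"].isna().any():
            row = int(df.index[df["truth"].isna()][0])
            raise DatasetError(f"truth is missing at row {row}; ground truth may not be NA")
        bad_truth = ~df["truth"].isin([0, 1])
        if bad_truth.any():
            row = int(df.index[bad_truth][0])
            raise DatasetError(f"truth not in {{0,1}} at row {row}")
        unknown = set(df["finding"].unique()) - set(self.findings)
        if unknown:
            raise DatasetError(f"unregistered findings present: {sorted(unknown)}")
        dup = df.duplicated(subset=["case_id", "finding"])
        if dup.any():
            pair = df.loc[df.index[dup][0], ["case_id", "finding"]]
            raise DatasetError(
                f"duplicate (case_id, finding) pair: ({pair['case_id']!r}, {pair['finding']!r})"
            )
        counts = df.groupby("finding", sort=False).size()
        if len(set(counts.values)) > 1 and len(counts) > 0:
            raise DatasetError(
                f"case count differs across findings: {dict(counts)}; the cohort must be rectangular"
            )

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StudyDataset):
            return NotImplemented
        return (
            self.readers == other.readers
            and self.findings == other.findings
            and self.frame.equals(other.frame)
        )

    @property
    def n_cases(self) -> int:
        return self.frame["case_id"].nunique()

    def records(self) -> Iterator[CaseRecord]:
        score_cols = {r: f"{r}{SCORE_SUFFIX}" for r in self.readers}
        for _, row in self.frame.iterrows():
            scores = {
                r: float(row[c])
                for r, c in score_cols.items()
                if c in self.frame.columns and not pd.isna(row[c])
            }
            yield CaseRecord(
                case_id=str(row["case_id"]),
                finding=str(row["finding"]),
                truth=int(row["truth"]),
                calls={r: ReaderCall.from_cell(row[r]) for r in self.readers},
                scores=scores,
            )

    def finding_frame(self, finding: str) -> pd.DataFrame:
        if finding not in self.findings:
            raise DatasetError(f"unknown finding {finding!r}; registered: {self.findings}")
        return self.frame[self.frame["finding"] == finding]

    def require_reader(self, reader: str):
        if reader not in self.readers:
            raise DatasetError(f"unknown reader {reader!r}; registered: {self.readers}")


def _reader_columns(columns) -> list[str]:
    return [
        c
        for c in columns
        if c not in RESERVED_COLUMNS and not c.endswith(SCORE_SUFFIX)
    ]


def read_dataset(path, *, sep: str = ",") -> StudyDataset:
    """Read a long-format per-case CSV into a validated :class:`StudyDataset`.

    Expected header: ``case_id,finding,truth,<reader>[,<reader>...]`` with
    optional ``<reader>_score`` columns.  Truth cells must be 0/1 (or
    true/false); reader cells 0/1/NA.  Errors name the offending CSV line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            dtype={"case_id": str, "finding": str},
            keep_default_na=True,
            na_values=["NA"],
        )
    except pd.errors.ParserError as exc:
        raise DatasetError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing required column(s) {missing}")
    readers = _reader_columns(df.columns)
    if not readers:
        raise DatasetError(f"{path}: no reader columns found")

    def _line(i: int) -> int:
        return i + 2  # header occupies line 1

    truth_raw = df["truth"]
    if truth_raw.isna().any():
        i = int(df.index[truth_raw.isna()][0])
        raise DatasetError(f"{path} line {_line(i)}: truth is NA; ground truth is required")
    truth = truth_raw.map(_coerce_binary)
    if truth.isna().any():
        i = int(df.index[truth.isna()][0])
        raise DatasetError(
            f"{path} line {_line(i)}: truth value {truth_raw.iloc[i]!r} not in 0/1/true/false"
        )
    df["truth"] = truth.astype("int8")

    for r in readers:
        coerced = df[r].map(_coerce_binary, na_action="ignore")
        bad = coerced.isna() & df[r].notna()
        if bad.any():
            i = int(df.index[bad][0])
            raise DatasetError(
                f"{path} line {_line(i)}: reader {r!r} value {df[r].iloc[i]!r} not in 0/1/NA"
            )
        df[r] = coerced.astype("Int8")
    for c in df.columns:
        if c.endswith(SCORE_SUFFIX):
            df[c] = pd.to_numeric(df[c], errors="raise").astype("float64")

    dup = df.duplicated(subset=["case_id", "finding"])
    if dup.any():
        i = int(df.index[dup][0])
        raise DatasetError(
            f"{path} line {_line(i)}: duplicate (case_id, finding) = "
            f"({df['case_id'].iloc[i]!r}, {df['finding'].iloc[i]!r})"
        )
    findings = list(pd.unique(df["finding"]))
    return StudyDataset(df, readers=readers, findings=findings)


def _coerce_binary(v):
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("1", "true"):
            return 1
        if s in ("0", "false"):
            return 0
        return None
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    if f in (0.0, 1.0):
        return int(f)
    return None


def write_dataset(ds: StudyDataset, path) -> Path:
    """Write ``ds`` as CSV; ``read_dataset(write_dataset(ds))`` round-trips."""
    path = Path(path)
    df = ds.frame.copy()
    buf = io.StringIO()
    df.to_csv(buf, index=False, na_rep="NA")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def confusion_from_calls(
    ds: StudyDataset,
    reader: str,
    finding: str,
    unavailable_policy: str = "drop",
) -> ConfusionTable:
    """Tally one reader's calls against truth for one finding.

    unavailable_policy:
        ``drop``
            exclude cases where the reader produced no output (the study's
            treatment of the 4 unprocessable radiographs: AI denominators
            shrink to 1400);
        ``count_negative``
            coerce unavailable to negative (a deployed triage system's
            failure is operationally a miss).
    """
    ds.require_reader(reader)
    sub = ds.finding_frame(finding)
    calls = sub[reader]
    truth = sub["truth"]
    if unavailable_policy == "drop":
        mask = calls.notna()
        calls, truth = calls[mask], truth[mask]
    elif unavailable_policy == "count_negative":
        calls = calls.fillna(0)
    else:
        raise ValueError(f"unknown unavailable_policy {unavailable_policy!r}")
    if len(calls) == 0:
        raise DatasetError(
            f"no contributing cases for reader {reader!r}, finding {finding!r} "
            f"under policy {unavailable_policy!r}"
        )
    c = calls.astype(int).to_numpy()
    t = truth.astype(int).to_numpy()
    return ConfusionTable(
        tp=int(((t == 1) & (c == 1)).sum()),
        fp=int(((t == 0) & (c == 1)).sum()),
        fn=int(((t == 1) & (c == 0)).sum()),
        tn=int(((t == 0) & (c == 0)).sum()),
    )


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

STUDY_READERS = ("radiologist", "ai")

STUDY_FINDINGS = (
    "pneumothorax",
    "pneumomediastinum",
    "rib_fracture",
    "clavicle_fracture",
    "humerus_fracture",
    "scapula_fracture",
    "lobar_segmental_collapse",
)

# Published 2x2 counts from a single-centre blunt-trauma cohort of 1404
# supine chest radiographs read both by the reporting radiologist and by a
# commercial deep-learning algorithm, each scored against the contemporaneous
# CT report.  Four radiographs could not be processed by the algorithm, so
# its denominators are 1400.  Cells are (tp, fp, fn, tn).
_STUDY_TABLES: dict[tuple[str, str], tuple[int, int, int, int]] = {
    ("pneumothorax", "radiologist"): (57, 8, 115, 1224),
    ("pneumothorax", "ai"): (67, 2, 104, 1227),
    ("pneumomediastinum", "radiologist"): (3, 1, 24, 1376),
    ("pneumomediastinum", "ai"): (3, 0, 24, 1373),
    ("rib_fracture", "radiologist"): (113, 13, 236, 1042),
    ("rib_fracture", "ai"): (143, 75, 205, 977),
    ("clavicle_fracture", "radiologist"): (43, 3, 36, 1322),
    ("clavicle_fracture", "ai"): (44, 37, 35, 1284),
    ("humerus_fracture", "radiologist"): (21, 2, 10, 1371),
    ("humerus_fracture", "ai"): (10, 8, 21, 1361),
    ("scapula_fracture", "radiologist"): (15, 5, 40, 1344),
    ("scapula_fracture", "ai"): (19, 64, 36, 1281),
    ("lobar_segmental_collapse", "radiologist"): (4, 1, 33, 1366),
    ("lobar_segmental_collapse", "ai"): (13, 21, 23, 1343),
}


def study_confusion_tables() -> dict[tuple[str, str], ConfusionTable]:
    """The packaged trauma-cohort confusion tables, keyed by (finding, reader).

    Seven findings x two readers.  Radiologist tables each total 1404 cases;
    algorithm tables total 1400 (four unprocessable radiographs dropped).
    """
    return {
        key: ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
        for key, (tp, fp, fn, tn) in _STUDY_TABLES.items()
    }
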