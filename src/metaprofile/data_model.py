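"""Domain types, validation and tabular I/O for cross-study summary data.

The canonical on-disk form is *long*: one row per (study, indicator, arm)
with columns ``study_id, indicator, arm, mean, sd, n``. Each row carries the
per-arm summary statistics a meta-analysis of continuous outcomes consumes.
A wide-format convertor is provided for spreadsheets that store indicators
as ``<indicator>_Baseline`` / ``<indicator>_Follow-up`` column groups.

Missing values (empty cells or ``NA``) are loaded as missing markers, never
dropped silently; :func:`read_dataset` returns a load report listing them.
"""

from __future__ import annotations

import enum
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("study_id", "indicator", "arm", "mean", "sd", "n")

_WS = re.compile(r"\s+")


class DataError(ValueError):
    """Base class for structured dataset errors."""


class MissingColumnError(DataError):
    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"missing required column(s): {', '.join(self.columns)}")


class DuplicateMeasurementError(DataError):
    def __init__(self, keys: Sequence[tuple]):
        self.keys = list(keys)
        super().__init__(
            "duplicate (study_id, indicator, arm) rows: "
            + "; ".join(map(str, self.keys))
        )


class NotFoundError(DataError, KeyError):
    pass


class Arm(enum.Enum):
    """Measurement arm of a two-arm study contrast.

    Longitudinal studies report baseline and follow-up arms; parallel-group
    studies (control vs experimental) are mapped onto the same two slots,
    control -> BASELINE and experimental -> FOLLOWUP, with the original role
    preserved in :attr:`IndicatorMeasurement.arm_role`.
    """

    BASELINE = "baseline"
    FOLLOWUP = "followup"


#: accepted spellings -> (Arm, arm_role)
_ARM_ALIASES = {
    "baseline": (Arm.BASELINE, "longitudinal"),
    "follow-up": (Arm.FOLLOWUP, "longitudinal"),
    "followup": (Arm.FOLLOWUP, "longitudinal"),
    "follow_up": (Arm.FOLLOWUP, "longitudinal"),
    "control": (Arm.BASELINE, "parallel"),
    "experimental": (Arm.FOLLOWUP, "parallel"),
}


def parse_arm(label: str) -> tuple[Arm, str]:
    key = _WS.sub("", str(label)).lower()
    try:
        return _ARM_ALIASES[key]
    except KeyError:
        raise DataError(f"unrecognized arm label: {label!r}") from None


class Design(enum.Enum):
    RCT = "RCT"
    CT = "CT"


class Intervention(enum.Enum):
    MECHANICAL = "mechanical"
    PHYSICAL = "physical"
    DRUG = "drug"
    PSYCHOLOGICAL = "psychological"
    OTHER = "other"


def normalize_indicator(name: str) -> str:
    """Whitespace-normalize an indicator name; matching stays case-sensitive.

    Distinct clinical terms (e.g. "AHI-REM" vs "AHI") are deliberately kept
    distinct: no synonym merging.
    """
    return _WS.sub(" ", str(name)).strip()


@dataclass(frozen=True)
class IndicatorMeasurement:
    """One (study, indicator, arm) summary: mean, SD and sample size.

    ``mean``/``sd`` may be NaN and ``n`` may be None to represent missing
    entries extracted from a publication.
    """

    study_id: str
    indicator: str
    arm: Arm
    mean: float
    sd: float
    n: int | None
    arm_role: str = "longitudinal"

    @property
    def complete(self) -> bool:
        return (
            _is_num(self.mean)
            and _is_num(self.sd)
            and self.n is not None
            and self.n >= 1
        )


@dataclass(frozen=True)
class StudyMeta:
    """Per-study metadata; only ``study_id`` is required."""

    study_id: str
    design: Design | None = None
    region: str | None = None
    year: int | None = None
    n_total: int | None = None
    n_male: int | None = None
    n_female: int | None = None
    intervention: Intervention | None = None


def _is_num(x) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class ArmSummary:
    mean: float
    sd: float
    n: int | None

    @property
    def complete(self) -> bool:
        return _is_num(self.mean) and _is_num(self.sd) and self.n is not None


@dataclass(frozen=True)
class PairedSeries:
    """Baseline and follow-up arm summaries for one (study, indicator).

    ``complete`` is true iff all six numbers (two means, two SDs, two sample
    sizes) are present; meta-analyses exclude incomplete series.
    """

    study_id: str
    indicator: str
    baseline: ArmSummary | None
    followup: ArmSummary | None

    @property
    def complete(self) -> bool:
        return (
            self.baseline is not None
            and self.followup is not None
            and self.baseline.complete
            and self.followup.complete
        )


@dataclass
class Dataset:
    """A cross-study collection of indicator measurements plus study metadata.

    ``T_s`` (the number of included studies) is the denominator of the
    indicator coverage ratio and is derived from the study table.
    """

    measurements: list[IndicatorMeasurement]
    studies: dict[str, StudyMeta] = field(default_factory=dict)

    def __post_init__(self):
        if not self.studies:
            self.studies = {
                m.study_id: StudyMeta(m.study_id) for m in self.measurements
            }
        missing = {m.study_id for m in self.measurements} - set(self.studies)
        if missing:
            raise DataError(f"measurements reference unknown studies: {sorted(missing)}")
        seen: set[tuple] = set()
        dups = []
        for m in self.measurements:
            key = (m.study_id, m.indicator, m.arm)
            if key in seen:
                dups.append((m.study_id, m.indicator, m.arm.value))
            seen.add(key)
        if dups:
            raise DuplicateMeasurementError(dups)
        self._index = {
            (m.study_id, m.indicator, m.arm): m for m in self.measurements
        }

    @property
    def T_s(self) -> int:
        return len(self.studies)

    @property
    def study_ids(self) -> list[str]:
        return sorted(self.studies)

    @property
    def indicators(self) -> list[str]:
        return sorted({m.indicator for m in self.measurements})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "study_id": m.study_id,
                "indicator": m.indicator,
                "arm": m.arm.value,
                "mean": m.mean,
                "sd": m.sd,
                "n": m.n,
                "arm_role": m.arm_role,
            }
            for m in self.measurements
        ]
        return pd.DataFrame(
            rows, columns=["study_id", "indicator", "arm", "mean", "sd", "n", "arm_role"]
        )


@dataclass
class LoadReport:
    """Rows whose numeric fields failed to parse (kept, with missing markers)."""

    unparseable: list[dict] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.unparseable


@dataclass
class ValidationIssue:
    kind: str
    study_id: str | None = None
    indicator: str | None = None
    arm: str | None = None
    detail: str = ""

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v not in (None, "")}


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.issues

    def count(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self.issues)
        return sum(1 for i in self.issues if i.kind == kind)

    def to_json(self, **kwargs) -> str:
        return json.dumps([i.to_dict() for i in self.issues], **kwargs)


def _parse_num(value, errors: list[str]):
    """Parse one numeric cell; empty/NA -> NaN, junk -> NaN + error note."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    s = str(value).strip()
    if s == "" or s.upper() in {"NA", "N/A", "NAN"}:
        return math.nan
    try:
        return float(s)
    except ValueError:
        errors.append(s)
        return math.nan


def dataset_from_frame(df: pd.DataFrame) -> tuple[Dataset, LoadReport]:
    """Build a validated :class:`Dataset` from a long-format dataframe."""
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise MissingColumnError(missing_cols)
    report = LoadReport()
    measurements = []
    for idx, row in df.iterrows():
        errs: list[str] = []
        arm, role = parse_arm(row["arm"])
        if "arm_role" in df.columns and _is_num_or_str(row.get("arm_role")):
            role = str(row["arm_role"])
        mean = _parse_num(row["mean"], errs)
        sd = _parse_num(row["sd"], errs)
        n_val = _parse_num(row["n"], errs)
        n = int(n_val) if _is_num(n_val) else None
        if errs:
            report.unparseable.append(
                {"row": int(idx), "study_id": str(row["study_id"]),
                 "indicator": str(row["indicator"]), "bad_values": errs}
            )
        measurements.append(
            IndicatorMeasurement(
                study_id=str(row["study_id"]).strip(),
                indicator=normalize_indicator(row["indicator"]),
                arm=arm,
                mean=mean,
                sd=sd,
                n=n,
                arm_role=role,
            )
        )
    return Dataset(measurements), report


def _is_num_or_str(x) -> bool:
    if x is None:
        return False
    if isinstance(x, float) and math.isnan(x):
        return False
    return str(x).strip() != ""


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    return {"tsv": "tsv", "txt": "tsv", "xlsx": "xlsx"}.get(suffix, "csv")


def read_dataset(
    path: str | Path,
    format: str | None = None,
    with_report: bool = False,
) -> Dataset | tuple[Dataset, LoadReport]:
    """Read a long-format CSV/TSV/XLSX file into a validated :class:`Dataset`.

    Rows with unparseable numerics are loaded with missing markers and listed
    in the load report (``with_report=True`` to receive it).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
    elif fmt == "xlsx":
        df = pd.read_excel(path, dtype=str)
    else:
        raise DataError(f"unknown format: {fmt!r}")
    ds, report = dataset_from_frame(df)
    return (ds, report) if with_report else ds


def write_dataset(ds: Dataset, path: str | Path, format: str | None = None) -> None:
    """Write a dataset in the canonical long format (CSV/TSV/XLSX)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    df = ds.to_frame()
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise DataError(f"unknown format: {fmt!r}")


_WIDE_SUFFIXES = {"_Baseline": "baseline", "_Follow-up": "followup"}


def wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a wide extraction sheet to the canonical long format.

    Expects a ``study_id`` column plus column triples named
    ``<indicator>_<Baseline|Follow-up>_<mean|sd|n>``. Returns a long dataframe
    suitable for :func:`dataset_from_frame`.
    """
    if "study_id" not in df.columns:
        raise MissingColumnError(["study_id"])
    groups: dict[tuple[str, str], dict[str, str]] = {}
    for col in df.columns:
        if col == "study_id":
            continue
        m = re.match(r"^(.*)_(Baseline|Follow-up)_(mean|sd|n)$", col)
        if not m:
            raise DataError(f"unrecognized wide column: {col!r}")
        ind, arm_label, stat = m.groups()
        groups.setdefault((ind, arm_label), {})[stat] = col
    rows = []
    for _, r in df.iterrows():
        for (ind, arm_label), cols in groups.items():
            vals = {stat: r.get(c) for stat, c in cols.items()}
            if all(not _is_num_or_str(v) for v in vals.values()):
                continue  # indicator not reported by this study
            rows.append(
                {
                    "study_id": r["study_id"],
                    "indicator": ind,
                    "arm": arm_label,
                    "mean": vals.get("mean"),
                    "sd": vals.get("sd"),
                    "n": vals.get("n"),
                }
            )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Report-only integrity checks: negative SDs, n < 1, unpaired arms.

    Orphan study ids cannot occur in a constructed :class:`Dataset` (the
    constructor rejects them) but the check is retained for reports built
    from partially assembled inputs.
    """
    report = ValidationReport()
    for m in ds.measurements:
        if _is_num(m.sd) and m.sd < 0:
            report.issues.append(
                ValidationIssue("negative_sd", m.study_id, m.indicator, m.arm.value,
                                f"sd={m.sd}")
            )
        if m.n is not None and m.n < 1:
            report.issues.append(
                ValidationIssue("nonpositive_n", m.study_id, m.indicator, m.arm.value,
                                f"n={m.n}")
            )
        if m.study_id not in ds.studies:
            report.issues.append(
                ValidationIssue("orphan_study", m.study_id, m.indicator, m.arm.value)
            )
    pairs: dict[tuple[str, str], set[Arm]] = {}
    for m in ds.measurements:
        pairs.setdefault((m.study_id, m.indicator), set()).add(m.arm)
    for (sid, ind), arms in sorted(pairs.items()):
        if len(arms) == 1:
            only = next(iter(arms))
            report.issues.append(
                ValidationIssue("unpaired_arm", sid, ind, only.value,
                                "partner arm absent")
            )
    return report


def presence_matrix(ds: Dataset) -> pd.DataFrame:
    """Binary study x indicator matrix: 1 iff the study reports the indicator
    in at least one arm. Empty dataset -> 0x0 frame."""
    studies = ds.study_ids
    indicators = ds.indicators
    mat = pd.DataFrame(0, index=studies, columns=indicators, dtype=int)
    for m in ds.measurements:
        mat.loc[m.study_id, m.indicator] = 1
    return mat


def paired_series(ds: Dataset, study_id: str, indicator: str) -> PairedSeries:
    """Both arm summaries for one (study, indicator); ``complete`` is false
    whenever any of the six numbers is missing."""
    if study_id not in ds.studies:
        raise NotFoundError(f"unknown study_id: {study_id!r}")
    if indicator not in set(ds.indicators):
        raise NotFoundError(f"unknown indicator: {indicator!r}")
    idx = ds._index
    out = {}
    for arm in Arm:
        m = idx.get((study_id, indicator, arm))
        out[arm] = None if m is None else ArmSummary(m.mean, m.sd, m.n)
    return PairedSeries(study_id, indicator, out[Arm.BASELINE], out[Arm.FOLLOWUP])
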