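"""Patient-level cohort tables: reading, validation, stratification and the
covariate transformations shared by every downstream stage.

A cohort is one row per patient with a follow-up duration (months), a binary
event indicator (1 = death from disease, 0 = censored), age at diagnosis
(years), tumor size (cm), the count of involved lymph nodes and optional
categorical labels (marital status, surgery type, AJCC stage, metastasis
status).  Internally all durations are in months; readers accept a unit flag
and convert days with 30.44 days/month.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, DataError

DAYS_PER_MONTH = 30.44

#: canonical column names; the first five are required
CORE_COLUMNS = ("time", "event", "age", "tumor_size", "n_nodes")
OPTIONAL_COLUMNS = ("marital", "surgery", "stage", "metastasis")


@dataclass(frozen=True)
class StandardizationParams:
    """Mean/SD used to turn age into a z-score (cohort defaults 47.04/10.70)."""

    mean_age: float
    sd_age: float

    def __post_init__(self) -> None:
        if not self.sd_age > 0:
            raise ConfigurationError("sd_age must be strictly positive")


@dataclass(frozen=True)
class PatientRecord:
    time: float
    event: int
    age: float
    tumor_size: float
    n_nodes: int
    marital: str | None = None
    surgery: str | None = None
    stage: str | None = None
    metastasis: str | None = None


@dataclass
class ValidationReport:
    """Per-row account of what a reader rejected and why."""

    n_read: int = 0
    n_valid: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def to_text(self) -> str:
        lines = [
            f"rows read: {self.n_read}",
            f"rows valid: {self.n_valid}",
            f"rows rejected: {self.n_rejected}",
        ]
        lines += [f"  row {i}: {reason}" for i, reason in self.rejected]
        return "\n".join(lines)


@dataclass
class Cohort:
    """A validated cohort. ``frame`` holds canonical columns; ``provenance``
    records where it came from (path, or generator config hash)."""

    frame: pd.DataFrame
    provenance: str = ""
    validation: ValidationReport | None = None

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise DataError("cohort is empty")
        missing = [c for c in CORE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"cohort frame lacks columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    def records(self) -> Iterator[PatientRecord]:
        for row in self.frame.itertuples(index=False):
            yield PatientRecord(
                time=float(row.time),
                event=int(row.event),
                age=float(row.age),
                tumor_size=float(row.tumor_size),
                n_nodes=int(row.n_nodes),
                **{
                    c: getattr(row, c, None)
                    for c in OPTIONAL_COLUMNS
                    if c in self.frame.columns
                },
            )


def _row_problems(df: pd.DataFrame, age_range: tuple[float, float]) -> pd.Series:
    """Return a string reason per invalid row ('' where valid)."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        sel = mask & (reasons == "")
        reasons[sel] = reason

    core = df[list(CORE_COLUMNS)]
    flag(core.isna().any(axis=1), "missing value in a required column")
    flag(~(df["time"] > 0), "time must be > 0")
    flag(~df["event"].isin([0, 1]), "event must be 0 or 1")
    flag(
        ~df["age"].between(age_range[0], age_range[1]),
        f"age outside plausible range {age_range}",
    )
    flag(~(df["tumor_size"] > 0), "tumor_size must be > 0")
    flag(~(df["n_nodes"] >= 0), "n_nodes must be >= 0")
    flag(df["n_nodes"] % 1 != 0, "n_nodes must be an integer count")
    return reasons


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | str | Path | None = None,
    *,
    unit: str = "months",
    age_range: tuple[float, float] = (18.0, 100.0),
    sep: str | None = None,
) -> Cohort:
    """Read a delimited cohort table, validate it row by row, and return the
    valid rows as a :class:`Cohort`.

    Parameters
    ----------
    path:
        Delimited text file (CSV/TSV) with a header row.
    column_map:
        Mapping from canonical names (``time``, ``event``, ``age``,
        ``tumor_size``, ``n_nodes``, optionally the categorical columns and
        ``unit``) to the file's column names, or a path to a YAML/JSON file
        holding such a mapping.  Omitted canonical names are assumed to match.
    unit:
        ``"months"`` (default) or ``"days"``; days are divided by 30.44.
        A ``unit`` key inside ``column_map`` overrides this argument.

    Rows violating the record invariants are dropped and reported in the
    returned cohort's ``validation`` report (listwise deletion, logged).
    """
    path = Path(path)
    if isinstance(column_map, (str, Path)):
        with open(column_map) as fh:
            column_map = yaml.safe_load(fh)
    column_map = dict(column_map or {})
    unit = str(column_map.pop("unit", unit)).lower()
    if unit not in ("months", "days"):
        raise ConfigurationError(f"unknown time unit {unit!r}")

    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep)

    rename = {v: k for k, v in column_map.items()}
    missing = [v for v in column_map.values() if v not in raw.columns]
    if missing:
        raise ConfigurationError(f"mapped column(s) not in file: {missing}")
    df = raw.rename(columns=rename)
    absent = [c for c in CORE_COLUMNS if c not in df.columns]
    if absent:
        raise ConfigurationError(
            f"required column(s) {absent} not present; supply a column_map"
        )

    keep = [c for c in CORE_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].copy()
    for c in CORE_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if unit == "days":
        df["time"] = df["time"] / DAYS_PER_MONTH

    reasons = _row_problems(df, age_range)
    report = ValidationReport(n_read=len(df))
    bad = reasons != ""
    report.rejected = [(int(i), r) for i, r in reasons[bad].items()]
    df = df[~bad].reset_index(drop=True)
    report.n_valid = len(df)
    if report.n_valid == 0:
        raise DataError("no valid rows after validation")
    df["event"] = df["event"].astype(int)
    df["n_nodes"] = df["n_nodes"].astype(int)
    return Cohort(frame=df, provenance=str(path), validation=report)


def write_cohort(cohort: Cohort, path: str | Path, *, sep: str | None = None) -> None:
    """Re-export a cohort in the same delimited format ``read_cohort`` reads."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    cohort.frame.to_csv(path, sep=sep, index=False)


def standardize_age(
    age: float | np.ndarray, params: StandardizationParams
) -> float | np.ndarray:
    """Age z-score ``(age - mean)/sd``.  The squared-age covariate used in the
    regression model is the square of this z-score."""
    return (np.asarray(age, dtype=float) - params.mean_age) / params.sd_age


def design_matrix(
    frame: pd.DataFrame | Cohort, params: StandardizationParams
) -> np.ndarray:
    """Model matrix ``(1, z^2, z, tumor_size, n_nodes)`` with z the age z-score."""
    if isinstance(frame, Cohort):
        frame = frame.frame
    z = standardize_age(frame["age"].to_numpy(float), params)
    return np.column_stack(
        [
            np.ones(len(frame)),
            z**2,
            z,
            frame["tumor_size"].to_numpy(float),
            frame["n_nodes"].to_numpy(float),
        ]
    )


# Stratification bands follow the printed labels of the source cohort's
# descriptive table: boundary ages of exactly 50 fall in the older stratum,
# tumors of exactly 2 (5) cm in the 2-5 cm band, node counts of 2 (7) in the
# lower (upper) band.
_BAND_SCHEMES: dict[str, tuple[str, list[tuple[float, float, str]]]] = {
    "age": ("age", [(-np.inf, 50.0, "<50"), (50.0, np.inf, ">=50")]),
    "tumor_size": (
        "tumor_size",
        [(-np.inf, 2.0, "<2 cm"), (2.0, 5.0 + 1e-12, "2-5 cm"), (5.0 + 1e-12, np.inf, ">5 cm")],
    ),
    "n_nodes": (
        "n_nodes",
        [(-np.inf, 3.0, "<=2"), (3.0, 7.0, "3-6"), (7.0, np.inf, ">=7")],
    ),
}
_CATEGORICAL_SCHEMES = set(OPTIONAL_COLUMNS)

STRATIFICATION_VARIABLES = tuple(_BAND_SCHEMES) + tuple(_CATEGORICAL_SCHEMES)


def stratum_labels(cohort: Cohort | pd.DataFrame, variable: str) -> pd.Series:
    """Per-row stratum label for one of the supported schemes."""
    frame = cohort.frame if isinstance(cohort, Cohort) else cohort
    if variable in _BAND_SCHEMES:
        col, bands = _BAND_SCHEMES[variable]
        x = frame[col].to_numpy(float)
        labels = pd.Series("", index=frame.index, dtype=object)
        for lo, hi, name in bands:
            labels[(x >= lo) & (x < hi)] = name
        return labels
    if variable in _CATEGORICAL_SCHEMES:
        if variable not in frame.columns:
            raise ConfigurationError(f"cohort has no column {variable!r}")
        return frame[variable].astype(object)
    raise ConfigurationError(
        f"unknown stratification variable {variable!r}; "
        f"choose one of {STRATIFICATION_VARIABLES}"
    )


def stratify(cohort: Cohort, variable: str) -> dict[str, Cohort | None]:
    """Partition a cohort by one stratification scheme.

    Every record lands in exactly one stratum.  Declared band levels with no
    records are present in the result, mapped to ``None`` (a ``Cohort`` cannot
    be empty).
    """
    labels = stratum_labels(cohort, variable)
    if variable in _BAND_SCHEMES:
        declared: Sequence[str] = [name for *_, name in _BAND_SCHEMES[variable][1]]
    else:
        declared = list(pd.unique(labels.dropna()))
    out: dict[str, Cohort | None] = {}
    for name in declared:
        sub = cohort.frame[labels == name]
        out[name] = (
            Cohort(
                frame=sub.reset_index(drop=True),
                provenance=f"{cohort.provenance}[{variable}={name}]",
            )
            if len(sub)
            else None
        )
    return out


def config_hash(obj) -> str:
    """Short stable hash used as generator provenance."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]
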