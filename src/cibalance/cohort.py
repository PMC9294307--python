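"""Cohort ingest, demographic summaries, and session time-bin assignment.

The study cohort is 13 adolescents with early-onset bilateral deafness who
received a right-ear cochlear implant (CI-1) in early childhood and a left-ear
implant (CI-2) roughly a decade later. Recording sessions after CI-2
activation are grouped into four categorical time bins (weeks 1–2, months
1–2, months 3–4, months 6–14) whose boundaries are configurable; the defaults
sit midway between the mean days-since-activation of adjacent bins so that
every reported session mean ± SD falls inside its bin.
"""

from __future__ import annotations

from enum import Enum
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "TimeBin",
    "NOT_AVAILABLE",
    "NUMERIC_COLUMNS",
    "load_cohort",
    "packaged_cohort",
    "summarize_cohort",
    "assign_time_bin",
    "validate_cohort",
]

NOT_AVAILABLE = "Not available"

NUMERIC_COLUMNS = [
    "age_onset_deafness",
    "duration_bilateral_deafness",
    "age_ci1",
    "age_ci2",
    "inter_implant_delay",
]

REQUIRED_COLUMNS = ["participant_id"] + NUMERIC_COLUMNS + [
    "electrode_array_ci1",
    "electrode_array_ci2",
    "etiology",
]


class TimeBin(str, Enum):
    """Categorical time since CI-2 activation."""

    WEEKS_1_2 = "weeks_1_2"
    MONTHS_1_2 = "months_1_2"
    MONTHS_3_4 = "months_3_4"
    MONTHS_6_14 = "months_6_14"

    @property
    def order(self) -> int:
        return list(TimeBin).index(self)


#: Bin edges in days since activation: [0,21] / (21,75] / (75,135] / (135,inf)
DEFAULT_BIN_EDGES = (21.0, 75.0, 135.0)


def assign_time_bin(days_since_activation: float,
                    edges: tuple = DEFAULT_BIN_EDGES) -> TimeBin:
    """Map days since CI-2 activation to a categorical time bin.

    Deterministic, exhaustive and non-overlapping for days ≥ 0. Raises
    ``ValueError`` for negative days.
    """
    d = float(days_since_activation)
    if d < 0:
        raise ValueError(f"days_since_activation must be >= 0, got {d}")
    e1, e2, e3 = edges
    if d <= e1:
        return TimeBin.WEEKS_1_2
    if d <= e2:
        return TimeBin.MONTHS_1_2
    if d <= e3:
        return TimeBin.MONTHS_3_4
    return TimeBin.MONTHS_6_14


def _parse_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    for col in NUMERIC_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: malformed numeric cell in column '{col}', row {row}"
                f" (value {df[col].iloc[row]!r})"
            )
        df[col] = parsed
    return df


def validate_cohort(df: pd.DataFrame, *, delay_tol: float = 0.05) -> None:
    """Check the structural invariants of a cohort table.

    CI-2 always follows CI-1, durations are non-negative, and the printed
    inter-implant delay agrees with ``age_ci2 − age_ci1`` within ``delay_tol``
    years (printed values are rounded to 2 decimals).
    """
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValueError(f"duplicate participant_id: {dup!r}")
    if (df["age_ci1"] < 0).any() or (df[NUMERIC_COLUMNS] < 0).any().any():
        raise ValueError("ages and durations must be non-negative")
    if (df["age_ci2"] <= df["age_ci1"]).any():
        raise ValueError("age_ci2 must exceed age_ci1 for every participant")
    recon = df["age_ci2"] - df["age_ci1"]
    off = (recon - df["inter_implant_delay"]).abs()
    if (off > delay_tol).any():
        pid = df.loc[off.idxmax(), "participant_id"]
        raise ValueError(
            f"inter_implant_delay inconsistent with age_ci2 - age_ci1 for "
            f"participant {pid!r} (|diff| = {off.max():.3f} y)"
        )


def load_cohort(path, *, sep=None) -> pd.DataFrame:
    """Load a participant table from delimited text (comma or tab).

    Returns records sorted ascending by age at CI-1. Missing electrode-array
    entries are kept as the explicit sentinel ``"Not available"``.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                     skip_blank_lines=True)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: cohort table has no rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = _parse_numeric(df, path)
    for col in ("electrode_array_ci1", "electrode_array_ci2", "etiology"):
        df[col] = df[col].fillna(NOT_AVAILABLE).replace("", NOT_AVAILABLE)
    validate_cohort(df)
    df = df.sort_values("age_ci1", kind="stable").reset_index(drop=True)
    return df


def packaged_cohort() -> pd.DataFrame:
    """The packaged 13-participant cohort fixture."""
    ref = resources.files("cibalance").joinpath("data/table1.csv")
    with resources.as_file(ref) as p:
        return load_cohort(p)


def summarize_cohort(cohort: pd.DataFrame, *, decimals: int = 2) -> pd.DataFrame:
    """Per-column mean and sample SD (n−1 denominator), to 2 decimals.

    Mirrors the cohort table's summary row convention: ``Mean (SD)`` over the
    numeric demographic columns.
    """
    if len(cohort) < 2:
        raise ValueError("summarize_cohort needs at least 2 records")
    rows = {}
    for col in NUMERIC_COLUMNS:
        vals = cohort[col].to_numpy(float)
        rows[col] = {
            "mean": round(float(np.mean(vals)), decimals),
            "sd": round(float(np.std(vals, ddof=1)), decimals),
            "n": int(vals.size),
        }
    return pd.DataFrame(rows).T[["mean", "sd", "n"]]


def flag_duplicate_bins(sessions: pd.DataFrame) -> pd.DataFrame:
    """Flag participants with more than one session in the same time bin.

    ``sessions`` needs columns ``participant_id`` and ``days_since_activation``.
    Returns the offending rows (empty frame when none); duplicates are
    reported, never silently dropped.
    """
    s = sessions.copy()
    s["time_bin"] = [assign_time_bin(d).value
                     for d in s["days_since_activation"]]
    dup = s.duplicated(subset=["participant_id", "time_bin"], keep=False)
    return s.loc[dup]
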