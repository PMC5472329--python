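"""Cohort file handling, sample construction and descriptive statistics.

Reads delimited-text cohort files, applies the analysis inclusion rules
(first CD4 count inside the follow-up window, CD4 measured before ART
start), and computes the descriptive quantities the downstream estimators
consume: the empirical distribution of first CD4 counts and binned
six-month uptake averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .synthetic import SIX_MONTHS_DAYS

__all__ = [
    "Cohort",
    "RegressionSample",
    "CD4Distribution",
    "BinnedUptake",
    "read_cohort",
    "cohort_from_frame",
    "apply_filters",
    "summarize",
    "estimate_cd4_distribution",
    "binned_uptake",
]

log = logging.getLogger(__name__)

SCHEMA = ["patient_id", "first_cd4_date", "cd4", "sex", "age_years", "art_start_date"]
TOPCODE = 999


@dataclass
class Cohort:
    """All parsed patient records plus provenance and drop accounting."""

    records: pd.DataFrame
    provenance: str
    n_dropped_missing_cd4: int = 0
    n_dropped_bad_date: int = 0

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class RegressionSample:
    """Records retained for estimation after window/ordering filters."""

    records: pd.DataFrame
    window_start: date
    window_end: date
    n_excluded_by_rule: dict

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CD4Distribution:
    """Empirical pmf of first CD4 counts over the integer grid 0..999."""

    pmf: np.ndarray
    n: int
    range_masses: tuple[float, float, float]  # [0,350), [350,500), [500,999]

    def mass(self, lo: int, hi: int) -> float:
        """Probability mass on the half-open CD4 range [lo, hi)."""
        return float(self.pmf[lo : min(hi, TOPCODE + 1)].sum())


@dataclass
class BinnedUptake:
    """Mean six-month uptake within fixed-width CD4 bins (display grain)."""

    bin_edges: np.ndarray  # left edges; bins are [e, e + width) truncated at 999
    bin_mean_uptake: np.ndarray  # NaN where a bin is empty
    bin_n: np.ndarray
    bin_width: int


def _derive_initiated(df: pd.DataFrame) -> pd.Series:
    delta = (df["art_start_date"] - df["first_cd4_date"]).dt.days
    return df["art_start_date"].notna() & (delta >= 0) & (delta <= SIX_MONTHS_DAYS)


def cohort_from_frame(df: pd.DataFrame, provenance: str = "generator") -> Cohort:
    """Wrap an in-memory cohort frame (e.g. from the synthetic generator)."""
    df = df.copy()
    if "initiated_6mo" not in df.columns:
        df["initiated_6mo"] = _derive_initiated(df)
    return Cohort(records=df, provenance=provenance)


def read_cohort(path, delimiter: str = ",", date_format: str | None = None) -> Cohort:
    """Parse a cohort file into a :class:`Cohort`.

    Rows with missing or unparseable CD4 values are dropped and counted
    (patients with no CD4 count never enter the analysis); CD4 values
    above 999 are top-coded to 999. Unparseable dates drop the row with a
    warning. A malformed header is a hard error naming the missing column.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype={"patient_id": str})
    for col in SCHEMA:
        if col not in df.columns:
            raise ValueError(f"cohort file {path}: missing required column '{col}'")
    if len(df) == 0:
        raise ValueError(f"cohort file {path}: no records")

    cd4 = pd.to_numeric(df["cd4"], errors="coerce")
    n_missing_cd4 = int(cd4.isna().sum())
    if n_missing_cd4:
        log.info("dropping %d rows with missing/unparseable CD4", n_missing_cd4)

    first_date = pd.to_datetime(df["first_cd4_date"], format=date_format, errors="coerce")
    n_bad_date = int((first_date.isna() & cd4.notna()).sum())
    if n_bad_date:
        log.warning("dropping %d rows with unparseable first CD4 date", n_bad_date)

    keep = cd4.notna() & first_date.notna()
    df = df.loc[keep].copy()
    df["cd4"] = cd4[keep].clip(upper=TOPCODE).round().astype(int)
    df["first_cd4_date"] = first_date[keep]
    df["art_start_date"] = pd.to_datetime(df["art_start_date"], format=date_format, errors="coerce")
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    df["initiated_6mo"] = _derive_initiated(df)
    if len(df) == 0:
        raise ValueError(f"cohort file {path}: no records after dropping invalid rows")
    return Cohort(
        records=df.reset_index(drop=True),
        provenance=str(path),
        n_dropped_missing_cd4=n_missing_cd4,
        n_dropped_bad_date=n_bad_date,
    )


def apply_filters(cohort: Cohort, window_start: date, window_end: date) -> RegressionSample:
    """Restrict to the estimation sample.

    Keeps records whose first CD4 date lies in ``[window_start,
    window_end]`` (the window end guarantees six months of follow-up) and
    whose ART start, if any, is not before the first CD4 count. Idempotent.
    """
    if window_start > window_end:
        raise ValueError("window_start must not be after window_end")
    df = cohort.records
    ws, we = pd.Timestamp(window_start), pd.Timestamp(window_end)
    in_window = (df["first_cd4_date"] >= ws) & (df["first_cd4_date"] <= we)
    art_ok = df["art_start_date"].isna() | (df["art_start_date"] >= df["first_cd4_date"])
    excl = {
        "out_of_window": int((~in_window).sum()),
        "after_art": int((in_window & ~art_ok).sum()),
    }
    return RegressionSample(
        records=df.loc[in_window & art_ok].reset_index(drop=True),
        window_start=window_start,
        window_end=window_end,
        n_excluded_by_rule=excl,
    )


def _records(sample) -> pd.DataFrame:
    return sample.records if hasattr(sample, "records") else sample


def summarize(sample) -> dict:
    """Descriptive summary: n, % female, age and CD4 medians/IQRs, uptake.

    Percent female and age statistics use non-missing denominators;
    quartiles use linear interpolation.
    """
    df = _records(sample)
    if len(df) == 0:
        raise ValueError("cannot summarize an empty sample")
    sex = df["sex"].dropna()
    age = df["age_years"].dropna()
    out = {
        "n": len(df),
        "pct_female": 100.0 * (sex == "female").mean() if len(sex) else np.nan,
        "n_missing_sex": int(df["sex"].isna().sum()),
        "median_age": float(age.median()) if len(age) else np.nan,
        "iqr_age": (float(age.quantile(0.25)), float(age.quantile(0.75))) if len(age) else (np.nan, np.nan),
        "n_missing_age": int(df["age_years"].isna().sum()),
        "median_cd4": float(df["cd4"].median()),
        "iqr_cd4": (float(df["cd4"].quantile(0.25)), float(df["cd4"].quantile(0.75))),
        "pct_initiated_6mo": 100.0 * float(df["initiated_6mo"].mean()),
        "n_initiated_6mo": int(df["initiated_6mo"].sum()),
    }
    # initiation by the end of the observation window, censored uniformly
    started = df["art_start_date"].notna() & (
        df["art_start_date"] >= df["first_cd4_date"]
    )
    out["pct_initiated_by_window_end"] = 100.0 * float(started.mean())
    return out


def estimate_cd4_distribution(sample, year_start: date, year_end: date) -> CD4Distribution:
    """Empirical pmf of first CD4 counts among patients presenting in a window.

    The pmf lives on the integer grid 0..999 (top-coded); range masses use
    the boundaries [0,350), [350,500), [500,999].
    """
    df = _records(sample)
    mask = (df["first_cd4_date"] >= pd.Timestamp(year_start)) & (
        df["first_cd4_date"] <= pd.Timestamp(year_end)
    )
    cd4 = df.loc[mask, "cd4"].to_numpy()
    if cd4.size == 0:
        raise ValueError("no records with first CD4 count in the requested window")
    counts = np.bincount(cd4, minlength=TOPCODE + 1).astype(float)
    pmf = counts / counts.sum()
    masses = (float(pmf[:350].sum()), float(pmf[350:500].sum()), float(pmf[500:].sum()))
    return CD4Distribution(pmf=pmf, n=int(cd4.size), range_masses=masses)


def binned_uptake(sample, bin_width: int = 25) -> BinnedUptake:
    """Mean six-month initiation within CD4 bins 0-24, 25-49, ..., 975-999.

    Empty bins report n = 0 and an undefined (NaN) mean.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    df = _records(sample)
    edges = np.arange(0, TOPCODE + 1, bin_width)
    idx = np.minimum(df["cd4"].to_numpy() // bin_width, len(edges) - 1)
    n = np.bincount(idx, minlength=len(edges)).astype(int)
    hits = np.bincount(idx, weights=df["initiated_6mo"].to_numpy(float), minlength=len(edges))
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, hits / np.maximum(n, 1), np.nan)
    return BinnedUptake(bin_edges=edges, bin_mean_uptake=mean, bin_n=n, bin_width=bin_width)
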