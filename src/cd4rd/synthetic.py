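"""Synthetic patient cohorts for the CD4-threshold uptake analysis.

Generates patient-level records (first CD4 count, sex, age, ART start date)
with the statistical structure the estimators assume: a right-skewed
mixture of first CD4 counts, a declining probability of six-month ART
initiation among CD4-eligible patients, a low flat initiation probability
among ineligible patients (clinical staging / pregnancy pathway), and a
discontinuity in uptake at the eligibility threshold.

The default parameters emulate a rural South African public-sector HIV
programme operating under a 350 cells/mm^3 eligibility threshold:
41.1% / 20.0% / 38.9% of presenters below 350 / 350-499 / at or above 500,
~47.8% six-month uptake among CD4-eligible patients, ~8% among ineligible
patients, and an uptake jump of ~33 percentage points at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "GammaMixture",
    "LogitUptake",
    "LinearUptake",
    "CohortParams",
    "generate_cohort",
    "true_curves",
    "default_params",
]

SIX_MONTHS_DAYS = 183


class InvalidCurveError(ValueError):
    """An uptake curve leaves [0, 1] somewhere on the CD4 grid."""


@dataclass(frozen=True)
class GammaMixture:
    """Finite mixture of gamma distributions for first CD4 counts.

    Parameters are (weight, shape, scale) per component; weights must sum
    to one. Draws are rounded to integer cells and top-coded downstream.
    """

    weights: tuple[float, ...]
    shapes: tuple[float, ...]
    scales: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.shapes) == len(self.scales)):
            raise ValueError("mixture component lists must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be nonnegative")

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        out = np.empty(n)
        for k, (shape, scale) in enumerate(zip(self.shapes, self.scales)):
            mask = comp == k
            out[mask] = rng.gamma(shape, scale, size=int(mask.sum()))
        return out

    def cdf(self, x: np.ndarray | float) -> np.ndarray | float:
        return sum(
            w * stats.gamma.cdf(x, a=shape, scale=scale)
            for w, shape, scale in zip(self.weights, self.shapes, self.scales)
        )


@dataclass(frozen=True)
class LogitUptake:
    """Uptake curve linear on the logit scale, centred at the threshold.

    P(initiate | cd4) = expit(intercept + slope * (cd4 - threshold)).
    Always a valid probability, for any intercept and slope.
    """

    intercept: float
    slope: float

    def prob(self, cd4: np.ndarray, threshold: int) -> np.ndarray:
        return expit(self.intercept + self.slope * (np.asarray(cd4, float) - threshold))


@dataclass(frozen=True)
class LinearUptake:
    """Uptake curve linear on the probability scale, centred at the threshold.

    P(initiate | cd4) = intercept + slope * (cd4 - threshold). Unlike
    :class:`LogitUptake` this can escape [0, 1]; parameter validation
    rejects any configuration that does so on the integer CD4 grid.
    """

    intercept: float
    slope: float

    def prob(self, cd4: np.ndarray, threshold: int) -> np.ndarray:
        return self.intercept + self.slope * (np.asarray(cd4, float) - threshold)


@dataclass(frozen=True)
class CohortParams:
    """Full parameterization of the synthetic cohort generator."""

    n_patients: int
    cd4_mixture: GammaMixture
    uptake_eligible: LogitUptake | LinearUptake
    uptake_ineligible: LogitUptake | LinearUptake
    eligibility_threshold: int = 350
    topcode: int = 999
    date_window: tuple[date, date] = (date(2011, 8, 12), date(2013, 12, 31))
    seed: int = 0
    # fraction of six-month non-initiators who start ART later, given time
    late_uptake: float = 0.035
    prop_female: float = 0.685
    age_log_mean: float = field(default=float(np.log(30.0)))
    age_log_sd: float = 0.33
    prop_missing_sex: float = 0.023
    prop_missing_age: float = 0.023

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not (0 < self.eligibility_threshold < self.topcode):
            raise ValueError("eligibility_threshold must lie in (0, topcode)")
        if self.date_window[0] > self.date_window[1]:
            raise ValueError("date_window start must precede end")
        grid = np.arange(self.topcode + 1)
        for name, curve in (
            ("uptake_eligible", self.uptake_eligible),
            ("uptake_ineligible", self.uptake_ineligible),
        ):
            p = np.asarray(curve.prob(grid, self.eligibility_threshold), float)
            bad = np.flatnonzero((p < 0.0) | (p > 1.0))
            if bad.size:
                raise InvalidCurveError(
                    f"{name} yields probability {p[bad[0]]:.4g} outside [0, 1] "
                    f"at CD4 = {int(grid[bad[0]])}"
                )


def default_params(n_patients: int = 15_000, seed: int = 0, **overrides) -> CohortParams:
    """Default generator: the 350-cell regime conditions.

    The CD4 mixture is calibrated so the probability masses of the ranges
    [0,350), [350,500) and [500, inf) are 0.411 / 0.200 / 0.389. The
    eligible curve passes through 40.8% at the threshold with a logit
    slope giving ~47.8% mean uptake below 350 under that mixture; the
    ineligible curve is flat at 8%.
    """
    params = CohortParams(
        n_patients=n_patients,
        cd4_mixture=GammaMixture(
            weights=(0.6301, 0.3699),
            shapes=(2.5, 7.0),
            scales=(135.27, 95.0),
        ),
        uptake_eligible=LogitUptake(intercept=-0.372239, slope=-0.00199),
        uptake_ineligible=LogitUptake(intercept=-2.442347, slope=0.0),
        seed=seed,
    )
    if overrides:
        params = replace(params, **overrides)
    return params


def true_curves(params: CohortParams) -> tuple[np.ndarray, np.ndarray]:
    """Generating uptake probabilities on the integer CD4 grid 0..topcode.

    Returns ``(p_eligible, p_ineligible)``, each an array of length
    ``topcode + 1`` evaluated exactly as :func:`generate_cohort` uses them.
    """
    params.validate()
    grid = np.arange(params.topcode + 1)
    c0 = params.eligibility_threshold
    return (
        np.asarray(params.uptake_eligible.prob(grid, c0), float),
        np.asarray(params.uptake_ineligible.prob(grid, c0), float),
    )


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a synthetic cohort as one row per patient.

    Columns: ``patient_id, first_cd4_date, cd4, sex, age_years,
    art_start_date, initiated_6mo``. CD4 counts are drawn from the
    mixture, rounded to integers, and top-coded; six-month initiation is
    Bernoulli with probability from the eligible curve when
    ``cd4 < eligibility_threshold`` and from the ineligible curve
    otherwise (a count exactly at the threshold is ineligible).
    Reproducible given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    c0 = params.eligibility_threshold

    cd4 = np.rint(params.cd4_mixture.rvs(n, rng))
    cd4 = np.clip(cd4, 0, params.topcode).astype(int)

    p_elig, p_inelig = true_curves(params)
    eligible = cd4 < c0
    p = np.where(eligible, p_elig[cd4], p_inelig[cd4])
    initiated = rng.random(n) < p

    start, end = params.date_window
    span = (end - start).days
    date_offsets = rng.integers(0, span + 1, size=n)
    first_dates = np.datetime64(start) + date_offsets.astype("timedelta64[D]")

    # ART start within 183 days for six-month initiators; a small share of
    # the remainder start later, if the window leaves room.
    delay_6mo = rng.integers(0, SIX_MONTHS_DAYS + 1, size=n)
    room = span - date_offsets
    late_mask = (~initiated) & (rng.random(n) < params.late_uptake) & (room > SIX_MONTHS_DAYS)
    late_extra = SIX_MONTHS_DAYS + 1 + np.floor(
        rng.random(n) * np.maximum(room - SIX_MONTHS_DAYS, 1)
    ).astype(int)
    art_offset = np.where(initiated, delay_6mo, late_extra).astype("timedelta64[D]")
    art_dates = np.where(
        initiated | late_mask, first_dates + art_offset, np.datetime64("NaT")
    )

    sex = np.where(rng.random(n) < params.prop_female, "female", "male").astype(object)
    sex[rng.random(n) < params.prop_missing_sex] = None
    age = np.exp(rng.normal(params.age_log_mean, params.age_log_sd, size=n))
    age[rng.random(n) < params.prop_missing_age] = np.nan

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:07d}" for i in range(n)],
            "first_cd4_date": pd.to_datetime(first_dates),
            "cd4": cd4,
            "sex": sex,
            "age_years": np.round(age, 1),
            "art_start_date": pd.to_datetime(art_dates),
            "initiated_6mo": initiated,
        }
    )
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort in the delimited-text interchange schema.

    Header ``patient_id,first_cd4_date,cd4,sex,age_years,art_start_date``;
    ISO-8601 dates; empty field = missing. ``initiated_6mo`` is derived on
    read, so it is not written.
    """
    out = df[["patient_id", "first_cd4_date", "cd4", "sex", "age_years", "art_start_date"]].copy()
    out["first_cd4_date"] = out["first_cd4_date"].dt.strftime("%Y-%m-%d")
    out["art_start_date"] = out["art_start_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
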