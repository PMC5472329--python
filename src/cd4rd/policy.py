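"""Threshold-change policy simulation.

Combines three ingredients — the CD4-at-presentation distribution f_CD4,
the counterfactual "if eligible" uptake curve, and the observed
"if ineligible" uptake curve — into the projected impact of raising or
eliminating the CD4 eligibility threshold. For a CD4 range R newly made
eligible, the expected number of new initiators is

    sum over cd4 in R of  f_CD4(cd4) * [p_eligible(cd4) - p_ineligible(cd4)],

an exact sum over the integer-valued empirical pmf. Results are expressed
as the standard report rows: share of presenters in the range (row 1),
uptake under the old regime (row 2) and under expanded criteria (row 3),
new initiators (row 4 = 3 - 2), non-initiators despite eligibility
(row 5 = 100 - 3), and the percent increase in programme initiators
(row 6), plus national scale-up projections (rows 7-8). Uncertainty is
propagated by parametric simulation from the fitted coefficient
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CD4Distribution
from .global_rd import GlobalRDFit, UptakeCurve, confidence_band, constant_uptake_bound

__all__ = [
    "PolicyScenario",
    "PolicyImpact",
    "NationalProjection",
    "simulate_policy",
    "complete_rows",
    "national_projection",
    "propagate_uncertainty",
    "sensitivity_scenario",
]

# programme reference counts: presenters and six-month initiators in the
# reference year, and the national scale-up denominators
DEFAULT_N_NATIONAL_INITIATORS = 614_000
DEFAULT_N_NATIONAL_ON_ART = 3_000_000


@dataclass(frozen=True)
class PolicyScenario:
    """A half-open CD4 range [lo, hi) newly made eligible."""

    cd4_range: tuple[int, int]
    label: str

    def __post_init__(self) -> None:
        lo, hi = self.cd4_range
        if not (0 <= lo < hi <= 1000):
            raise ValueError("cd4_range must be a nonempty subrange of [0, 1000)")

    @classmethod
    def raise_to_500(cls) -> "PolicyScenario":
        return cls(cd4_range=(350, 500), label="raise_to_500")

    @classmethod
    def eliminate_threshold(cls) -> "PolicyScenario":
        return cls(cd4_range=(500, 1000), label="eliminate_threshold")


@dataclass
class PolicyImpact:
    """Report rows (1)-(6) for one scenario, percentages in [0, 100]."""

    scenario: PolicyScenario
    pct_of_presenters: float  # row 1
    pct_initiate_old_regime: float  # row 2
    pct_initiate_expanded: float  # row 3
    pct_new_initiators: float  # row 4
    pct_not_initiating: float  # row 5
    pct_increase_in_initiators: float  # row 6
    n_presenters_ref: int
    n_initiators_ref: int
    intervals: dict = field(default_factory=dict)  # row name -> (lo, hi)


@dataclass
class NationalProjection:
    """Rows (7)-(8): national initiator and on-ART scale-up."""

    additional_initiators_per_year: float  # raw
    additional_initiators_rounded: int  # nearest 1,000
    pct_increase_on_art: float
    n_national_initiators: int
    n_national_on_art: int


def complete_rows(
    pct_of_presenters: float,
    pct_initiate_old_regime: float,
    pct_initiate_expanded: float,
    n_presenters_ref: int,
    n_initiators_ref: int,
) -> dict:
    """Rows (4)-(6) from rows (1)-(3) and the reference counts.

    Row 4 is the conditional percentage-point gain within the range, row 5
    the share still not initiating, and row 6 rescales the absolute number
    of new initiators (row4 x row1 x presenters) to a percent increase on
    the reference year's initiator count.
    """
    row4 = pct_initiate_expanded - pct_initiate_old_regime
    row5 = 100.0 - pct_initiate_expanded
    new_initiators = row4 / 100.0 * pct_of_presenters / 100.0 * n_presenters_ref
    row6 = new_initiators / n_initiators_ref * 100.0
    return {
        "pct_new_initiators": row4,
        "pct_not_initiating": row5,
        "pct_increase_in_initiators": row6,
        "n_new_initiators": new_initiators,
    }


def _range_rows(pmf: np.ndarray, p_elig: np.ndarray, p_inelig: np.ndarray, lo: int, hi: int):
    hi = min(hi, pmf.size)
    sl = slice(lo, hi)
    mass = pmf[sl].sum()
    if mass <= 0:
        raise ValueError(f"CD4 range [{lo}, {hi}) carries no probability mass")
    row1 = 100.0 * mass
    row2 = 100.0 * float(np.sum(pmf[sl] * p_inelig[sl]) / mass)
    row3 = 100.0 * float(np.sum(pmf[sl] * p_elig[sl]) / mass)
    return row1, row2, row3


def simulate_policy(
    fcd4: CD4Distribution,
    eligible_curve: UptakeCurve,
    ineligible_curve: UptakeCurve,
    scenario: PolicyScenario,
    n_presenters_ref: int,
    n_initiators_ref: int,
) -> PolicyImpact:
    """Project the impact of making ``scenario.cd4_range`` eligible.

    Integration is the exact sum over the integer-CD4 empirical pmf; the
    two curves must be defined on the full grid 0..999.
    """
    lo, hi = scenario.cd4_range
    row1, row2, row3 = _range_rows(fcd4.pmf, eligible_curve.p, ineligible_curve.p, lo, hi)
    rest = complete_rows(row1, row2, row3, n_presenters_ref, n_initiators_ref)
    return PolicyImpact(
        scenario=scenario,
        pct_of_presenters=row1,
        pct_initiate_old_regime=row2,
        pct_initiate_expanded=row3,
        pct_new_initiators=rest["pct_new_initiators"],
        pct_not_initiating=rest["pct_not_initiating"],
        pct_increase_in_initiators=rest["pct_increase_in_initiators"],
        n_presenters_ref=n_presenters_ref,
        n_initiators_ref=n_initiators_ref,
    )


def national_projection(
    pct_increase: float,
    n_national_initiators: int = DEFAULT_N_NATIONAL_INITIATORS,
    n_national_on_art: int = DEFAULT_N_NATIONAL_ON_ART,
) -> NationalProjection:
    """Scale a programme-level percent increase to the national programme."""
    if n_national_initiators <= 0 or n_national_on_art <= 0:
        raise ValueError("national reference counts must be positive")
    raw = pct_increase / 100.0 * n_national_initiators
    return NationalProjection(
        additional_initiators_per_year=raw,
        additional_initiators_rounded=int(round(raw / 1000.0) * 1000),
        pct_increase_on_art=raw / n_national_on_art * 100.0,
        n_national_initiators=n_national_initiators,
        n_national_on_art=n_national_on_art,
    )


def propagate_uncertainty(
    fit: GlobalRDFit,
    fcd4: CD4Distribution,
    scenario: PolicyScenario,
    n_presenters_ref: int,
    n_initiators_ref: int,
    n_draws: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Percentile intervals for rows (3)-(6) by parametric simulation.

    Coefficient vectors are drawn from the asymptotic normal distribution
    of the fit; rows are recomputed per draw and the central
    ``level`` percentile interval reported per row.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    vc = (fit.vcov + fit.vcov.T) / 2
    if float(np.linalg.eigvalsh(vc).min()) < -1e-8:
        raise ValueError("coefficient covariance is not positive semidefinite")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.coef, vc, size=n_draws, method="svd")

    lo, hi = scenario.cd4_range
    hi = min(hi, fcd4.pmf.size)
    grid = np.arange(lo, hi, dtype=float)
    centred = grid - fit.threshold
    pmf = fcd4.pmf[lo:hi]
    mass = pmf.sum()
    w = pmf / mass

    # eligible: alpha + gamma + beta_below * centred; ineligible: alpha + beta_above * centred
    eta_e = draws[:, [0]] + draws[:, [1]] + draws[:, [2]] * centred[None, :]
    eta_i = draws[:, [0]] + draws[:, [3]] * centred[None, :]
    p_e = 1.0 / (1.0 + np.exp(-eta_e))
    p_i = 1.0 / (1.0 + np.exp(-eta_i))
    row3 = 100.0 * p_e @ w
    row2 = 100.0 * p_i @ w
    row1 = 100.0 * mass
    row4 = row3 - row2
    row5 = 100.0 - row3
    row6 = row4 / 100.0 * row1 / 100.0 * n_presenters_ref / n_initiators_ref * 100.0

    q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
    out = {}
    for name, vals in (
        ("pct_initiate_expanded", row3),
        ("pct_new_initiators", row4),
        ("pct_not_initiating", row5),
        ("pct_increase_in_initiators", row6),
    ):
        lo_q, hi_q = np.percentile(vals, q)
        out[name] = (float(lo_q), float(hi_q))
    return out


def sensitivity_scenario(
    fit: GlobalRDFit,
    fcd4: CD4Distribution,
    scenario: PolicyScenario,
    n_presenters_ref: int,
    n_initiators_ref: int,
) -> PolicyImpact:
    """Upper-bound variant: uptake held constant above the threshold.

    Identical to :func:`simulate_policy` with the eligible curve replaced
    by the constant-uptake bound.
    """
    return simulate_policy(
        fcd4,
        constant_uptake_bound(fit),
        confidence_band(fit, eligible=False),
        scenario,
        n_presenters_ref,
        n_initiators_ref,
    )
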