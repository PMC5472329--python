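"""Global regression discontinuity: logistic uptake model with a threshold jump.

The model posits that the probability of six-month ART initiation is
linear in logits on each side of the CD4 eligibility threshold c0, with
an intercept shift at c0:

    logit P(initiate | cd4) = alpha + gamma * 1[cd4 < c0]
                              + beta_below * (cd4 - c0) * 1[cd4 < c0]
                              + beta_above * (cd4 - c0) * 1[cd4 >= c0]

so alpha is the ineligible-side level at the threshold, gamma the jump
attributable to eligibility, and the betas side-specific slopes per cell.
The below-side line, extended above c0, is the counterfactual
"if eligible" uptake curve used for policy extrapolation; the above-side
line is observed uptake through the non-CD4 pathway (clinical staging,
pregnancy). Pointwise confidence bands come from the delta method on the
logit scale, so they respect (0, 1) and widen with extrapolation distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

__all__ = [
    "GlobalRDFit",
    "UptakeCurve",
    "SeparationError",
    "fit_global_rd",
    "predict_uptake",
    "confidence_band",
    "constant_uptake_bound",
]

COEF_NAMES = ("alpha", "gamma", "beta_below", "beta_above")


class SeparationError(RuntimeError):
    """Outcomes are all 0 or all 1 on one side of the threshold."""


@dataclass
class GlobalRDFit:
    """Maximum-likelihood fit of the four-coefficient discontinuity model."""

    threshold: int
    coef: np.ndarray  # (alpha, gamma, beta_below, beta_above)
    vcov: np.ndarray  # 4x4
    n_obs: int
    loglik: float

    @property
    def alpha(self) -> float:
        return float(self.coef[0])

    @property
    def gamma(self) -> float:
        return float(self.coef[1])

    @property
    def beta_below(self) -> float:
        return float(self.coef[2])

    @property
    def beta_above(self) -> float:
        return float(self.coef[3])

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


@dataclass
class UptakeCurve:
    """A probability curve on the integer CD4 grid with a pointwise band."""

    grid: np.ndarray
    p: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    regime_label: str  # if_eligible | if_ineligible | constant_bound


def _design(cd4: np.ndarray, threshold: int) -> np.ndarray:
    cd4 = np.asarray(cd4, float)
    below = (cd4 < threshold).astype(float)
    centred = cd4 - threshold
    return np.column_stack(
        [np.ones_like(cd4), below, centred * below, centred * (1.0 - below)]
    )


def fit_global_rd(sample, threshold: int = 350, drop_topcoded: bool = False) -> GlobalRDFit:
    """Fit the discontinuity model to individual patient records.

    ``sample`` is a :class:`~cd4rd.cohort.RegressionSample` (or any object
    with a ``records`` frame carrying ``cd4`` and ``initiated_6mo``). The
    likelihood is the individual-level Bernoulli likelihood, maximized by
    Newton iterations to gradient tolerance 1e-8; the covariance is the
    inverse observed information. Top-coded records (cd4 = 999) are kept
    unless ``drop_topcoded``.
    """
    df = sample.records if hasattr(sample, "records") else sample
    if drop_topcoded:
        df = df[df["cd4"] < 999]
    cd4 = df["cd4"].to_numpy(float)
    y = df["initiated_6mo"].to_numpy(float)

    for side, mask in (("below", cd4 < threshold), ("above", cd4 >= threshold)):
        ys = y[mask]
        if ys.size == 0 or ys.min() == ys.max():
            raise SeparationError(
                f"outcomes on the {side}-threshold side are degenerate "
                f"(all {int(ys[0]) if ys.size else 'absent'}); "
                "the logistic model is not identified"
            )

    X = _design(cd4, threshold)
    model = sm.Logit(y, X)
    try:
        res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=False)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(f"logistic fit did not converge: {res.mle_retvals}")
    return GlobalRDFit(
        threshold=threshold,
        coef=np.asarray(res.params, float),
        vcov=np.asarray(res.cov_params(), float),
        n_obs=int(len(y)),
        loglik=float(res.llf),
    )


def _linear_predictor(fit: GlobalRDFit, cd4: np.ndarray, eligible: bool):
    """Logit-scale prediction and its design rows under a counterfactual regime.

    Under ``eligible=True`` every CD4 count uses the below-side line
    (gamma included), i.e. the extrapolation above the threshold; under
    ``eligible=False`` every count uses the above-side line.
    """
    cd4 = np.asarray(cd4, float)
    if np.any(cd4 < 0) or np.any(cd4 > 999):
        raise ValueError("cd4 out of range [0, 999]")
    centred = cd4 - fit.threshold
    ones = np.ones_like(cd4)
    if eligible:
        X = np.column_stack([ones, ones, centred, np.zeros_like(cd4)])
    else:
        X = np.column_stack([ones, np.zeros_like(cd4), np.zeros_like(cd4), centred])
    return X @ fit.coef, X


def predict_uptake(fit: GlobalRDFit, cd4, eligible: bool):
    """Probability of six-month initiation at given CD4 under a regime.

    Scalar in, scalar out; array in, array out.
    """
    scalar = np.isscalar(cd4)
    eta, _ = _linear_predictor(fit, np.atleast_1d(np.asarray(cd4, float)), eligible)
    p = expit(eta)
    return float(p[0]) if scalar else p


def confidence_band(
    fit: GlobalRDFit, grid=None, eligible: bool = True, level: float = 0.95
) -> UptakeCurve:
    """Pointwise delta-method confidence band for an uptake curve.

    The variance of the linear predictor, x' V x, is computed from the
    coefficient covariance; the normal band on the logit scale is then
    mapped through the inverse logit.
    """
    if grid is None:
        grid = np.arange(1000)
    grid = np.asarray(grid, float)
    eigmin = float(np.linalg.eigvalsh((fit.vcov + fit.vcov.T) / 2).min())
    if eigmin < -1e-8:
        raise ValueError("coefficient covariance is not positive semidefinite")
    eta, X = _linear_predictor(fit, grid, eligible)
    var = np.einsum("ij,jk,ik->i", X, fit.vcov, X)
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    return UptakeCurve(
        grid=grid.astype(int),
        p=expit(eta),
        lo95=expit(eta - z * se),
        hi95=expit(eta + z * se),
        regime_label="if_eligible" if eligible else "if_ineligible",
    )


def constant_uptake_bound(fit: GlobalRDFit, grid=None, level: float = 0.95) -> UptakeCurve:
    """Sensitivity upper bound: uptake flat above the threshold.

    Below the threshold the curve equals the fitted eligible curve; at and
    above it, uptake is held at the eligible prediction evaluated at the
    threshold (the below-side line at c0). The band above the threshold is
    likewise the threshold-point band, held constant.
    """
    if grid is None:
        grid = np.arange(1000)
    grid = np.asarray(grid, int)
    base = confidence_band(fit, grid=grid, eligible=True, level=level)
    at_c0 = confidence_band(fit, grid=np.array([fit.threshold]), eligible=True, level=level)
    above = grid >= fit.threshold
    p = np.where(above, at_c0.p[0], base.p)
    lo = np.where(above, at_c0.lo95[0], base.lo95)
    hi = np.where(above, at_c0.hi95[0], base.hi95)
    return UptakeCurve(grid=grid, p=p, lo95=lo, hi95=hi, regime_label="constant_bound")
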