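"""Core two-sample MR estimators.

All estimators consume a harmonized :class:`~hcymr.data_model.InstrumentSet`
and return :class:`MREstimate` records on the log-odds scale (the outcome
here is binary), with the odds-ratio scale available as derived properties.

Per-variant causal estimates are Wald ratios theta_j = beta_Yj / beta_Xj.
The pooled estimators are:

* IVW — the inverse-variance weighted mean of the Wald ratios with
  first-order weights w_j = beta_Xj^2 / se_Yj^2.  The fixed-effect standard
  error is 1/sqrt(sum w_j); the multiplicative random-effects model inflates
  it by max(1, sqrt(Q/(J-1))), never deflating below the fixed-effect value.
* MR-Egger — weighted least squares of beta_Y on beta_X with a free
  intercept and weights 1/se_Yj^2, after orienting all exposure betas
  non-negative.  The slope estimates the causal effect allowing directional
  pleiotropy; a nonzero intercept is the pleiotropy signal.  Residual
  overdispersion scales the coefficient variances by max(1, sigma^2).
* Weighted median — the 50% point of the inverse-variance-weighted empirical
  distribution of Wald ratios, consistent while valid instruments carry a
  majority of the weight; its SE comes from a parametric bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import HarmonizedInstrument, InstrumentSet

__all__ = [
    "Z_95",
    "MREstimate",
    "HeterogeneityResult",
    "EggerResult",
    "wald_ratio",
    "wald_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "cochran_q",
    "first_order_weights",
]

#: two-sided 95% normal quantile
Z_95 = 1.959963985


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with its uncertainty, on the log-odds scale."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_instruments: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.estimate)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q across per-variant Wald ratios."""

    q_statistic: float
    df: int
    p_value: float
    i_squared: float


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: MREstimate


def _normal_p(z: float) -> float:
    # clamp into (0, 1]; an exact zero only arises from infinite z
    return max(float(2.0 * stats.norm.sf(abs(z))), 5e-324)


def _make_estimate(method: str, estimate: float, se: float,
                   n_instruments: int, *, crit: float = Z_95,
                   p_value: float | None = None) -> MREstimate:
    if p_value is None:
        p_value = _normal_p(estimate / se) if se > 0 else 1.0
    return MREstimate(
        method=method,
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - crit * se),
        ci_high=float(estimate + crit * se),
        p_value=float(p_value),
        n_instruments=n_instruments,
    )


def first_order_weights(iset: InstrumentSet) -> np.ndarray:
    """IVW weights w_j = beta_Xj^2 / se_Yj^2 (exposure noise ignored)."""
    return iset.beta_exposure ** 2 / iset.se_outcome ** 2


def wald_ratio(inst: HarmonizedInstrument, *, second_order: bool = False) -> MREstimate:
    """Per-variant causal estimate beta_Y / beta_X.

    The default (first-order) delta-method SE is |se_Y / beta_X|, ignoring
    sampling error in the exposure beta; ``second_order=True`` adds the
    exposure-noise term, which is negligible for strong instruments.
    """
    if inst.beta_exposure == 0:
        raise ZeroDivisionError(
            f"{inst.variant_id}: zero exposure beta, Wald ratio undefined")
    est = inst.beta_outcome / inst.beta_exposure
    se = abs(inst.se_outcome / inst.beta_exposure)
    if second_order:
        se = math.sqrt(
            inst.se_outcome ** 2 / inst.beta_exposure ** 2
            + inst.beta_outcome ** 2 * inst.se_exposure ** 2
            / inst.beta_exposure ** 4)
    return _make_estimate("wald", est, se, 1)


def wald_ratios(iset: InstrumentSet) -> np.ndarray:
    """Vector of per-variant Wald ratios."""
    bx = iset.beta_exposure
    if np.any(bx == 0):
        raise ZeroDivisionError("zero exposure beta, Wald ratio undefined")
    return iset.beta_outcome / bx


def ivw(iset: InstrumentSet, model: str = "auto") -> MREstimate:
    """Inverse-variance weighted causal estimate.

    ``model`` is ``"fixed"``, ``"multiplicative_random"`` or ``"auto"``;
    auto uses multiplicative random effects when J >= 4, fixed otherwise
    (the convention of the standard reference implementation).  A single
    instrument degenerates to its Wald ratio.
    """
    if model not in ("fixed", "multiplicative_random", "auto"):
        raise ValueError(f"unknown IVW model {model!r}")
    J = len(iset)
    if J == 1:
        est = wald_ratio(iset.instruments[0])
        return _make_estimate("ivw_fe", est.estimate, est.se, 1)
    theta_j = wald_ratios(iset)
    w = first_order_weights(iset)
    theta = float(np.sum(w * theta_j) / np.sum(w))
    se_fe = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (theta_j - theta) ** 2))
    if model == "auto":
        model = "multiplicative_random" if J >= 4 else "fixed"
    if model == "fixed":
        return _make_estimate("ivw_fe", theta, se_fe, J)
    se = se_fe * max(1.0, math.sqrt(q / (J - 1)))
    return _make_estimate("ivw_mre", theta, se, J)


def egger(iset: InstrumentSet, p_reference: str = "normal") -> EggerResult:
    """MR-Egger regression: causal slope plus directional-pleiotropy intercept.

    Exposure betas are oriented non-negative before fitting (flipping the
    outcome beta jointly), as the regression is not invariant to per-variant
    sign conventions.  ``p_reference`` selects the reference distribution for
    CIs and p-values: ``"normal"`` (default) or ``"t"`` with J-2 df.
    """
    J = len(iset)
    if J < 3:
        raise ValueError(f"MR-Egger requires >= 3 instruments, got {J}")
    if p_reference not in ("normal", "t"):
        raise ValueError(f"unknown p_reference {p_reference!r}")
    sign = np.sign(iset.beta_exposure)
    sign[sign == 0] = 1.0
    bx = iset.beta_exposure * sign
    by = iset.beta_outcome * sign
    if np.allclose(bx, bx[0]):
        raise ValueError("degenerate design: all exposure betas equal")
    w = 1.0 / iset.se_outcome ** 2

    X = np.column_stack([np.ones(J), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid ** 2) / (J - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se_int, se_slope = np.sqrt(np.diag(cov))

    if p_reference == "normal":
        crit = Z_95
        p_slope = _normal_p(coef[1] / se_slope)
        p_int = _normal_p(coef[0] / se_int)
    else:
        crit = float(stats.t.ppf(0.975, J - 2))
        p_slope = max(float(2 * stats.t.sf(abs(coef[1] / se_slope), J - 2)), 5e-324)
        p_int = max(float(2 * stats.t.sf(abs(coef[0] / se_int), J - 2)), 5e-324)
    return EggerResult(
        slope=_make_estimate("egger_slope", coef[1], se_slope, J,
                             crit=crit, p_value=p_slope),
        intercept=_make_estimate("egger_intercept", coef[0], se_int, J,
                                 crit=crit, p_value=p_int),
    )


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    # merge tied ratios (summing their weights) so the result does not
    # depend on the argsort order among ties
    theta, inverse = np.unique(theta, return_inverse=True)
    w = np.bincount(inverse, weights=w)
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, theta))


def weighted_median(iset: InstrumentSet, n_boot: int = 10_000,
                    seed: int = 12345) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate interpolates the Wald ratios at standardized
    cumulative weight 0.5 (weights w_j = beta_Xj^2/se_Yj^2).  The SE is the
    standard deviation of the weighted median over ``n_boot`` parametric
    resamples of (beta_X, beta_Y) from their normal sampling distributions.
    """
    J = len(iset)
    if J < 3:
        raise ValueError(f"weighted median requires >= 3 instruments, got {J}")
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    theta_j = wald_ratios(iset)
    w = first_order_weights(iset)
    point = _weighted_median(theta_j, w)

    rng = np.random.default_rng(seed)
    bx = rng.normal(iset.beta_exposure, iset.se_exposure, size=(n_boot, J))
    by = rng.normal(iset.beta_outcome, iset.se_outcome, size=(n_boot, J))
    ratios = by / bx
    wts = bx ** 2 / iset.se_outcome ** 2
    order = np.argsort(ratios, axis=1)
    r_sorted = np.take_along_axis(ratios, order, axis=1)
    w_sorted = np.take_along_axis(wts, order, axis=1)
    cum = np.cumsum(w_sorted, axis=1)
    s = (cum - 0.5 * w_sorted) / cum[:, -1:]
    medians = np.empty(n_boot)
    for i in range(n_boot):
        medians[i] = np.interp(0.5, s[i], r_sorted[i])
    se = float(np.std(medians, ddof=1))
    return _make_estimate("weighted_median", point, se, J)


def cochran_q(iset: InstrumentSet, theta: float | None = None) -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic across Wald ratios.

    ``theta`` defaults to the fixed-effect IVW estimate; supplying another
    pooled value measures dispersion about that value instead.
    """
    J = len(iset)
    if J < 2:
        raise ValueError("heterogeneity needs >= 2 instruments")
    theta_j = wald_ratios(iset)
    w = first_order_weights(iset)
    if theta is None:
        theta = float(np.sum(w * theta_j) / np.sum(w))
    q = float(np.sum(w * (theta_j - theta) ** 2))
    df = J - 1
    return HeterogeneityResult(
        q_statistic=q,
        df=df,
        p_value=float(stats.chi2.sf(q, df)),
        i_squared=max(0.0, (q - df) / q) if q > 0 else 0.0,
    )
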