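"""Pleiotropy and directionality diagnostics: MR-PRESSO, Steiger, leave-one-out.

MR-PRESSO compares the observed weighted residual sum of squares about
leave-one-out IVW fits to its distribution under a simulated no-pleiotropy
null; variants whose own residual is extreme (Bonferroni-corrected empirical
p) are flagged as pleiotropic outliers.  The Steiger test checks causal
direction by comparing the variance the instruments explain in the exposure
versus the outcome.  Leave-one-out re-fits IVW omitting each variant in turn
to expose single-variant leverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import InstrumentSet
from .estimators import MREstimate, ivw

__all__ = [
    "PressoResult",
    "SteigerResult",
    "LeaveOneOutResult",
    "presso",
    "steiger",
    "leave_one_out",
    "effective_sample_size",
]


@dataclass(frozen=True)
class PressoResult:
    global_rss_observed: float
    global_p: float
    outlier_p: dict[str, float]
    outliers: tuple[str, ...]
    distortion_p: float | None
    n_sim: int
    seed: int


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    p_value: float


@dataclass(frozen=True)
class LeaveOneOutResult:
    variant_ids: tuple[str, ...]
    estimates: tuple[MREstimate, ...]
    full_estimate: MREstimate

    def __post_init__(self) -> None:
        if len(self.variant_ids) != len(self.estimates):
            raise ValueError("one estimate required per excluded variant")


def _loo_theta(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, vectorized over leading axes.

    The fixed-effect IVW slope is sum(w bx by)/sum(w bx^2) with w = 1/sy^2;
    dropping variant j just removes its two sum contributions.
    """
    w = 1.0 / sy ** 2
    num = w * bx * by
    den = w * bx * bx
    return ((num.sum(axis=-1, keepdims=True) - num)
            / (den.sum(axis=-1, keepdims=True) - den))


def _rss_terms(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Per-variant weighted squared residual about its leave-one-out fit."""
    theta_loo = _loo_theta(bx, by, sy)
    resid = by - theta_loo * bx
    return resid ** 2 / sy ** 2


def presso(iset: InstrumentSet, n_sim: int = 5_000, seed: int = 12345,
           significance: float = 0.05, resample_exposure: bool = True,
           ) -> PressoResult:
    """MR-PRESSO global and outlier tests.

    The observed statistic is the sum over variants of the weighted squared
    residual about each variant's leave-one-out fixed-effect IVW fit.  The
    null is simulated by redrawing outcome betas about their leave-one-out
    fitted values at the reported standard errors (and, by default, exposure
    betas about their observed values — ``resample_exposure=False`` holds
    them fixed), recomputing the statistic on each simulated dataset.
    Empirical p-values use the (r+1)/(n+1) correction.  A variant is flagged
    when its own residual's empirical p falls below ``significance``
    Bonferroni-divided by J.  The distortion test (observed shift of the IVW
    estimate when outliers are dropped, against a resampling null) is
    computed only when outliers are flagged.
    """
    J = len(iset)
    if J < 4:
        raise ValueError(f"MR-PRESSO requires >= 4 instruments, got {J}")
    if n_sim < 1_000:
        raise ValueError("n_sim must be >= 1000 for stable empirical p-values")

    bx = iset.beta_exposure
    by = iset.beta_outcome
    sx = iset.se_exposure
    sy = iset.se_outcome

    obs_terms = _rss_terms(bx, by, sy)
    rss_obs = float(obs_terms.sum())
    theta_loo = _loo_theta(bx, by, sy)

    rng = np.random.default_rng(seed)
    if resample_exposure:
        bx_sim = rng.normal(bx, sx, size=(n_sim, J))
    else:
        bx_sim = np.broadcast_to(bx, (n_sim, J))
    by_sim = rng.normal(theta_loo * bx_sim, sy, size=(n_sim, J))
    sim_terms = _rss_terms(bx_sim, by_sim, sy)

    global_p = float((np.sum(sim_terms.sum(axis=1) >= rss_obs) + 1) / (n_sim + 1))
    per_variant = (np.sum(sim_terms >= obs_terms, axis=0) + 1) / (n_sim + 1)
    outlier_p = {vid: float(p) for vid, p in zip(iset.variant_ids, per_variant)}
    alpha_bonf = significance / J
    candidates = [j for j, p in enumerate(per_variant) if p < alpha_bonf]

    # Confirmatory stage: a gross outlier contaminates the leave-one-out fits
    # of its neighbours, so a clean variant can be flagged alongside it.
    # Re-test each candidate against the fit from non-candidate variants
    # only; candidates that stop being extreme once the others are out of
    # the reference fit are released.
    flagged_idx = candidates
    if candidates and len(candidates) < J - 1:
        clean = np.array([j for j in range(J) if j not in candidates])
        w_c = 1.0 / sy[clean] ** 2
        theta_clean = float(np.sum(w_c * bx[clean] * by[clean])
                            / np.sum(w_c * bx[clean] ** 2))
        if resample_exposure:
            bxc_sim = bx_sim[:, clean]
        else:
            bxc_sim = np.broadcast_to(bx[clean], (n_sim, len(clean)))
        byc_sim = rng.normal(theta_clean * bxc_sim, sy[clean],
                             size=(n_sim, len(clean)))
        theta_sim = (np.sum(w_c * bxc_sim * byc_sim, axis=1)
                     / np.sum(w_c * bxc_sim ** 2, axis=1))
        flagged_idx = []
        for j in candidates:
            t_obs = (by[j] - theta_clean * bx[j]) ** 2 / sy[j] ** 2
            bxj = bx_sim[:, j] if resample_exposure else bx[j]
            byj = rng.normal(theta_sim * bxj, sy[j])
            t_sim = (byj - theta_sim * bxj) ** 2 / sy[j] ** 2
            p_j = float((np.sum(t_sim >= t_obs) + 1) / (n_sim + 1))
            outlier_p[iset.variant_ids[j]] = min(outlier_p[iset.variant_ids[j]], p_j)
            if p_j < alpha_bonf:
                flagged_idx.append(j)
    flagged = tuple(iset.variant_ids[j] for j in flagged_idx)

    distortion_p = None
    if flagged:
        distortion_p = _distortion_p(iset, flagged, rng, n_sim=min(n_sim, 1_000))
    return PressoResult(
        global_rss_observed=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=flagged,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


def _distortion_p(iset: InstrumentSet, flagged: tuple[str, ...],
                  rng: np.random.Generator, n_sim: int) -> float:
    """Does dropping the flagged outliers shift the IVW estimate abnormally?

    The observed distortion (relative shift of the all-instrument estimate
    from the outlier-free one) is compared with shifts obtained by replacing
    the outliers with bootstrap draws from the non-outlier variants.
    """
    keep = iset.subset([v for v in iset.variant_ids if v not in flagged])
    if len(keep) < 2:
        return float("nan")
    theta_no = ivw(keep, model="fixed").estimate
    theta_all = ivw(iset, model="fixed").estimate
    d_obs = abs(theta_all - theta_no)

    bx, by, sy = keep.beta_exposure, keep.beta_outcome, keep.se_outcome
    w = 1.0 / sy ** 2
    n_out = len(flagged)
    idx = rng.integers(0, len(keep), size=(n_sim, n_out))
    num0 = float(np.sum(w * bx * by))
    den0 = float(np.sum(w * bx * bx))
    num = num0 + np.sum((w * bx * by)[idx], axis=1)
    den = den0 + np.sum((w * bx * bx)[idx], axis=1)
    d_sim = np.abs(num / den - theta_no)
    return float((np.sum(d_sim >= d_obs) + 1) / (n_sim + 1))


def effective_sample_size(n_cases: int, n_controls: int) -> float:
    """Effective N for a case-control GWAS: 4 / (1/cases + 1/controls)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def steiger(iset: InstrumentSet, n_exposure: int | None = None,
            n_outcome_effective: float | None = None) -> SteigerResult:
    """Steiger directionality test.

    Variance explained in the exposure is summed over instruments from the
    F statistics, r2_j = F_j/(F_j + N_exp - 2); variance explained in the
    outcome analogously from the outcome z-scores with the effective
    case-control sample size 4/(1/cases + 1/controls).  The causal direction
    exposure -> outcome is supported when the instruments explain more
    variance in the exposure.  The p-value tests equality of the two
    multiple correlations by Fisher z transformation.
    """
    n_exp = n_exposure if n_exposure is not None else iset.n_exposure
    if n_exp is None:
        raise ValueError("exposure sample size required for the Steiger test")
    if n_outcome_effective is None:
        if iset.n_outcome_cases is None or iset.n_outcome_controls is None:
            raise ValueError("outcome case/control counts required")
        n_outcome_effective = effective_sample_size(
            iset.n_outcome_cases, iset.n_outcome_controls)

    f = iset.f_statistics
    r2_exp = float(np.sum(f / (f + n_exp - 2)))
    z_out = (iset.beta_outcome / iset.se_outcome) ** 2
    r2_out = float(np.sum(z_out / (z_out + n_outcome_effective - 2)))

    r_exp = math.sqrt(min(r2_exp, 1.0 - 1e-12))
    r_out = math.sqrt(min(r2_out, 1.0 - 1e-12))
    if r_exp == r_out:
        p = 1.0
    else:
        z = ((math.atanh(r_exp) - math.atanh(r_out))
             / math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_outcome_effective - 3)))
        p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        direction_correct=r2_exp > r2_out,
        p_value=p,
    )


def leave_one_out(iset: InstrumentSet, model: str = "auto") -> LeaveOneOutResult:
    """Re-fit IVW omitting each variant in turn."""
    if len(iset) < 3:
        raise ValueError("leave-one-out needs >= 3 instruments")
    ids = iset.variant_ids
    estimates = tuple(ivw(iset.without(vid), model=model) for vid in ids)
    return LeaveOneOutResult(
        variant_ids=ids,
        estimates=estimates,
        full_estimate=ivw(iset, model=model),
    )
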