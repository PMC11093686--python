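"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generative model is the linear instrumental-variable model the MR
estimators assume.  Each instrument j has a true exposure effect b_Xj; the
true outcome effect is

    b_Yj = theta * b_Xj + alpha_j

where theta is the causal effect and alpha_j a direct (pleiotropic) effect
on the outcome.  Direct effects are defined relative to the
exposure-increasing allele (alpha_j enters as sign(b_Xj) * alpha_j), so a
positive directional mean biases causal estimates upward regardless of how
each variant's allele happens to be coded; this matches how the MR-Egger
intercept is interpreted after orienting exposure betas non-negative.
Observed betas add independent normal sampling noise at the stated standard
errors, mimicking two non-overlapping GWAS samples.

Pleiotropy modes
----------------
* ``none``        alpha_j = 0 — all instruments valid.
* ``balanced``    alpha_j ~ N(0, pleiotropy_scale) — InSIDE holds, IVW
                  remains consistent but overdispersed.
* ``directional`` alpha_j ~ N(directional_mean, pleiotropy_scale) — biases
                  IVW; the Egger intercept estimates directional_mean.
* ``inside_violated`` alpha_j tracks instrument strength
                  (alpha_j = directional_mean * b_Xj / mean|b_X| + noise),
                  breaking the InSIDE assumption that Egger relies on.

Gross outliers — single variants whose outcome beta is displaced by many
standard errors, the signature MR-PRESSO hunts — are planted on top via
``n_outliers`` / ``outlier_shift``.

Default magnitudes mirror the homocysteine instrument panel: exposure
effects of 0.044-0.16 SD with SE 0.008 give F statistics spanning roughly
30-400, and outcome SEs of 0.035 log-odds match mid-sized case-control GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data_model import HarmonizedInstrument, InstrumentSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "OutcomeStudyConfig",
    "simulate_instrument_set",
    "replicate_study_trio",
]

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violated")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-sample summary-statistics generator."""

    n_instruments: int = 14
    true_theta: float = 0.0
    beta_x_range: tuple[float, float] = (0.044, 0.16)
    se_x: float = 0.008
    se_y: float = 0.035
    pleiotropy_mode: str = "none"
    pleiotropy_scale: float = 0.0
    directional_mean: float = 0.0
    n_outliers: int = 0
    outlier_shift: float = 0.0
    seed: int = 0
    n_exposure: int = 44_147
    n_outcome_cases: int = 4_000
    n_outcome_controls: int = 20_000

    def __post_init__(self) -> None:
        if self.n_instruments < 2:
            raise ValueError("need at least 2 instruments")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        lo, hi = self.beta_x_range
        if not (0 < lo <= hi):
            raise ValueError("beta_x_range must be a positive (low, high) pair")
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError("standard-error scales must be positive")
        if self.pleiotropy_scale < 0:
            raise ValueError("pleiotropy_scale must be >= 0")
        if not (0 <= self.n_outliers <= self.n_instruments):
            raise ValueError("n_outliers must lie in [0, n_instruments]")


@dataclass(frozen=True)
class GroundTruth:
    """The latent quantities behind one simulated dataset."""

    theta: float
    beta_x_true: tuple[float, ...]
    alpha: tuple[float, ...]
    outlier_ids: tuple[str, ...]


def _draw_alpha(cfg: SimulationConfig, bx_true: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    J = cfg.n_instruments
    if cfg.pleiotropy_mode == "none":
        return np.zeros(J)
    if cfg.pleiotropy_mode == "balanced":
        return rng.normal(0.0, cfg.pleiotropy_scale, J)
    if cfg.pleiotropy_mode == "directional":
        return rng.normal(cfg.directional_mean, cfg.pleiotropy_scale, J)
    # inside_violated: direct effects proportional to instrument strength
    base = cfg.directional_mean * bx_true / np.mean(np.abs(bx_true))
    return base + rng.normal(0.0, cfg.pleiotropy_scale, J)


def simulate_instrument_set(cfg: SimulationConfig, label: str = "simulated",
                            ) -> tuple[InstrumentSet, GroundTruth]:
    """Draw one synthetic harmonized instrument set plus its ground truth.

    Bit-reproducible for a given config (the seed lives in the config).
    """
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_instruments
    lo, hi = cfg.beta_x_range
    bx_true = rng.uniform(lo, hi, J) * rng.choice([-1.0, 1.0], J)
    alpha = np.sign(bx_true) * _draw_alpha(cfg, bx_true, rng)
    by_true = cfg.true_theta * bx_true + alpha

    sx = np.full(J, cfg.se_x, dtype=float)
    sy = np.full(J, cfg.se_y, dtype=float)
    bx_obs = bx_true + rng.normal(0.0, sx)
    by_obs = by_true + rng.normal(0.0, sy)

    ids = tuple(f"sim{j + 1:03d}" for j in range(J))
    outlier_idx = (rng.choice(J, size=cfg.n_outliers, replace=False)
                   if cfg.n_outliers else np.array([], dtype=int))
    by_obs[outlier_idx] += cfg.outlier_shift * sy[outlier_idx]

    instruments = tuple(
        HarmonizedInstrument(ids[j], float(bx_obs[j]), float(sx[j]),
                             float(by_obs[j]), float(sy[j]))
        for j in range(J))
    iset = InstrumentSet(
        label=label,
        instruments=instruments,
        n_exposure=cfg.n_exposure,
        n_outcome_cases=cfg.n_outcome_cases,
        n_outcome_controls=cfg.n_outcome_controls,
    )
    truth = GroundTruth(
        theta=cfg.true_theta,
        beta_x_true=tuple(bx_true),
        alpha=tuple(alpha),
        outlier_ids=tuple(ids[j] for j in sorted(outlier_idx)),
    )
    return iset, truth


@dataclass(frozen=True)
class OutcomeStudyConfig:
    """Per-study overrides for a multi-cohort simulation."""

    label: str
    se_y: float = 0.035
    missing_variants: tuple[str, ...] = ()
    n_cases: int = 4_000
    n_controls: int = 20_000


def replicate_study_trio(cfg: SimulationConfig,
                         studies: Sequence[OutcomeStudyConfig],
                         ) -> tuple[list[InstrumentSet], GroundTruth]:
    """One shared exposure draw, several independent outcome draws.

    Mirrors a multi-cohort two-sample design: every outcome study reuses the
    same observed exposure statistics (one exposure GWAS) but draws its own
    outcome noise at its own SE scale, and may lack some variants entirely
    (an availability mask), as when a cohort's imputation panel misses them.
    """
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_instruments
    lo, hi = cfg.beta_x_range
    bx_true = rng.uniform(lo, hi, J) * rng.choice([-1.0, 1.0], J)
    alpha = np.sign(bx_true) * _draw_alpha(cfg, bx_true, rng)
    by_true = cfg.true_theta * bx_true + alpha
    sx = np.full(J, cfg.se_x)
    bx_obs = bx_true + rng.normal(0.0, sx)
    ids = tuple(f"sim{j + 1:03d}" for j in range(J))

    sets: list[InstrumentSet] = []
    for study in studies:
        unknown = set(study.missing_variants) - set(ids)
        if unknown:
            raise ValueError(f"{study.label}: mask names unknown variants {sorted(unknown)}")
        sy = np.full(J, study.se_y)
        by_obs = by_true + rng.normal(0.0, sy)
        instruments = tuple(
            HarmonizedInstrument(ids[j], float(bx_obs[j]), float(sx[j]),
                                 float(by_obs[j]), float(sy[j]))
            for j in range(J) if ids[j] not in study.missing_variants)
        sets.append(InstrumentSet(
            label=study.label,
            instruments=instruments,
            n_exposure=cfg.n_exposure,
            n_outcome_cases=study.n_cases,
            n_outcome_controls=study.n_controls,
        ))
    truth = GroundTruth(cfg.true_theta, tuple(bx_true), tuple(alpha), ())
    return sets, truth
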