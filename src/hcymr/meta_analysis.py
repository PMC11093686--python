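"""Pooling per-study causal estimates across outcome cohorts.

The per-study IVW estimates (log-odds of PCOS per SD of homocysteine) are
combined by inverse-variance weighting.  Fixed-effect pooling is the
default; DerSimonian-Laird random effects is available when between-study
heterogeneity should widen the interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, Z_95

__all__ = ["MetaResult", "meta_fixed", "meta_random", "forest_table"]


@dataclass(frozen=True)
class MetaResult:
    pooled_estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    per_study_weights: tuple[float, ...]
    q_between: float
    q_p_value: float
    model: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.pooled_estimate <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")
        if abs(sum(self.per_study_weights) - 1.0) > 1e-9:
            raise ValueError("normalized weights must sum to 1")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.pooled_estimate)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)


def _pool(theta: np.ndarray, w: np.ndarray, model: str) -> MetaResult:
    pooled = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(theta) - 1
    p = max(float(2.0 * stats.norm.sf(abs(pooled / se))), 5e-324)
    return MetaResult(
        pooled_estimate=pooled,
        se=se,
        ci_low=pooled - Z_95 * se,
        ci_high=pooled + Z_95 * se,
        p_value=p,
        per_study_weights=tuple(w / np.sum(w)),
        q_between=q,
        q_p_value=float(stats.chi2.sf(q, df)),
        model=model,
    )


def _validate(estimates: Sequence[MREstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) < 2:
        raise ValueError("meta-analysis requires at least 2 studies")
    theta = np.array([e.estimate for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(se)) and np.all(se > 0)):
        raise ValueError("every study needs a finite estimate and positive se")
    return theta, se


def meta_fixed(estimates: Sequence[MREstimate]) -> MetaResult:
    """Fixed-effect inverse-variance pooling of log-odds estimates."""
    theta, se = _validate(estimates)
    return _pool(theta, 1.0 / se ** 2, "fixed")


def meta_random(estimates: Sequence[MREstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling."""
    theta, se = _validate(estimates)
    w = 1.0 / se ** 2
    pooled = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(theta) - 1
    c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return _pool(theta, 1.0 / (se ** 2 + tau2), "random")


def forest_table(estimates: Sequence[MREstimate], labels: Sequence[str],
                 pooled: MetaResult) -> pd.DataFrame:
    """Forest-plot data: one row per study plus the combined row.

    Columns are on the odds-ratio scale with normalized pooling weights;
    this is the numeric content of the usual meta-analysis forest plot.
    """
    if len(estimates) != len(labels):
        raise ValueError("one label required per study")
    rows = [
        {"study": lab, "odds_ratio": e.odds_ratio,
         "or_ci_low": e.or_ci_low, "or_ci_high": e.or_ci_high,
         "weight": wt, "p_value": e.p_value}
        for lab, e, wt in zip(labels, estimates, pooled.per_study_weights)
    ]
    rows.append({
        "study": "Combined", "odds_ratio": pooled.odds_ratio,
        "or_ci_low": pooled.or_ci_low, "or_ci_high": pooled.or_ci_high,
        "weight": 1.0, "p_value": pooled.p_value,
    })
    return pd.DataFrame(rows)
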