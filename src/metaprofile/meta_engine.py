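"""Standardized-mean-difference meta-analysis for two-arm summary data.

The effect size is Hedges' g: the between-arm mean difference divided by the
pooled SD, times the small-sample bias correction
``J = 1 - 3/(4*(n_b + n_f - 2) - 1)``. The contrast is follow-up minus
baseline, so a negative g is a *decrease* of the indicator at follow-up.
Arms are treated as two independent groups (only per-arm mean/SD/n are
available from study-level extraction; no within-subject correlation is
modeled).

Pooling is inverse-variance. The fixed-effects model assumes one common true
effect; the random-effects model adds the DerSimonian-Laird between-study
variance tau^2 to every weight. Heterogeneity is assessed by Cochran's Q
(chi-square with k-1 df) and I^2 = max(0, 100*(Q - df)/Q); following the
conventional decision rule, the random-effects model is selected iff the
heterogeneity test has p < 0.05 *and* I^2 > 50%, otherwise fixed effects.
Significance of the pooled effect is a two-sided normal z-test at alpha=0.05
with a normal-quantile 95% CI; no multiple-testing correction is applied
across indicators or profiles.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

Z975 = float(stats.norm.ppf(0.975))


class MetaError(ValueError):
    pass


class DegenerateInputError(MetaError):
    pass


@dataclass(frozen=True)
class EffectSize:
    """One study's standardized mean difference with its standard error."""

    study_id: str
    indicator: str
    g: float
    se: float
    n_b: int
    n_f: int


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q test and derived heterogeneity measures."""

    Q: float
    df: int
    p_Q: float
    I2: float  # percent, in [0, 100]
    tau2: float


class Direction(enum.Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    NONE = "none"


@dataclass(frozen=True)
class MetaResult:
    """Pooled result for one indicator within one profile."""

    indicator: str
    k: int
    model: str  # "fixed" | "random"
    pooled_g: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    het: HeterogeneityResult | None
    significant: bool
    direction: Direction
    flagged: bool = False  # k below the configured minimum for pooling

    def to_dict(self) -> dict:
        d = {
            "indicator": self.indicator,
            "k": self.k,
            "model": self.model,
            "pooled_g": self.pooled_g,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "z": self.z,
            "p": self.p,
            "Q": self.het.Q if self.het else math.nan,
            "p_Q": self.het.p_Q if self.het else math.nan,
            "I2": self.het.I2 if self.het else math.nan,
            "tau2": self.het.tau2 if self.het else math.nan,
            "significant": self.significant,
            "direction": self.direction.value,
            "flagged": self.flagged,
        }
        return d


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    g: float
    se: float


class PooledEstimate(NamedTuple):
    pooled_g: float
    se: float
    z: float
    p: float


def hedges_g(
    baseline: tuple[float, float, int],
    followup: tuple[float, float, int],
    study_id: str = "",
    indicator: str = "",
    bias_correction: bool = True,
) -> EffectSize:
    """Standardized mean difference (follow-up minus baseline) for one study.

    Parameters are ``(mean, sd, n)`` triples. With ``bias_correction=False``
    the estimator is plain Cohen's d. The sampling variance is
    ``(n_b + n_f)/(n_b*n_f) + g^2/(2*(n_b + n_f))``.
    """
    m_b, sd_b, n_b = baseline
    m_f, sd_f, n_f = followup
    n_b, n_f = int(n_b), int(n_f)
    if n_b < 1 or n_f < 1 or n_b + n_f < 3:
        raise DegenerateInputError(
            f"arm sizes too small for an effect size: n_b={n_b}, n_f={n_f}"
        )
    dof = n_b + n_f - 2
    s_pooled = math.sqrt(((n_b - 1) * sd_b**2 + (n_f - 1) * sd_f**2) / dof)
    if s_pooled <= 0:
        raise DegenerateInputError("pooled SD is zero; SMD undefined")
    d = (m_f - m_b) / s_pooled
    J = 1.0 - 3.0 / (4.0 * dof - 1.0) if bias_correction else 1.0
    g = J * d
    ntot = n_b + n_f
    var = ntot / (n_b * n_f) + g**2 / (2.0 * ntot)
    return EffectSize(study_id, indicator, g, math.sqrt(var), n_b, n_f)


def _weights(effects: Sequence[EffectSize], tau2: float = 0.0) -> np.ndarray:
    se = np.array([e.se for e in effects], dtype=float)
    if np.any(se <= 0):
        raise DegenerateInputError("all standard errors must be positive")
    return 1.0 / (se**2 + tau2)


def _pool(effects: Sequence[EffectSize], tau2: float) -> PooledEstimate:
    if not effects:
        raise MetaError("cannot pool an empty list of effects")
    w = _weights(effects, tau2)
    g = np.array([e.g for e in effects], dtype=float)
    pooled = float(np.sum(w * g) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PooledEstimate(pooled, se, z, p)


def fixed_effect_pool(effects: Sequence[EffectSize]) -> PooledEstimate:
    """Inverse-variance fixed-effects pooling."""
    return _pool(effects, tau2=0.0)


def random_effects_pool(effects: Sequence[EffectSize], tau2: float) -> PooledEstimate:
    """Random-effects pooling with weights 1/(se^2 + tau^2)."""
    if tau2 < 0:
        raise MetaError("tau2 must be non-negative")
    return _pool(effects, tau2=tau2)


def heterogeneity(effects: Sequence[EffectSize]) -> HeterogeneityResult:
    """Cochran's Q, I^2 and the DerSimonian-Laird tau^2 estimate (k >= 2)."""
    k = len(effects)
    if k < 2:
        raise MetaError("heterogeneity is undefined for k < 2")
    w = _weights(effects)
    g = np.array([e.g for e in effects], dtype=float)
    pooled = float(np.sum(w * g) / np.sum(w))
    Q = float(np.sum(w * (g - pooled) ** 2))
    df = k - 1
    p_Q = float(stats.chi2.sf(Q, df))
    I2 = 0.0 if Q <= 0 else max(0.0, 100.0 * (Q - df) / Q)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(Q=Q, df=df, p_Q=p_Q, I2=I2, tau2=tau2)


def select_and_pool(
    effects: Sequence[EffectSize],
    alpha_het: float = 0.05,
    i2_cut: float = 50.0,
    alpha: float = 0.05,
    min_k: int = 2,
) -> MetaResult:
    """Pool one indicator's effects with the fixed/random decision rule.

    The random-effects model is used iff the heterogeneity test has
    ``p_Q < alpha_het`` *and* ``I^2 > i2_cut`` (a conjunction); otherwise the
    fixed-effects model. A single study is pooled trivially under the fixed
    model with heterogeneity undefined; results with ``k < min_k`` are
    flagged rather than suppressed.
    """
    if not effects:
        raise MetaError("cannot pool an empty list of effects")
    k = len(effects)
    indicator = effects[0].indicator
    if k == 1:
        het = None
        model = "fixed"
        est = fixed_effect_pool(effects)
    else:
        het = heterogeneity(effects)
        if het.p_Q < alpha_het and het.I2 > i2_cut:
            model = "random"
            est = random_effects_pool(effects, het.tau2)
        else:
            model = "fixed"
            est = fixed_effect_pool(effects)
    significant = est.p < alpha
    if significant:
        direction = Direction.INCREASE if est.pooled_g > 0 else Direction.DECREASE
    else:
        direction = Direction.NONE
    return MetaResult(
        indicator=indicator,
        k=k,
        model=model,
        pooled_g=est.pooled_g,
        se=est.se,
        ci_low=est.pooled_g - Z975 * est.se,
        ci_high=est.pooled_g + Z975 * est.se,
        z=est.z,
        p=est.p,
        het=het,
        significant=significant,
        direction=direction,
        flagged=k < min_k,
    )


def funnel_points(effects: Sequence[EffectSize]) -> list[FunnelPoint]:
    """One (g, se) point per study, untransformed, for funnel-plot inspection."""
    return [FunnelPoint(e.study_id, e.g, e.se) for e in effects]
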