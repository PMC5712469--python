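"""Meta-analytic layer: assembling samples and summarising them.

A meta-analysis here is the set of K published effect estimates of one
simulated literature, together with the counterfactual first-attempt
estimates of the same authors. Summaries are the inverse-variance
fixed-effect estimate, Cochran's Q / I-squared heterogeneity, the shares of
studies that committed and succeeded at publication bias, and the p-value
deflation factor -- the ratio of the fixed-effect meta-analytic p-value on
the published sample to that on the first-attempt sample, i.e. how much
selective publication alone shrank the meta-analytic p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .dgp import (
    ConditionSpec,
    EffectTable,
    SimConstants,
    DEFAULT_CONSTANTS,
)

__all__ = [
    "MetaSample",
    "MetaSummary",
    "FixedEffectResult",
    "assemble_meta_sample",
    "fixed_effect_meta",
    "i_squared",
    "deflation_factor",
    "prevalence_shares",
    "summarize_meta_sample",
    "read_effect_table",
]

LN2 = math.log(2.0)


@dataclass
class MetaSample:
    """Published and counterfactual first-attempt estimates of one meta-analysis."""

    condition: ConditionSpec
    published: EffectTable
    firsts: EffectTable
    committed: np.ndarray
    successful: np.ndarray

    @property
    def k(self) -> int:
        return len(self.published)

    @property
    def committed_count(self) -> int:
        return int(self.committed.sum())

    @property
    def successful_count(self) -> int:
        return int(self.successful.sum())


@dataclass(frozen=True)
class FixedEffectResult:
    theta: float
    se: float
    z: float
    p: float
    log_p: float  # natural log of the two-sided p, safe against underflow


@dataclass(frozen=True)
class MetaSummary:
    theta_fe: float
    se_fe: float
    z_fe: float
    p_fe: float
    q_stat: float
    i2: float
    committed_share: float
    successful_share: float
    success_given_committed: float
    deflation: float


def assemble_meta_sample(
    condition: ConditionSpec,
    constants: SimConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
    method: str = "fast",
) -> MetaSample:
    """Simulate K independent primary studies and collect their estimates.

    ``method='fast'`` uses the vectorised batch engines; ``'reference'``
    loops over the per-study full-data procedures (slow, for validation).
    """
    from . import behavior  # local import to keep module load order simple

    rng = np.random.default_rng() if rng is None else rng
    if method == "fast":
        firsts, published, committed, successful = behavior.batch_meta_sample_arrays(
            condition, constants, rng
        )
    elif method == "reference":
        studies = [
            behavior.simulate_primary_study(condition, constants, rng)
            for _ in range(condition.k)
        ]
        from .dgp import EffectTable as ET

        firsts = ET.from_estimates([s.first for s in studies])
        published = ET.from_estimates([s.published for s in studies])
        committed = np.array([s.committed for s in studies])
        successful = np.array([s.successful_at(constants.alpha) for s in studies])
    else:
        raise ValueError(f"unknown method {method!r}")
    return MetaSample(condition, published, firsts, committed, successful)


def fixed_effect_meta(es: np.ndarray, se: np.ndarray) -> FixedEffectResult:
    """Inverse-variance fixed-effect pooled estimate with a two-sided normal p."""
    es = np.asarray(es, dtype=float)
    se = np.asarray(se, dtype=float)
    if es.size < 2:
        raise ValueError("need at least 2 estimates")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / se**2
    theta = float(np.sum(w * es) / np.sum(w))
    se_fe = float(1.0 / np.sqrt(np.sum(w)))
    z = theta / se_fe
    log_p = LN2 + float(special.log_ndtr(-abs(z)))
    return FixedEffectResult(theta=theta, se=se_fe, z=z, p=math.exp(log_p), log_p=log_p)


def cochran_q(es: np.ndarray, se: np.ndarray) -> float:
    es = np.asarray(es, dtype=float)
    se = np.asarray(se, dtype=float)
    w = 1.0 / se**2
    theta = np.sum(w * es) / np.sum(w)
    return float(np.sum(w * (es - theta) ** 2))


def i_squared(es: np.ndarray, se: np.ndarray) -> float:
    """Higgins I² in percent: share of between-study variation in Q, floored at 0."""
    es = np.asarray(es, dtype=float)
    if es.size < 2:
        raise ValueError("need at least 2 estimates")
    q = cochran_q(es, se)
    if q == 0.0:
        return 0.0
    return max(0.0, (q - (es.size - 1)) / q) * 100.0


def deflation_factor(sample: MetaSample) -> float:
    """p(published) / p(first attempts), computed on the log scale.

    Exactly 1 whenever nothing was selected (published == firsts).
    """
    pub = fixed_effect_meta(sample.published.es, sample.published.se)
    first = fixed_effect_meta(sample.firsts.es, sample.firsts.se)
    return math.exp(pub.log_p - first.log_p)


def prevalence_shares(sample: MetaSample) -> tuple[float, float, float]:
    """(committed share, successful share, success-given-committed).

    The conditional share is NaN when no study committed bias.
    """
    k = sample.k
    committed = sample.committed_count
    successful = sample.successful_count
    cond = successful / committed if committed > 0 else float("nan")
    return committed / k, successful / k, cond


def summarize_meta_sample(sample: MetaSample) -> MetaSummary:
    fe = fixed_effect_meta(sample.published.es, sample.published.se)
    committed_share, successful_share, cond = prevalence_shares(sample)
    return MetaSummary(
        theta_fe=fe.theta,
        se_fe=fe.se,
        z_fe=fe.z,
        p_fe=fe.p,
        q_stat=cochran_q(sample.published.es, sample.published.se),
        i2=i_squared(sample.published.es, sample.published.se),
        committed_share=committed_share,
        successful_share=successful_share,
        success_given_committed=cond,
        deflation=deflation_factor(sample),
    )


def read_effect_table(path) -> EffectTable:
    """Load a user-supplied (es, se[, n]) CSV into an EffectTable.

    The two-sided p is recomputed from the normal approximation when the
    table carries no per-study degrees of freedom.
    """
    frame = pd.read_csv(path)
    missing = {"es", "se"} - set(frame.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    bad = np.flatnonzero(~(frame["se"].to_numpy(dtype=float) > 0))
    if bad.size:
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"non-positive se in CSV line(s) {rows}")
    es = frame["es"].to_numpy(dtype=float)
    se = frame["se"].to_numpy(dtype=float)
    n = frame["n"].to_numpy(dtype=np.int64) if "n" in frame else np.zeros(len(frame), np.int64)
    z = es / se
    p = 2.0 * special.ndtr(-np.abs(z))
    return EffectTable(es=es, se=se, p=np.maximum(p, 5e-324), n=n,
                       df=np.maximum(n - 2, 0))
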