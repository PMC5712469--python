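"""The four publication-bias tests with a harmonised result contract.

All tests consume a flat table of effect sizes and standard errors (and,
when available, the studies' own two-sided p-values) and return a
:class:`TestResult`. Degenerate inputs -- no significant positive study for
p-uniform, an empty caliper window, constant precision for the funnel
regression -- yield ``applicable=False`` instead of an exception, so that
Monte Carlo aggregation can treat them as missing observations.

Formulations (one-sided throughout, targeting bias in favour of positive
significant effects):

* FAT (funnel-plot asymmetry / Egger-type regression): OLS of z_i = es_i/se_i
  on an intercept and precision 1/se_i; an intercept above zero means small
  (imprecise) studies report systematically larger standardised effects.
* p-uniform: for every significant positive study, the p-value conditional
  on just clearing the threshold given the fixed-effect mean effect; under
  no selection these are Uniform(0,1), so L = sum(-ln q_i) ~ Gamma(m, 1).
  Selection piles q_i near 1 (just-significant excess), shrinking L, hence a
  lower-tail Gamma test.
* TES (test of excess significance): compares the observed number of
  significant studies O (either sign, matching the test's all-studies
  sample) with the expected number E = sum of per-study two-sided powers at
  the fixed-effect estimate. The two-cell chi-square A = (O-E)^2/E +
  (O-E)^2/(K-E) is converted to a one-sided test via its signed square root,
  p = Phi-bar(sign(O-E) * sqrt(A)), so only an excess of significant
  results counts as evidence of bias.
* Caliper test: counts z-statistics just over vs. just under the critical
  value; an exact one-sided binomial test of equal probability. The default
  caliper is multiplicative (width w spans z_crit*(1-w) to z_crit*(1+w),
  the over side closed at z_crit); an additive dialect (+- w in z units) is
  available.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import special, stats

from .dgp import EffectTable

__all__ = [
    "TestResult",
    "fat",
    "p_uniform_test",
    "tes",
    "caliper_test",
    "run_all_tests",
    "DEFAULT_TEST_NAMES",
]

DEFAULT_TEST_NAMES = ("PU", "FAT", "TES", "CT3", "CT5", "CT10", "CT15")


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    significant: bool
    applicable: bool
    detail: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.significant and not self.applicable:
            raise ValueError("a non-applicable test cannot be significant")


def _not_applicable(name: str, **detail: Any) -> TestResult:
    return TestResult(name, float("nan"), float("nan"), False, False, detail)


def _coerce(table, se=None, p=None):
    """Accept an EffectTable or plain (es, se[, p]) arrays."""
    if isinstance(table, EffectTable):
        return table.es, table.se, table.p
    es = np.asarray(table, dtype=float)
    se = np.asarray(se, dtype=float)
    if p is None:
        p = 2.0 * special.ndtr(-np.abs(es / se))
    return es, se, np.asarray(p, dtype=float)


def fat(table, se=None, p=None, alpha: float = 0.05,
        alternative: str = "greater") -> TestResult:
    """Funnel-asymmetry (Egger-type) regression test.

    Regression of the standardised effect on precision; the test statistic
    is the intercept's t-ratio with K - 2 degrees of freedom. One-sided
    (intercept > 0) by default.
    """
    es, se_arr, _ = _coerce(table, se, p)
    k = es.size
    if k < 3:
        return _not_applicable("FAT", reason="fewer than 3 estimates")
    z = es / se_arr
    prec = 1.0 / se_arr
    xbar, zbar = prec.mean(), z.mean()
    cxx = float(np.sum((prec - xbar) ** 2))
    if cxx <= 0:
        return _not_applicable("FAT", reason="constant precision")
    slope = float(np.sum((prec - xbar) * (z - zbar))) / cxx
    intercept = zbar - slope * xbar
    resid = z - intercept - slope * prec
    df = k - 2
    sigma2 = float(resid @ resid) / df
    se_int = np.sqrt(sigma2 * (1.0 / k + xbar**2 / cxx))
    t_stat = intercept / se_int
    if alternative == "greater":
        p_val = float(stats.t.sf(t_stat, df))
    elif alternative == "two-sided":
        p_val = 2.0 * float(stats.t.sf(abs(t_stat), df))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(
        "FAT", float(t_stat), p_val, bool(p_val < alpha), True,
        {"intercept": float(intercept), "intercept_se": float(se_int),
         "slope": slope, "df": df},
    )


def p_uniform_test(table, se=None, p=None, alpha: float = 0.05,
                   theta: float | None = None) -> TestResult:
    """p-uniform publication-bias test on the significant positive studies.

    q_i = P(ES > es_i | theta) / P(ES > cv_i | theta) with cv_i the one-sided
    5% critical effect se_i * z_{1-alpha/2}; computed on the log scale via
    log_ndtr so that extreme z-statistics do not underflow. ``theta``
    defaults to the fixed-effect estimate from *all* studies.
    """
    es, se_arr, p_arr = _coerce(table, se, p)
    if theta is None:
        from .meta import fixed_effect_meta

        theta = fixed_effect_meta(es, se_arr).theta
    z_crit = float(-special.ndtri(alpha / 2.0))
    sel = (p_arr < alpha) & (es > 0)
    m = int(sel.sum())
    if m == 0:
        return _not_applicable("PU", reason="no significant positive estimate")
    es_s, se_s = es[sel], se_arr[sel]
    cv = se_s * z_crit
    log_q = special.log_ndtr(-(es_s - theta) / se_s) - special.log_ndtr(-(cv - theta) / se_s)
    log_q = np.minimum(log_q, 0.0)
    stat = float(-np.sum(log_q))
    p_val = float(stats.gamma.cdf(stat, a=m))  # lower tail: small L = excess of q near 1
    return TestResult(
        "PU", stat, p_val, bool(p_val < alpha), True,
        {"m": m, "theta": float(theta), "q": np.exp(log_q)},
    )


def _tes_statistic(o: float, e: float, k: int) -> float:
    """Two-cell chi-square comparing observed vs expected significant counts."""
    return (o - e) ** 2 / e + (o - e) ** 2 / (k - e)


def tes(table, se=None, p=None, alpha: float = 0.05) -> TestResult:
    """Test of excess significance against the fixed-effect mean effect.

    Per-study power is the normal-approximation probability of a two-sided
    significant result at the fixed-effect estimate theta; O counts
    significant studies of either sign. One-sided: the statistic is the
    signed square root of the two-cell chi-square, rejecting only for an
    excess of significant results.
    """
    es, se_arr, p_arr = _coerce(table, se, p)
    k = es.size
    if k < 2:
        return _not_applicable("TES", reason="fewer than 2 estimates")
    from .meta import fixed_effect_meta

    theta = fixed_effect_meta(es, se_arr).theta
    z_crit = float(-special.ndtri(alpha / 2.0))
    mu = theta / se_arr
    power = special.ndtr(mu - z_crit) + special.ndtr(-mu - z_crit)
    e = float(np.sum(power))
    o = int(np.sum(p_arr < alpha))
    if e <= 0 or e >= k:
        return _not_applicable("TES", reason="degenerate expected count", E=e, O=o)
    stat = math.copysign(math.sqrt(_tes_statistic(o, e, k)), o - e)
    p_val = float(special.ndtr(-stat))
    return TestResult(
        "TES", float(stat), p_val, bool(p_val < alpha), True,
        {"E": e, "O": o, "theta": float(theta)},
    )


def caliper_test(table, se=None, p=None, width: float = 0.05,
                 alpha: float = 0.05, dialect: str = "multiplicative") -> TestResult:
    """Caliper test around the two-sided critical z-value.

    Over-caliper: z in [z_crit, upper]; under-caliper: z in [lower, z_crit).
    Exact one-sided binomial test of over-representation of just-significant
    statistics.
    """
    if not 0 < width < 1:
        raise ValueError("width must be in (0, 1)")
    es, se_arr, _ = _coerce(table, se, p)
    z = es / se_arr
    z_crit = float(-special.ndtri(alpha / 2.0))
    if dialect == "multiplicative":
        lower, upper = z_crit * (1 - width), z_crit * (1 + width)
    elif dialect == "additive":
        lower, upper = z_crit - width, z_crit + width
    else:
        raise ValueError(f"unknown caliper dialect {dialect!r}")
    over = int(np.sum((z >= z_crit) & (z <= upper)))
    under = int(np.sum((z >= lower) & (z < z_crit)))
    name = f"CT{width * 100:g}"
    if over + under == 0:
        return _not_applicable(name, over=0, under=0)
    p_val = float(stats.binom.sf(over - 1, over + under, 0.5))
    return TestResult(
        name, float(over), p_val, bool(p_val < alpha), True,
        {"over": over, "under": under, "width": width, "dialect": dialect},
    )


def run_all_tests(
    table,
    se=None,
    p=None,
    alpha: float = 0.05,
    caliper_widths: tuple[float, ...] = (0.03, 0.05, 0.10, 0.15),
    caliper_dialect: str = "multiplicative",
    fat_alternative: str = "greater",
) -> dict[str, TestResult]:
    """Apply FAT, PU, TES and all caliper widths to one meta-analytic sample."""
    es, se_arr, p_arr = _coerce(table, se, p)
    out = {
        "PU": p_uniform_test(es, se_arr, p_arr, alpha=alpha),
        "FAT": fat(es, se_arr, p_arr, alpha=alpha, alternative=fat_alternative),
        "TES": tes(es, se_arr, p_arr, alpha=alpha),
    }
    for w in caliper_widths:
        res = caliper_test(es, se_arr, p_arr, width=w, alpha=alpha, dialect=caliper_dialect)
        out[res.test_name] = res
    return out
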