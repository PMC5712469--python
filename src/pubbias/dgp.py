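"""Data-generating process for simulated primary studies.

Each simulated "study" is a bivariate linear regression literature entry:
a dataset (x, y) with y = beta * x + eps, eps ~ N(0, sigma_eps), x ~ N(0,
sigma_x), analysed by OLS. The slope on x, its standard error and the
two-sided t-test p-value are what a study "reports" and what enters a
meta-analysis. Sample sizes follow a right-skewed absolute-normal law
truncated at n > 30, mimicking the spread of study sizes in applied fields.

Two generation routes exist and are distributionally identical (tested):

* the *data route* -- draw the raw dataset and run OLS on it; required
  whenever the analysis is re-specified on the same data (p-hacking with
  collider covariates);
* the *sampling-law route* (:func:`sample_effect_table`) -- draw the OLS
  slope and standard error directly from their exact finite-sample
  distribution given N, which is orders of magnitude faster and is used
  for first attempts and file-drawer retries, where each attempt is an
  independent dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimConstants",
    "BetaSpec",
    "ConditionSpec",
    "Dataset",
    "EffectEstimate",
    "EffectTable",
    "draw_sample_size",
    "simulate_dataset",
    "make_colliders",
    "fit_ols",
    "sample_effect_table",
    "bivariate_ols_flat",
]


@dataclass(frozen=True)
class SimConstants:
    """Fixed parameters of the data-generating process.

    Defaults are the study conditions: predictor sd 2, regression error sd
    10 (so per-study slope se^2 ~= 25/N), sample sizes |N(mu, 150)|
    truncated strictly above 30, collider weights (gamma, gamma_y) =
    (0.5, -0.5), 5% significance threshold, at most 9 extra file-drawer
    datasets, and caliper widths 3/5/10/15% of the critical value.

    The collider y-weight is negative by default so that conditioning on a
    collider inflates the x-slope (population partial slope +0.2 at beta =
    0), making the model search a workable p-hacking strategy; with a
    positive y-weight the induced bias is negative and the strategy
    essentially never reaches positive significance.
    """

    sigma_x: float = 2.0
    sigma_eps: float = 10.0
    n_sd: float = 150.0
    n_min: int = 30
    gamma: float = 0.5
    gamma_y: float = -0.5
    sigma_z: float = 10.0
    alpha: float = 0.05
    max_extra_samples: int = 9
    caliper_widths: tuple[float, ...] = (0.03, 0.05, 0.10, 0.15)

    def __post_init__(self) -> None:
        for name in ("sigma_x", "sigma_eps", "n_sd", "sigma_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")
        if self.max_extra_samples < 0:
            raise ValueError("max_extra_samples must be >= 0")
        if any(not 0 < w < 1 for w in self.caliper_widths):
            raise ValueError("caliper widths must be in (0, 1)")


DEFAULT_CONSTANTS = SimConstants()


@dataclass(frozen=True)
class BetaSpec:
    """How a study's true slope is drawn.

    ``fixed``    -- every study shares the same beta.
    ``uniform``  -- per-study beta ~ Uniform(low, high); the heterogeneous
                    condition, Uniform(0, 2), between-study variance 1/3.
    ``mixture``  -- per-study beta drawn uniformly from a discrete set.
    """

    kind: str = "fixed"
    value: float = 0.0
    low: float = 0.0
    high: float = 2.0
    mixture: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "uniform", "mixture"):
            raise ValueError(f"unknown BetaSpec kind {self.kind!r}")
        if self.kind == "uniform" and not self.high > self.low:
            raise ValueError("uniform BetaSpec needs high > low")
        if self.kind == "mixture" and len(self.mixture) == 0:
            raise ValueError("mixture BetaSpec needs a non-empty set")

    @classmethod
    def fixed(cls, value: float) -> "BetaSpec":
        return cls(kind="fixed", value=float(value))

    @classmethod
    def heterogeneous(cls, low: float = 0.0, high: float = 2.0) -> "BetaSpec":
        """Continuous uniform heterogeneity over the simulated effect range."""
        return cls(kind="uniform", low=low, high=high)

    @classmethod
    def discrete(cls, values: Sequence[float]) -> "BetaSpec":
        return cls(kind="mixture", mixture=tuple(float(v) for v in values))

    @property
    def label(self) -> str:
        if self.kind == "fixed":
            return f"{self.value:g}"
        return "het"

    def draw(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.kind == "fixed":
            return self.value if size is None else np.full(size, self.value)
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size)
        return rng.choice(np.asarray(self.mixture, dtype=float), size=size)


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the simulation design matrix.

    ``intent`` is the probability that a study's author is willing to run
    extra analyses after a non-significant or negative first result;
    ``form`` says what those extra analyses are.
    """

    beta_spec: BetaSpec
    mu_n: float
    k: int
    intent: float
    form: str  # "none" | "file_drawer" | "p_hacking"

    def __post_init__(self) -> None:
        if self.form not in ("none", "file_drawer", "p_hacking"):
            raise ValueError(f"unknown bias form {self.form!r}")
        if not 0 <= self.intent <= 1:
            raise ValueError("intent must be in [0, 1]")
        if (self.intent == 0) != (self.form == "none"):
            raise ValueError("intent == 0 if and only if form == 'none'")
        if self.mu_n <= 0:
            raise ValueError("mu_n must be > 0")
        if self.k < 2:
            raise ValueError("k must be >= 2")

    @property
    def condition_id(self) -> str:
        form_key = {"none": "none", "file_drawer": "fd", "p_hacking": "ph"}[self.form]
        return (
            f"b{self.beta_spec.label}-n{self.mu_n:g}-k{self.k}"
            f"-pb{round(self.intent * 100)}-{form_key}"
        )


@dataclass
class Dataset:
    """Raw data of one primary study (plus optional collider covariates)."""

    x: np.ndarray
    y: np.ndarray
    z: list[np.ndarray] = field(default_factory=list)
    beta_true: float = 0.0

    @property
    def n(self) -> int:
        return self.x.size

    def __post_init__(self) -> None:
        if self.y.size != self.n or any(zj.size != self.n for zj in self.z):
            raise ValueError("x, y and all z must have identical length")

    def to_frame(self) -> pd.DataFrame:
        cols = {"x": self.x, "y": self.y}
        for j, zj in enumerate(self.z, start=1):
            cols[f"z{j}"] = zj
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class EffectEstimate:
    """One published regression result: the slope on x and its uncertainty."""

    es: float
    se: float
    p_two_sided: float
    n: int
    df: int
    model_id: str = "x"

    @property
    def z_stat(self) -> float:
        return self.es / self.se

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be > 0")
        if not 0 < self.p_two_sided <= 1:
            raise ValueError("p_two_sided must be in (0, 1]")


@dataclass
class EffectTable:
    """Column-vector form of K effect estimates (the meta-analytic sample)."""

    es: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: np.ndarray
    df: np.ndarray

    def __len__(self) -> int:
        return self.es.size

    @property
    def z(self) -> np.ndarray:
        return self.es / self.se

    def copy(self) -> "EffectTable":
        return EffectTable(*(getattr(self, f).copy() for f in ("es", "se", "p", "n", "df")))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"es": self.es, "se": self.se, "p": self.p, "n": self.n, "df": self.df}
        )

    @classmethod
    def from_estimates(cls, estimates: Sequence[EffectEstimate]) -> "EffectTable":
        return cls(
            es=np.array([e.es for e in estimates]),
            se=np.array([e.se for e in estimates]),
            p=np.array([e.p_two_sided for e in estimates]),
            n=np.array([e.n for e in estimates]),
            df=np.array([e.df for e in estimates]),
        )


def draw_sample_size(
    mu_n: float,
    constants: SimConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
    size: int | tuple[int, ...] | None = None,
) -> int | np.ndarray:
    """Draw study sample sizes: round(|Normal(mu_n, n_sd)|) conditioned on > n_min.

    Rejection sampling; the acceptance region is applied after rounding, so
    the smallest possible N is n_min + 1.
    """
    if mu_n <= 0:
        raise ValueError("mu_n must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    scalar = size is None
    total = 1 if scalar else int(np.prod(size))
    out = np.empty(total, dtype=np.int64)
    filled = 0
    while filled < total:
        batch = max(total - filled, 16)
        draws = np.rint(np.abs(rng.normal(mu_n, constants.n_sd, 2 * batch))).astype(np.int64)
        draws = draws[draws > constants.n_min][: total - filled]
        out[filled : filled + draws.size] = draws
        filled += draws.size
    if scalar:
        return int(out[0])
    return out.reshape(size)


def simulate_dataset(
    beta_spec: BetaSpec,
    n: int,
    constants: SimConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
) -> Dataset:
    """Generate one study's raw data under y = beta x + eps."""
    if n <= constants.n_min:
        raise ValueError(f"n must exceed n_min = {constants.n_min}")
    rng = np.random.default_rng() if rng is None else rng
    beta = float(beta_spec.draw(rng))
    x = rng.normal(0.0, constants.sigma_x, n)
    eps = rng.normal(0.0, constants.sigma_eps, n)
    return Dataset(x=x, y=beta * x + eps, beta_true=beta)


def make_colliders(
    dataset: Dataset,
    constants: SimConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
    n_colliders: int = 3,
) -> Dataset:
    """Attach collider covariates z_j = gamma x + gamma_y y + e_z to a dataset.

    A collider is caused by both the predictor and the outcome, so
    conditioning on it biases the x -> y slope -- which is exactly what the
    simulated p-hacker exploits.
    """
    rng = np.random.default_rng() if rng is None else rng
    z = [
        constants.gamma * dataset.x
        + constants.gamma_y * dataset.y
        + rng.normal(0.0, constants.sigma_z, dataset.n)
        for _ in range(n_colliders)
    ]
    return replace(dataset, z=z)


def fit_ols(dataset: Dataset, covariate_subset: Sequence[int] = ()) -> EffectEstimate:
    """OLS of y on intercept + x (+ selected colliders); report the slope on x.

    p-value from the t distribution with residual degrees of freedom.
    ``covariate_subset`` holds 0-based indices into ``dataset.z``.
    """
    cols = [np.ones(dataset.n), dataset.x] + [dataset.z[j] for j in covariate_subset]
    X = np.column_stack(cols)
    df = dataset.n - X.shape[1]
    if df < 1:
        raise ValueError("insufficient observations for the requested model")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as err:  # pragma: no cover - degenerate input
        raise ValueError("rank-deficient design") from err
    coef = XtX_inv @ (X.T @ dataset.y)
    resid = dataset.y - X @ coef
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    es = float(coef[1])
    t_stat = es / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    model_id = "x" if not covariate_subset else "x+" + "".join(
        f"z{j + 1}" for j in covariate_subset
    )
    return EffectEstimate(es=es, se=se, p_two_sided=max(p, 5e-324), n=dataset.n,
                          df=df, model_id=model_id)


def sample_effect_table(
    beta: np.ndarray | float,
    n: np.ndarray | int,
    constants: SimConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
) -> EffectTable:
    """Draw OLS (slope, se) directly from their exact sampling distribution.

    Conditional on the realised predictor values, the bivariate OLS slope is
    Normal(beta, sigma_eps^2 / Sxx) with Sxx = sigma_x^2 * chi2(n-1), the
    residual variance is sigma_eps^2 * chi2(n-2)/(n-2) independent of the
    slope, and se^2 = s^2 / Sxx. Broadcasting beta against n gives one draw
    per element.
    """
    rng = np.random.default_rng() if rng is None else rng
    beta = np.asarray(beta, dtype=float)
    n = np.asarray(n)
    beta, n = np.broadcast_arrays(beta, n)
    sxx = constants.sigma_x**2 * rng.chisquare(n - 1)
    es = rng.normal(beta, constants.sigma_eps / np.sqrt(sxx))
    s2 = constants.sigma_eps**2 * rng.chisquare(n - 2) / (n - 2)
    se = np.sqrt(s2 / sxx)
    p = 2.0 * stats.t.sf(np.abs(es / se), n - 2)
    return EffectTable(es=es, se=se, p=np.maximum(p, 5e-324),
                       n=n.astype(np.int64), df=(n - 2).astype(np.int64))


def bivariate_ols_flat(
    x: np.ndarray, y: np.ndarray, n: np.ndarray, starts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised bivariate OLS over many studies stored back-to-back.

    ``x`` and ``y`` hold all studies' observations concatenated; study i
    occupies ``x[starts[i]:starts[i] + n[i]]``. Returns (es, se, p) per study.
    """
    sx = np.add.reduceat(x, starts)
    sy = np.add.reduceat(y, starts)
    sxx = np.add.reduceat(x * x, starts) - sx * sx / n
    sxy = np.add.reduceat(x * y, starts) - sx * sy / n
    syy = np.add.reduceat(y * y, starts) - sy * sy / n
    es = sxy / sxx
    rss = syy - es * sxy
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    p = 2.0 * stats.t.sf(np.abs(es / se), n - 2)
    return es, se, np.maximum(p, 5e-324)
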