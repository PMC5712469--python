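"""Publication-bias behaviour of simulated study authors.

Two procedures are modelled. Under the *file-drawer* an author whose first
analysis is non-significant or negative collects up to nine fresh datasets
(new sample size each time, same underlying effect) and publishes the first
significant positive slope; failed datasets stay in the drawer. Under
*p-hacking* the author keeps the dataset but re-specifies the model, adding
collider covariates (up to three, seven non-empty combinations) until the
slope of interest turns significant and positive. In both procedures, if no
attempt qualifies, the attempt closest to the one-sided significance goal is
published so that every study contributes exactly one estimate to the
meta-analysis.

The per-study functions build full datasets and are the reference
implementation. The ``batch_*`` engines produce whole meta-analytic samples
at once (file-drawer via the exact sampling-law route, p-hacking via
cross-moment OLS on fully generated data) and are checked against the
per-study path distributionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dgp import (
    BetaSpec,
    ConditionSpec,
    Dataset,
    EffectEstimate,
    EffectTable,
    SimConstants,
    DEFAULT_CONSTANTS,
    bivariate_ols_flat,
    draw_sample_size,
    fit_ols,
    make_colliders,
    sample_effect_table,
    simulate_dataset,
)

__all__ = [
    "PrimaryStudy",
    "SUBSET_ORDER",
    "needs_bias",
    "positive_one_sided_p",
    "run_file_drawer",
    "run_p_hacking",
    "simulate_primary_study",
    "batch_meta_sample_arrays",
]

# p-hacking model search order: subsets of the three colliders by increasing
# size, then lexicographically. The bivariate model is always attempt 0.
SUBSET_ORDER: tuple[tuple[int, ...], ...] = (
    (0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2),
)


@dataclass
class PrimaryStudy:
    """One simulated study: what was tried and what got published."""

    condition_id: str
    is_biaser: bool
    attempts: list[EffectEstimate]
    published_index: int
    committed: bool

    @property
    def first(self) -> EffectEstimate:
        return self.attempts[0]

    @property
    def published(self) -> EffectEstimate:
        return self.attempts[self.published_index]

    @property
    def successful(self) -> bool:
        """Did executed bias procedures deliver a significant positive result?"""
        return self.committed and self.published.es > 0 and self.published.p_two_sided < 0.05

    def successful_at(self, alpha: float) -> bool:
        return self.committed and self.published.es > 0 and self.published.p_two_sided < alpha


def needs_bias(estimate: EffectEstimate, alpha: float = 0.05) -> bool:
    """True when the result misses the author's goal: p >= alpha or a non-positive slope."""
    return estimate.p_two_sided >= alpha or estimate.es <= 0


def positive_one_sided_p(es: np.ndarray | float, p_two_sided: np.ndarray | float):
    """One-sided p-value for H1: beta > 0, used as 'distance to the goal'.

    p/2 for positive estimates, 1 - p/2 for negative ones; the fallback
    publication rule picks the attempt minimising this quantity.
    """
    es = np.asarray(es, dtype=float)
    p = np.asarray(p_two_sided, dtype=float)
    out = np.where(es > 0, p / 2.0, 1.0 - p / 2.0)
    return float(out) if out.ndim == 0 else out


def _qualifies(est: EffectEstimate, alpha: float) -> bool:
    return est.p_two_sided < alpha and est.es > 0


def _publish(attempts: list[EffectEstimate], alpha: float) -> int:
    """Index of the published attempt: earliest qualifying, else closest to goal."""
    for i, est in enumerate(attempts):
        if _qualifies(est, alpha):
            return i
    ps = [positive_one_sided_p(e.es, e.p_two_sided) for e in attempts]
    return int(np.argmin(ps))


def run_file_drawer(
    condition: ConditionSpec,
    constants: SimConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
    is_biaser: bool | None = None,
) -> PrimaryStudy:
    """Simulate one study under the file-drawer procedure (full-data path)."""
    if condition.form != "file_drawer":
        raise ValueError("condition form must be 'file_drawer'")
    rng = np.random.default_rng() if rng is None else rng
    if is_biaser is None:
        is_biaser = bool(rng.random() < condition.intent)
    n0 = draw_sample_size(condition.mu_n, constants, rng)
    data = simulate_dataset(condition.beta_spec, n0, constants, rng)
    beta = data.beta_true
    attempts = [fit_ols(data)]
    committed = is_biaser and needs_bias(attempts[0], constants.alpha)
    if committed:
        fixed_beta = BetaSpec.fixed(beta)
        for _ in range(constants.max_extra_samples):
            n_new = draw_sample_size(condition.mu_n, constants, rng)
            attempts.append(fit_ols(simulate_dataset(fixed_beta, n_new, constants, rng)))
            if _qualifies(attempts[-1], constants.alpha):
                break
    return PrimaryStudy(
        condition_id=condition.condition_id,
        is_biaser=is_biaser,
        attempts=attempts,
        published_index=_publish(attempts, constants.alpha),
        committed=committed,
    )


def run_p_hacking(
    condition: ConditionSpec,
    constants: SimConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
    is_biaser: bool | None = None,
) -> PrimaryStudy:
    """Simulate one study under the p-hacking procedure (full-data path)."""
    if condition.form != "p_hacking":
        raise ValueError("condition form must be 'p_hacking'")
    rng = np.random.default_rng() if rng is None else rng
    if is_biaser is None:
        is_biaser = bool(rng.random() < condition.intent)
    n = draw_sample_size(condition.mu_n, constants, rng)
    data = simulate_dataset(condition.beta_spec, n, constants, rng)
    attempts = [fit_ols(data)]
    committed = is_biaser and needs_bias(attempts[0], constants.alpha)
    if committed:
        data = make_colliders(data, constants, rng)
        for subset in SUBSET_ORDER:
            attempts.append(fit_ols(data, subset))
            if _qualifies(attempts[-1], constants.alpha):
                break
    return PrimaryStudy(
        condition_id=condition.condition_id,
        is_biaser=is_biaser,
        attempts=attempts,
        published_index=_publish(attempts, constants.alpha),
        committed=committed,
    )


def simulate_primary_study(
    condition: ConditionSpec,
    constants: SimConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
) -> PrimaryStudy:
    """Draw the author's intent, then run the condition's bias procedure."""
    rng = np.random.default_rng() if rng is None else rng
    if condition.form == "none":
        n = draw_sample_size(condition.mu_n, constants, rng)
        data = simulate_dataset(condition.beta_spec, n, constants, rng)
        attempts = [fit_ols(data)]
        return PrimaryStudy(condition.condition_id, False, attempts, 0, False)
    is_biaser = bool(rng.random() < condition.intent)
    if condition.form == "file_drawer":
        return run_file_drawer(condition, constants, rng, is_biaser)
    return run_p_hacking(condition, constants, rng, is_biaser)


# ---------------------------------------------------------------------------
# batch engines
# ---------------------------------------------------------------------------


def _batch_file_drawer(beta, n0, first, committed, mu_n, constants, rng):
    published = first.copy()
    idx = np.flatnonzero(committed)
    m = idx.size
    r = constants.max_extra_samples
    if m == 0 or r == 0:
        return published
    # Retries are independent datasets, so drawing all `r` up front and
    # selecting the earliest qualifying one is equivalent to stopping early.
    n_r = draw_sample_size(mu_n, constants, rng, size=(m, r))
    retries = sample_effect_table(beta[idx][:, None], n_r, constants, rng)
    qual = (retries.p < constants.alpha) & (retries.es > 0)
    any_q = qual.any(axis=1)
    first_q = np.argmax(qual, axis=1)

    posp = np.column_stack([
        np.atleast_1d(positive_one_sided_p(first.es[idx], first.p[idx])),
        positive_one_sided_p(retries.es, retries.p),
    ])
    chosen = np.where(any_q, first_q + 1, np.argmin(posp, axis=1))
    rows = np.arange(m)
    for f in ("es", "se", "p"):
        stacked = np.column_stack([getattr(first, f)[idx], getattr(retries, f)])
        getattr(published, f)[idx] = stacked[rows, chosen]
    for f in ("n", "df"):
        stacked = np.column_stack([getattr(first, f)[idx], getattr(retries, f)])
        getattr(published, f)[idx] = stacked[rows, chosen]
    return published


def _batch_p_hacking_data(beta, mu_n, constants, rng):
    """Generate every study's dataset flat and fit the bivariate model."""
    k = beta.size
    n = draw_sample_size(mu_n, constants, rng, size=k)
    starts = np.concatenate([[0], np.cumsum(n)[:-1]])
    total = int(n.sum())
    x = rng.normal(0.0, constants.sigma_x, total)
    y = np.repeat(beta, n) * x + rng.normal(0.0, constants.sigma_eps, total)
    es, se, p = bivariate_ols_flat(x, y, n, starts)
    first = EffectTable(es=es, se=se, p=p, n=n, df=n - 2)
    return first, x, y, n, starts


def _batch_p_hack_committed(x, y, n, starts, committed, constants, rng):
    """Exact OLS for the 7 collider models of every committed study.

    Works from per-study centred cross-moment matrices of (x, y, z1..z3);
    returns per-attempt (es, se, p, df) arrays of shape (m, 8) where column
    0 is the bivariate first attempt re-derived from the same moments.
    """
    obs_mask = np.repeat(committed, n)
    xc, yc = x[obs_mask], y[obs_mask]
    nc = n[committed]
    m = nc.size
    startsc = np.concatenate([[0], np.cumsum(nc)[:-1]])
    z = (constants.gamma * xc + constants.gamma_y * yc
         + rng.normal(0.0, constants.sigma_z, (3, xc.size)))
    V = np.vstack([xc, yc, z])  # variables: 0=x, 1=y, 2..4=z1..z3
    sums = np.add.reduceat(V, startsc, axis=1)
    means = sums / nc
    C = np.empty((5, 5, m))
    for a in range(5):
        for b in range(a, 5):
            pr = np.add.reduceat(V[a] * V[b], startsc)
            C[a, b] = C[b, a] = pr - nc * means[a] * means[b]

    n_att = 1 + len(SUBSET_ORDER)
    es = np.empty((m, n_att))
    se = np.empty((m, n_att))
    df = np.empty((m, n_att), dtype=np.int64)
    attempts_vars = [(0,)] + [(0,) + tuple(2 + j for j in s) for s in SUBSET_ORDER]
    for a_idx, pvars in enumerate(attempts_vars):
        P = list(pvars)
        A = C[np.ix_(P, P)].transpose(2, 0, 1)  # (m, p, p)
        b_vec = C[P, 1].T  # (m, p)
        coef = np.linalg.solve(A, b_vec[:, :, None])[:, :, 0]
        rss = C[1, 1] - np.einsum("ij,ij->i", coef, b_vec)
        dfi = nc - len(P) - 1
        sigma2 = rss / dfi
        inv00 = np.linalg.inv(A)[:, 0, 0]
        se[:, a_idx] = np.sqrt(sigma2 * inv00)
        es[:, a_idx] = coef[:, 0]
        df[:, a_idx] = dfi
    p = 2.0 * stats.t.sf(np.abs(es / se), df)
    return es, se, np.maximum(p, 5e-324), df, nc


def _batch_p_hacking(beta, intent, mu_n, constants, rng):
    first, x, y, n, starts = _batch_p_hacking_data(beta, mu_n, constants, rng)
    k = beta.size
    biaser = rng.random(k) < intent
    needs = (first.p >= constants.alpha) | (first.es <= 0)
    committed = biaser & needs
    published = first.copy()
    if committed.any():
        es_a, se_a, p_a, df_a, nc = _batch_p_hack_committed(
            x, y, n, starts, committed, constants, rng
        )
        qual = (p_a < constants.alpha) & (es_a > 0)
        # attempt 0 never qualifies for committed studies by construction
        any_q = qual[:, 1:].any(axis=1)
        first_q = np.argmax(qual[:, 1:], axis=1) + 1
        fallback = np.argmin(positive_one_sided_p(es_a, p_a), axis=1)
        chosen = np.where(any_q, first_q, fallback)
        rows = np.arange(nc.size)
        idx = np.flatnonzero(committed)
        published.es[idx] = es_a[rows, chosen]
        published.se[idx] = se_a[rows, chosen]
        published.p[idx] = p_a[rows, chosen]
        published.df[idx] = df_a[rows, chosen]
    return first, published, committed


def batch_meta_sample_arrays(
    condition: ConditionSpec,
    constants: SimConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
) -> tuple[EffectTable, EffectTable, np.ndarray, np.ndarray]:
    """Simulate the K studies of one meta-analysis, vectorised.

    Returns (firsts, published, committed, successful). ``firsts`` are the
    counterfactual first-attempt estimates of the same authors.
    """
    rng = np.random.default_rng() if rng is None else rng
    beta = np.atleast_1d(condition.beta_spec.draw(rng, condition.k)).astype(float)

    if condition.form == "p_hacking":
        first, published, committed = _batch_p_hacking(
            beta, condition.intent, condition.mu_n, constants, rng
        )
    else:
        n0 = draw_sample_size(condition.mu_n, constants, rng, size=condition.k)
        first = sample_effect_table(beta, n0, constants, rng)
        if condition.form == "none":
            committed = np.zeros(condition.k, dtype=bool)
            published = first
        else:
            biaser = rng.random(condition.k) < condition.intent
            needs = (first.p >= constants.alpha) | (first.es <= 0)
            committed = biaser & needs
            published = _batch_file_drawer(
                beta, n0, first, committed, condition.mu_n, constants, rng
            )
    successful = committed & (published.p < constants.alpha) & (published.es > 0)
    return first, published, committed, successful
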