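"""Design matrix, replication planning, grid execution and aggregation.

The full design crosses 5 effect-size specifications (beta = 0, 0.5, 1,
1.5, heterogeneous), 2 mean sample sizes (100, 500), 2 meta-analysis sizes
(K = 100, 1000) and 5 behavioural cells (no bias; 50% and 100% intent under
file-drawer and p-hacking) into 100 conditions. Each (condition, rep) run
assembles one meta-analysis, applies the seven bias tests (PU, FAT, TES and
four caliper widths) to the published estimates, and records significance
flags together with the run's heterogeneity and bias-prevalence summaries.
Rates (power / false-positive) and the summary regressions are computed
from the resulting run table.

Child RNG streams are keyed by (master seed, canonical condition index,
rep), so results are reproducible and independent of execution order or
condition filtering.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special

from .bias_tests import DEFAULT_TEST_NAMES, run_all_tests
from .dgp import BetaSpec, ConditionSpec, SimConstants, DEFAULT_CONSTANTS
from .meta import assemble_meta_sample, summarize_meta_sample

__all__ = [
    "build_design",
    "design_index",
    "required_replications",
    "run_grid",
    "rate_table",
    "summary_regressions",
    "DEFAULT_TEST_NAMES",
]

BETA_SPECS: tuple[BetaSpec, ...] = (
    BetaSpec.fixed(0.0),
    BetaSpec.fixed(0.5),
    BetaSpec.fixed(1.0),
    BetaSpec.fixed(1.5),
    BetaSpec.heterogeneous(),
)
MU_N_LEVELS = (100.0, 500.0)
K_LEVELS = (100, 1000)
BIAS_CELLS = (
    (0.0, "none"),
    (0.5, "file_drawer"),
    (0.5, "p_hacking"),
    (1.0, "file_drawer"),
    (1.0, "p_hacking"),
)


def build_design() -> list[ConditionSpec]:
    """The 100-cell design matrix in canonical order."""
    design = [
        ConditionSpec(beta_spec=b, mu_n=mu, k=k, intent=intent, form=form)
        for b in BETA_SPECS
        for mu in MU_N_LEVELS
        for k in K_LEVELS
        for intent, form in BIAS_CELLS
    ]
    return design


def design_index() -> dict[str, int]:
    return {c.condition_id: i for i, c in enumerate(build_design())}


def required_replications(
    p_ref: float, delta: float, power: float = 0.8, alpha: float = 0.05
) -> int:
    """Replications needed to detect a ``delta`` shift from proportion ``p_ref``.

    ceil((z_{1-alpha/2} + z_power)^2 * p_ref (1 - p_ref) / delta^2).
    """
    if not 0 < p_ref < 1:
        raise ValueError("p_ref must be in (0, 1)")
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must be in (0, 1)")
    z_a = float(-special.ndtri(alpha / 2.0))
    z_b = float(-special.ndtri(1.0 - power))
    return math.ceil((z_a + z_b) ** 2 * p_ref * (1.0 - p_ref) / delta**2)


def _reps_for(reps, condition: ConditionSpec) -> int:
    if isinstance(reps, Mapping):
        return int(reps[condition.condition_id])
    if callable(reps):
        return int(reps(condition))
    return int(reps)


def run_grid(
    design: Sequence[ConditionSpec] | None = None,
    reps: int | Mapping[str, int] | Callable[[ConditionSpec], int] = 10,
    master_seed: int = 0,
    constants: SimConstants = DEFAULT_CONSTANTS,
    caliper_dialect: str = "multiplicative",
    fat_alternative: str = "greater",
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Run every (condition, rep) cell and return the flat run table.

    One row per run; ``s_<TEST>`` is 1.0/0.0 where the test applied and NaN
    where it did not (e.g. an empty caliper), ``ap_<TEST>`` the applicability
    flag. Deterministic given ``master_seed`` and the canonical design.
    """
    if design is None:
        design = build_design()
    canon = design_index()
    records: list[dict] = []
    for cond in design:
        ci = canon.get(cond.condition_id)
        if ci is None:
            raise ValueError(f"condition {cond.condition_id} not in the canonical design")
        n_reps = _reps_for(reps, cond)
        if n_reps < 1:
            raise ValueError("reps must be >= 1")
        if progress is not None:
            progress(f"{cond.condition_id}: {n_reps} reps")
        for rep in range(n_reps):
            rng = np.random.default_rng([master_seed, ci, rep])
            sample = assemble_meta_sample(cond, constants, rng)
            summary = summarize_meta_sample(sample)
            results = run_all_tests(
                sample.published,
                alpha=constants.alpha,
                caliper_widths=constants.caliper_widths,
                caliper_dialect=caliper_dialect,
                fat_alternative=fat_alternative,
            )
            row = {
                "condition_id": cond.condition_id,
                "beta": cond.beta_spec.label,
                "mu_n": cond.mu_n,
                "k": cond.k,
                "intent": cond.intent,
                "form": cond.form,
                "rep": rep,
                "i2": summary.i2,
                "theta_fe": summary.theta_fe,
                "p_fe": summary.p_fe,
                "committed_share": summary.committed_share,
                "successful_share": summary.successful_share,
                "success_given_committed": summary.success_given_committed,
                "deflation": summary.deflation,
            }
            for name, res in results.items():
                row[f"s_{name}"] = float(res.significant) if res.applicable else float("nan")
                row[f"ap_{name}"] = res.applicable
            records.append(row)
    return pd.DataFrame.from_records(records)


def rate_table(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-condition, per-test rejection rates over applicable runs.

    ``kind`` is 'FPR' for no-bias conditions and 'power' otherwise; the
    95% interval is the normal-approximation binomial interval.
    """
    rows = []
    test_cols = [c[2:] for c in records.columns if c.startswith("s_")]
    for cond_id, grp in records.groupby("condition_id", sort=False):
        kind = "FPR" if float(grp["intent"].iloc[0]) == 0.0 else "power"
        for test in test_cols:
            s = grp[f"s_{test}"].dropna()
            r = len(s)
            if r == 0:
                rows.append({"condition_id": cond_id, "test": test, "rate": float("nan"),
                             "n_runs": 0, "kind": kind, "ci_low": float("nan"),
                             "ci_high": float("nan"), "estimable": False})
                continue
            rate = float(s.mean())
            half = 1.959964 * math.sqrt(max(rate * (1 - rate), 1e-12) / r)
            rows.append({"condition_id": cond_id, "test": test, "rate": rate,
                         "n_runs": r, "kind": kind,
                         "ci_low": max(0.0, rate - half),
                         "ci_high": min(1.0, rate + half), "estimable": True})
    return pd.DataFrame(rows)


def _fit_ols_table(y: pd.Series, X: pd.DataFrame, table: str, outcome: str) -> list[dict]:
    model = sm.OLS(
        y.to_numpy(dtype=float),
        sm.add_constant(X.to_numpy(dtype=float), has_constant="add"),
    )
    res = model.fit()
    terms = ["const"] + list(X.columns)
    return [
        {
            "table": table,
            "outcome": outcome,
            "term": term,
            "coef": float(res.params[i]),
            "se": float(res.bse[i]),
            "pvalue": float(res.pvalues[i]),
            "n": int(res.nobs),
            "r2": float(res.rsquared),
        }
        for i, term in enumerate(terms)
    ]


def _design_dummies(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    out["n500"] = (df["mu_n"] == 500).astype(float)
    for lab, col in (("0.5", "beta_0.5"), ("1", "beta_1.0"),
                     ("1.5", "beta_1.5"), ("het", "beta_het")):
        out[col] = (df["beta"] == lab).astype(float)
    out["p_hacking"] = (df["form"] == "p_hacking").astype(float)
    out["k1000"] = (df["k"] == 1000).astype(float)
    out["i2_10pp"] = df["i2"].to_numpy(dtype=float) / 10.0
    return out


def summary_regressions(records: pd.DataFrame) -> pd.DataFrame:
    """The prevalence, success, deflation, FPR and power regressions.

    Unit of analysis is one meta-analysis run. Committed and successful
    shares enter the deflation and power models centred at their realised
    means over all publication-bias runs, in 10-percentage-point units, so
    the constants are interpretable at average observed bias prevalence.
    Classical (non-robust) standard errors.
    """
    d = _design_dummies(records)
    bias = records["intent"] > 0
    rows: list[dict] = []

    for intent, table in ((0.5, "committed_intent50"), (1.0, "committed_intent100")):
        mask = records["intent"] == intent
        if mask.any():
            rows += _fit_ols_table(
                records.loc[mask, "committed_share"],
                d.loc[mask, ["n500", "beta_0.5", "beta_1.0", "beta_1.5", "beta_het"]],
                table, "committed_share",
            )

    mask = bias & records["success_given_committed"].notna()
    if mask.any():
        rows += _fit_ols_table(
            records.loc[mask, "success_given_committed"],
            d.loc[mask, ["n500", "beta_0.5", "beta_1.0", "beta_1.5", "beta_het",
                         "p_hacking"]],
            "success_given_committed", "success_given_committed",
        )

    if bias.any():
        com_mean = float(records.loc[bias, "committed_share"].mean())
        suc_mean = float(records.loc[bias, "successful_share"].mean())
        centred = pd.DataFrame(
            {
                "p_hacking": d.loc[bias, "p_hacking"],
                "committed_10pp": (records.loc[bias, "committed_share"] - com_mean) / 0.10,
                "successful_10pp": (records.loc[bias, "successful_share"] - suc_mean) / 0.10,
            }
        )
        rows += _fit_ols_table(records.loc[bias, "deflation"], centred,
                               "deflation", "deflation")

        test_cols = [c[2:] for c in records.columns if c.startswith("s_")]
        power_X = pd.concat(
            [d.loc[bias, ["k1000", "i2_10pp"]], centred], axis=1
        )
        for test in test_cols:
            m = bias & records[f"s_{test}"].notna()
            if not m.any():
                continue
            idx = records.index[m]
            rows += _fit_ols_table(
                records.loc[idx, f"s_{test}"], power_X.loc[idx],
                f"power_{test}", f"s_{test}",
            )

    no_bias = ~bias
    if no_bias.any():
        test_cols = [c[2:] for c in records.columns if c.startswith("s_")]
        for test in test_cols:
            m = no_bias & records[f"s_{test}"].notna()
            if not m.any():
                continue
            rows += _fit_ols_table(
                records.loc[m, f"s_{test}"],
                d.loc[m, ["k1000", "i2_10pp"]],
                f"fpr_{test}", f"s_{test}",
            )

    return pd.DataFrame(rows)
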