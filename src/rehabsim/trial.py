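"""Trial design and statistics for a two-arm rehabilitation study.

Covers the design machinery of a parallel-group controlled trial:
covariate-adaptive minimization assignment and its post hoc balance
enumeration, power / sample-size computation for the primary outcome,
cohort summaries, longitudinal slope regression with confidence intervals,
and a mixed-design ANOVA (between factor: group; within factor: session)
with Greenhouse–Geisser correction, simple-main-effects decomposition, and
an explicit missing-data policy (impute the subject mean, or drop the
subject when three or more sessions are missing).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "assign_minimization",
    "balance_percentile",
    "imbalance_score",
    "sample_size_two_sample",
    "power_one_sample",
    "cohort_summary",
    "session_slope",
    "impute_and_filter",
    "mixed_anova",
    "SlopeResult",
]

MINIMIZATION_COVARIATES = ("baseline_arat", "age")
GROUPS = ("AAN", "ST")


def _pooled_sd(values: np.ndarray) -> float:
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return sd


def imbalance_score(table: pd.DataFrame, covariates=MINIMIZATION_COVARIATES) -> float:
    """Sum over covariates of |group-mean difference| / pooled SD.

    Standardizing by the covariate's SD over all listed subjects makes age
    (years) and ARAT (points) commensurate.  Empty groups contribute the
    raw standardized mean of the other group.
    """
    score = 0.0
    for cov in covariates:
        vals = table[cov].to_numpy(dtype=float)
        sd = _pooled_sd(vals)
        if sd == 0:
            continue
        means = []
        for g in GROUPS:
            sub = table.loc[table["group"] == g, cov]
            means.append(float(sub.mean()) if len(sub) else 0.0)
        score += abs(means[0] - means[1]) / sd
    return score


def assign_minimization(
    table: pd.DataFrame,
    new_subject: dict,
    covariates=MINIMIZATION_COVARIATES,
    seed: int | None = None,
) -> str:
    """Assign a new subject to the group minimizing covariate imbalance.

    ``table`` holds already-assigned subjects (column ``group``);
    ``new_subject`` must supply every minimization covariate.  For each
    candidate group the post-assignment imbalance score is evaluated and the
    smaller one wins; exact ties (including the empty-trial start) are
    broken by a seeded coin flip.
    """
    for cov in covariates:
        if cov not in new_subject or pd.isna(new_subject[cov]):
            raise ValueError(f"new subject is missing covariate {cov!r}")
    rng = np.random.default_rng(seed)
    scores = {}
    for g in GROUPS:
        cand = pd.concat(
            [table, pd.DataFrame([{**new_subject, "group": g}])], ignore_index=True
        )
        scores[g] = imbalance_score(cand, covariates)
    if np.isclose(scores[GROUPS[0]], scores[GROUPS[1]]):
        return GROUPS[rng.integers(2)]
    return min(scores, key=scores.get)


def balance_percentile(
    table: pd.DataFrame,
    covariates=MINIMIZATION_COVARIATES,
    max_exhaustive: int = 22,
    n_sample: int = 100_000,
    seed: int | None = 0,
) -> float:
    """Fraction of balanced-size labelings strictly worse than the realized one.

    Enumerates every assignment of the enrolled subjects into two groups of
    (near-)equal size, scores each with :func:`imbalance_score`, and returns
    the proportion with strictly larger imbalance than the realized
    assignment.  Beyond ``max_exhaustive`` subjects a random sample of
    labelings is used instead (with a warning).
    """
    n = len(table)
    covs = np.column_stack([table[c].to_numpy(dtype=float) for c in covariates])
    sds = covs.std(axis=0, ddof=1)
    sds[sds == 0] = np.inf
    realized = imbalance_score(table, covariates)
    k = n // 2

    def score(mask: np.ndarray) -> float:
        a = covs[mask].mean(axis=0)
        b = covs[~mask].mean(axis=0)
        return float(np.sum(np.abs(a - b) / sds))

    if n <= max_exhaustive:
        combos = itertools.combinations(range(n), k)
    else:
        warnings.warn(
            f"{n} subjects: falling back to {n_sample} sampled labelings",
            stacklevel=2,
        )
        rng = np.random.default_rng(seed)
        combos = (tuple(rng.choice(n, size=k, replace=False)) for _ in range(n_sample))
    worse = total = 0
    for combo in combos:
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        total += 1
        if score(mask) > realized + 1e-12:
            worse += 1
    return worse / total


def sample_size_two_sample(
    delta: float,
    sd: float,
    power: float = 0.90,
    alpha: float = 0.05,
    loss_rate: float = 0.20,
) -> tuple[int, int]:
    """Per-group completers and total enrollment for a two-sample t-test.

    Normal-approximation formula ``n = ceil(2 ((z_{1-a/2} + z_{power}) sd /
    delta)^2)`` per group, inflated for attrition by ``(1 + loss_rate)``.
    Returns ``(n_per_group_completers, n_enrolled)``.
    """
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be > 0")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n_per_group = int(np.ceil(2 * ((z_a + z_b) * sd / delta) ** 2))
    n_enrolled = int(round(2 * n_per_group * (1 + loss_rate)))
    return n_per_group, n_enrolled


def power_one_sample(n: int, delta: float, sd: float, alpha: float = 0.05) -> dict:
    """Power of a two-sided one-sample t-test at effect ``delta``.

    Returns both the normal-approximation value and the exact noncentral-t
    value, labeled separately.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    ncp = delta * np.sqrt(n) / sd
    z_a = stats.norm.ppf(1 - alpha / 2)
    normal = stats.norm.cdf(ncp - z_a) + stats.norm.cdf(-ncp - z_a)
    df = n - 1
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    exact = stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    if not np.isfinite(exact):  # noncentral-t overflows at extreme df*ncp
        exact = normal
    return {"normal": float(normal), "exact": float(exact)}


def cohort_summary(
    table: pd.DataFrame, completers_only: bool = True, n_screened: int | None = None
) -> dict:
    """Cohort descriptives at the precision conventionally reported.

    Mean age uses age-range midpoints when only ranges were recorded.
    Dropout % is relative to the enrolled cohort; enrollment % (if
    ``n_screened`` given) relative to everyone screened.
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")
    enrolled = len(table)
    dropouts = int(table["dropout"].sum())
    sub = table.loc[~table["dropout"].astype(bool)] if completers_only else table
    if "age" in sub.columns:
        age = sub["age"]
    else:
        age = (sub["age_lo"] + sub["age_hi"]) / 2.0
    out = {
        "n": len(sub),
        "mean_age": round(float(age.mean()), 1),
        "mean_time_since_injury": round(float(sub["time_since_injury"].mean())),
        "mean_baseline_arat": round(float(sub["baseline_arat"].mean())),
        "dropout_pct": round(100.0 * dropouts / enrolled),
    }
    if n_screened is not None:
        out["enrollment_pct"] = round(100.0 * enrolled / n_screened)
    return out


@dataclass(frozen=True)
class SlopeResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    significant: bool
    zero_residual: bool


def session_slope(deltas, sessions=None, conf: float = 0.95) -> SlopeResult:
    """OLS slope of per-session group-averaged changes, with a t-based CI.

    ``significant`` means the confidence interval excludes zero.  Exactly
    collinear data yield a degenerate zero-width CI, flagged via
    ``zero_residual``.
    """
    y = np.asarray(deltas, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 sessions")
    x = np.arange(1, y.size + 1, dtype=float) if sessions is None else np.asarray(sessions, float)
    res = stats.linregress(x, y)
    dof = y.size - 2
    resid = y - (res.intercept + res.slope * x)
    zero_resid = bool(np.allclose(resid, 0.0, atol=1e-12))
    half = 0.0 if zero_resid else stats.t.ppf(0.5 + conf / 2, dof) * res.stderr
    lo, hi = res.slope - half, res.slope + half
    return SlopeResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0 or hi < 0),
        zero_residual=zero_resid,
    )


def impute_and_filter(
    matrix: pd.DataFrame, max_missing: int = 3, value_col: str = "value"
) -> tuple[pd.DataFrame, dict]:
    """Apply the missing-data policy to a long-format longitudinal matrix.

    ``matrix`` columns: subject, group, session, and ``value_col`` (NaN =
    missing); optional dof/metric columns partition the analysis.  Within
    each partition, a subject missing ``max_missing`` or more sessions is
    excluded; remaining missing cells are replaced by that subject's mean
    over observed sessions.  Returns the completed matrix and a report with
    ``n_replaced`` and ``excluded`` subject lists.
    """
    group_cols = [c for c in ("dof", "metric") if c in matrix.columns]
    out = []
    excluded = []
    n_replaced = 0
    for _, part in matrix.groupby(group_cols) if group_cols else [((), matrix)]:
        for subj, sub in part.groupby("subject"):
            missing = int(sub[value_col].isna().sum())
            if missing >= max_missing or missing == len(sub):
                if missing == len(sub) and missing < max_missing:
                    warnings.warn(f"subject {subj}: all sessions missing; removed", stacklevel=2)
                excluded.append(subj)
                continue
            sub = sub.copy()
            if missing:
                sub[value_col] = sub[value_col].fillna(sub[value_col].mean())
                n_replaced += missing
            out.append(sub)
    completed = pd.concat(out, ignore_index=True) if out else matrix.iloc[0:0]
    return completed, {"n_replaced": n_replaced, "excluded": excluded}


def mixed_anova(
    matrix: pd.DataFrame,
    value_col: str = "value",
    alpha: float = 0.05,
    sphericity_alpha: float = 0.05,
) -> dict:
    """Mixed-design ANOVA: between = group, within = session.

    Greenhouse–Geisser correction is applied when Mauchly's test rejects
    sphericity at ``sphericity_alpha``.  On a significant group x session
    interaction, one-way repeated-measures ANOVAs per group (simple main
    effects) are added.  Requires a balanced, complete matrix (run
    :func:`impute_and_filter` first).  Returns a dict with the effects
    table, epsilon, sphericity flag, and any simple main effects.
    """
    for g in matrix["group"].unique():
        if matrix.loc[matrix["group"] == g, "subject"].nunique() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    aov = pg.mixed_anova(
        data=matrix, dv=value_col, within="session", between="group",
        subject="subject", correction=True, effsize="np2",
    )
    sess_row = aov.loc[aov["Source"] == "session"].iloc[0]
    n_levels = matrix["session"].nunique()
    if n_levels > 2 and not pd.isna(sess_row.get("p_spher", np.nan)):
        sphericity_ok = bool(sess_row["p_spher"] >= sphericity_alpha)
        eps = float(sess_row["eps"])
    else:
        sphericity_ok, eps = True, 1.0
    use_gg = not sphericity_ok
    table = []
    for _, row in aov.iterrows():
        p = row["p_unc"]
        if use_gg and row["Source"] != "group" and not pd.isna(row.get("p_GG_corr", np.nan)):
            p = row["p_GG_corr"]
        table.append(
            {
                "effect": row["Source"].lower(),
                "F": float(row["F"]),
                "df1": float(row["DF1"]),
                "df2": float(row["DF2"]),
                "p": float(p),
                "gg_applied": bool(use_gg and row["Source"] != "group"),
            }
        )
    result = {
        "effects": pd.DataFrame(table),
        "epsilon": eps,
        "sphericity": sphericity_ok,
        "simple_main_effects": None,
    }
    inter = next(r for r in table if r["effect"] == "interaction")
    if inter["p"] < alpha:
        sme = {}
        for g, sub in matrix.groupby("group"):
            rm = pg.rm_anova(
                data=sub, dv=value_col, within="session", subject="subject", correction=use_gg
            )
            sme[g] = rm
        result["simple_main_effects"] = sme
    return result
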