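"""Propensity-score full matching.

The propensity score is the modelled probability of MT (exposed) group
membership given the confounders (age, pubertal status, gender, SES, IQ,
ethnicity).  *Full matching* partitions the whole cohort into subclasses
that each contain at least one participant from each group; as in any
optimal full match, every subclass is a star — one treated with k controls
or k treated with one control — and its cost is the sum of |score
distances| from the members to the singleton.  Minimising total cost over
all such partitions is equivalent to a minimum-cost edge cover of the
treated/control bipartite graph (a minimal edge cover is exactly a star
forest), and on a one-dimensional score an optimal cover is non-crossing,
so the solver here is an exact O(n_t * n_c) dynamic programme over the two
sorted score lists rather than a network-flow code.  Distances may be
taken on the probability scale (default) or the logit scale.

Matching weights: treated participants get weight 1; each control in a
subclass with a treated and b controls gets (a / b) x (N_control /
N_treated), so each group's weights sum to its size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import MatchingError
from .resampling import ContingencyResult, bootstrap_chi_square

DEFAULT_COVARIATES = ("age", "pubertal", "gender", "ses", "iq", "ethnicity")
CATEGORICAL = {"gender", "ethnicity"}


@dataclass
class MatchSpec:
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    method: str = "full"
    distance_scale: str = "probability"  # or "logit"


@dataclass
class MatchResult:
    """Per-participant propensity scores, subclass ids and weights
    (aligned with the cohort rows used for matching)."""

    propensity: np.ndarray
    subclass: np.ndarray
    weight: np.ndarray
    total_distance: float
    balance: pd.DataFrame | None = field(default=None)


def _design_matrix(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=cohort.index)
    X["intercept"] = 1.0
    for cov in covariates:
        if cov not in cohort.columns:
            raise MatchingError(f"covariate {cov!r} not in cohort")
        col = cohort[cov]
        if cov in CATEGORICAL or col.dtype == object:
            levels = sorted(pd.Series(col).dropna().unique())
            mode = col.mode().iloc[0]
            filled = col.fillna(mode)
            if col.isna().any():
                warnings.warn(f"covariate {cov!r}: missing values mode-imputed")
            for lev in levels[1:]:  # first level is the reference
                X[f"{cov}={lev}"] = (filled == lev).astype(float)
        else:
            x = pd.to_numeric(col, errors="coerce").astype(float)
            if x.isna().any():
                warnings.warn(f"covariate {cov!r}: missing values mean-imputed")
                x = x.fillna(x.mean())
            X[cov] = x
    return X


def estimate_propensity(cohort: pd.DataFrame, spec: MatchSpec | None = None) -> np.ndarray:
    """Logistic model of MT membership on the matching covariates."""
    spec = spec or MatchSpec()
    X = _design_matrix(cohort, spec.covariates)
    y = (cohort["group"] == "MT").astype(float).to_numpy()
    if y.min() == y.max():
        raise MatchingError("cohort contains only one group")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial()).fit()
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
        raise MatchingError(
            "propensity model separated; reduce or coarsen the covariate set"
        ) from exc
    p = np.asarray(fit.fittedvalues)
    return np.clip(p, 1e-12, 1 - 1e-12)


def full_match(scores, groups, *, distance_scale: str = "probability") -> MatchResult:
    """Exact optimal full matching of scalar scores by dynamic programming.

    ``groups`` marks treated (MT) participants either as booleans or as
    "MT"/"NMT" labels.  The recurrence covers prefixes of the two sorted
    score lists: covering (i, j) always ends with the edge (t_i, c_j),
    whose predecessor state may leave either endpoint already covered,

        dp[i, j] = |t_i - c_j| + min(dp[i-1, j-1], dp[i-1, j], dp[i, j-1]).

    Returns subclass ids, matching weights and the minimised total
    distance; raises :class:`MatchingError` when either group is empty.
    """
    p = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    treated = g == "MT" if g.dtype.kind in "UOS" else g.astype(bool)
    n = len(p)
    n_t, n_c = int(treated.sum()), int((~treated).sum())
    if n_t == 0 or n_c == 0:
        raise MatchingError("full matching needs at least one participant per group")

    x = np.log(p / (1 - p)) if distance_scale == "logit" else p
    t_idx = np.flatnonzero(treated)[np.argsort(x[treated], kind="stable")]
    c_idx = np.flatnonzero(~treated)[np.argsort(x[~treated], kind="stable")]
    a, b = x[t_idx], x[c_idx]

    dp = np.full((n_t + 1, n_c + 1), np.inf)
    dp[0, 0] = 0.0
    for i in range(1, n_t + 1):
        for j in range(1, n_c + 1):
            d = abs(a[i - 1] - b[j - 1])
            dp[i, j] = d + min(dp[i - 1, j - 1], dp[i - 1, j], dp[i, j - 1])

    # backtrack the optimal monotone edge cover
    edges = []
    i, j = n_t, n_c
    while i > 0 or j > 0:
        edges.append((i - 1, j - 1))
        prev = min(dp[i - 1, j - 1], dp[i - 1, j], dp[i, j - 1])
        if dp[i - 1, j - 1] == prev:
            i, j = i - 1, j - 1
        elif dp[i - 1, j] == prev:
            i = i - 1
        else:
            j = j - 1

    # drop edges with both endpoints already covered elsewhere (cost can only
    # fall); the remaining cover is a star forest: the subclasses
    deg_t = np.zeros(n_t, dtype=int)
    deg_c = np.zeros(n_c, dtype=int)
    for ti, cj in edges:
        deg_t[ti] += 1
        deg_c[cj] += 1
    kept = []
    for ti, cj in edges:
        if deg_t[ti] > 1 and deg_c[cj] > 1:
            deg_t[ti] -= 1
            deg_c[cj] -= 1
        else:
            kept.append((ti, cj))
    total = float(sum(abs(a[ti] - b[cj]) for ti, cj in kept))

    # connected components of the star forest -> subclass ids
    parent = list(range(n_t + n_c))

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for ti, cj in kept:
        ru, rv = find(ti), find(n_t + cj)
        if ru != rv:
            parent[ru] = rv

    subclass = np.empty(n, dtype=int)
    roots: dict[int, int] = {}
    for k, orig in enumerate(list(t_idx) + list(c_idx)):
        r = find(k)
        subclass[orig] = roots.setdefault(r, len(roots))

    weight = np.ones(n)
    for sid in np.unique(subclass):
        mask = subclass == sid
        a = int((treated & mask).sum())
        b = int((~treated & mask).sum())
        weight[mask & ~treated] = (a / b) * (n_c / n_t)
    return MatchResult(propensity=p, subclass=subclass, weight=weight,
                       total_distance=total)


def balance_table(cohort: pd.DataFrame, result: MatchResult,
                  covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Standardized mean differences before and after weighting.

    Numeric covariates: (weighted MT mean - weighted NMT mean) divided by
    the *unweighted* pooled SD, so before/after share a denominator.
    Categorical covariates: per-level difference in (weighted) proportions.
    """
    treated = (cohort["group"] == "MT").to_numpy()
    w = result.weight
    rows = []

    def wmean(x, mask, weights):
        return float(np.average(x[mask], weights=weights[mask]))

    for cov in covariates:
        col = cohort[cov]
        if cov in CATEGORICAL or col.dtype == object:
            for lev in sorted(pd.Series(col).dropna().unique()):
                x = (col == lev).astype(float).to_numpy()
                before = x[treated].mean() - x[~treated].mean()
                after = wmean(x, treated, w) - wmean(x, ~treated, w)
                rows.append({"covariate": f"{cov}={lev}", "statistic": "prop_diff",
                             "before": before, "after": after})
        else:
            x = pd.to_numeric(col, errors="coerce").astype(float).to_numpy()
            s_t = np.nanstd(x[treated], ddof=1)
            s_c = np.nanstd(x[~treated], ddof=1)
            pooled = np.sqrt((s_t ** 2 + s_c ** 2) / 2.0)
            diff_before = np.nanmean(x[treated]) - np.nanmean(x[~treated])
            diff_after = wmean(x, treated, w) - wmean(x, ~treated, w)
            if pooled == 0:
                smd_b = 0.0 if diff_before == 0 else np.nan
                smd_a = 0.0 if diff_after == 0 else np.nan
            else:
                smd_b, smd_a = diff_before / pooled, diff_after / pooled
            rows.append({"covariate": cov, "statistic": "smd",
                         "before": smd_b, "after": smd_a})
    return pd.DataFrame(rows)


def weighted_chi_square(groups, categories, weights, n_reps: int = 5000,
                        n_sims: int = 5000, seed=0, *, row_order=None,
                        col_order=None) -> ContingencyResult:
    """Post-matching association test on the weighted contingency table.

    Weighted counts play the role of effective counts in the Pearson
    statistic; the bootstrap resamples participants carrying their weights;
    the Monte-Carlo p simulates with the rounded weighted margins.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    return bootstrap_chi_square(groups, categories, n_reps=n_reps, n_sims=n_sims,
                                seed=seed, row_order=row_order, col_order=col_order,
                                weights=w)
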