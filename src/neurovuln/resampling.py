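"""Resampling-based inference: bootstrapped logistic regression and
bootstrapped / Monte-Carlo chi-square tests.

The logistic fit is maximum likelihood via iteratively reweighted least
squares (IRLS).  Bootstrap inference is case resampling: whole participant
records are drawn with replacement, the model is refit per replicate, and
bias, SE and a 95% percentile interval are reported per coefficient — the
reporting style (B, bias, SE, percentile CI, OR) of standard statistical
bootstrap output.  Replicates that fail (separation, or a resampled column
that has collapsed to a constant) are dropped and counted rather than
silently included, because small-sample logistic bootstraps routinely
produce separation and including the diverged fits corrupts the SE.

The contingency-table p-value is simulated under independence with both
margins fixed, drawing tables by a sequential-cell multivariate
hypergeometric construction (uniform over tables with the observed
margins) and using the (1 + k) / (1 + n_sims) estimator so the reported
p can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateTableError, InferenceInstabilityError

MAX_ITER = 100
TOL = 1e-8
#: a coefficient this large in |.| is treated as a diverged (separated) fit
DIVERGENCE_BOUND = 1e2


@dataclass
class LogisticFit:
    """Coefficients of one maximum-likelihood logistic fit."""

    coef: np.ndarray
    converged: bool
    separated: bool
    n_iter: int
    n_obs: int

    @property
    def ok(self) -> bool:
        return self.converged and not self.separated


@dataclass
class BootstrapEstimate:
    """Case-resampling bootstrap summary for one coefficient.

    ``bias`` is the mean of the bootstrap replicates minus the original
    estimate; ``ci_low``/``ci_high`` are the 2.5th/97.5th percentiles of the
    replicate distribution; ``significant`` means that interval excludes 0.
    """

    name: str
    b: float
    bias: float
    se: float
    ci_low: float
    ci_high: float
    or_: float
    n_reps: int
    significant: bool


def _as_design(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), [str(c) for c in design.columns]
    X = np.asarray(design, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def fit_logistic(outcome, design) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    ``design`` must already contain an intercept column.  Rows with any
    missing value are dropped before fitting.  Convergence is declared when
    the largest absolute coefficient change falls below 1e-8, within 100
    iterations.  Complete separation does not raise: the fit is returned as
    of the iteration cap with ``separated=True`` so that bootstrap callers
    can apply their exclusion policy.
    """
    X, _ = _as_design(design)
    y = np.asarray(outcome, dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]
    n, p = X.shape
    if n == 0:
        return LogisticFit(np.full(p, np.nan), False, True, 0, 0)

    beta = np.zeros(p)
    converged = False
    singular = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError:
            singular = True
            break
        if not np.all(np.isfinite(beta_new)):
            singular = True
            break
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < TOL:
            converged = True
            break

    separated = (
        singular
        or not converged
        or bool(np.max(np.abs(beta)) > DIVERGENCE_BOUND)
        or len(np.unique(y)) < 2
    )
    return LogisticFit(beta, converged, separated, it, n)


def _degenerate_resample(y: np.ndarray, X: np.ndarray, orig_constant: np.ndarray) -> bool:
    """A replicate whose outcome, or a predictor that varied in the original
    design (i.e. not the intercept), has collapsed to a constant."""
    if len(np.unique(y)) < 2:
        return True
    collapsed = np.ptp(X, axis=0) == 0
    return bool(np.any(collapsed & ~orig_constant))


def bootstrap_logistic(
    outcome,
    design,
    n_reps: int = 5000,
    seed: int | np.random.Generator = 0,
    *,
    strata=None,
    max_failure_fraction: float = 0.5,
) -> list[BootstrapEstimate]:
    """Case-resampling bootstrap of a logistic regression.

    Each replicate draws n rows with replacement (within ``strata`` if
    given) and refits.  Replicates with separation or a collapsed column
    are excluded and counted; if more than ``max_failure_fraction`` of the
    requested replicates fail, an :class:`InferenceInstabilityError` is
    raised rather than reporting numbers from the surviving minority.
    """
    X, names = _as_design(design)
    y = np.asarray(outcome, dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]
    n = len(y)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    base = fit_logistic(y, X)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    orig_constant = np.ptp(X, axis=0) == 0

    if strata is not None:
        strata = np.asarray(strata)[keep]
        groups = [np.flatnonzero(strata == g) for g in np.unique(strata)]

    reps = []
    for _ in range(n_reps):
        if strata is None:
            idx = rng.integers(0, n, n)
        else:
            idx = np.concatenate([g[rng.integers(0, len(g), len(g))] for g in groups])
        yb, Xb = y[idx], X[idx]
        if _degenerate_resample(yb, Xb, orig_constant):
            continue
        fit = fit_logistic(yb, Xb)
        if fit.separated:
            continue
        reps.append(fit.coef)

    n_ok = len(reps)
    if n_ok < n_reps * (1.0 - max_failure_fraction):
        raise InferenceInstabilityError(
            f"{n_reps - n_ok}/{n_reps} bootstrap replicates failed (separation or collapse)"
        )
    B = np.asarray(reps)
    lo, hi = np.percentile(B, [2.5, 97.5], axis=0)
    out = []
    for j, name in enumerate(names):
        b = float(base.coef[j])
        out.append(
            BootstrapEstimate(
                name=name,
                b=b,
                bias=float(B[:, j].mean() - b),
                se=float(B[:, j].std(ddof=1)),
                ci_low=float(lo[j]),
                ci_high=float(hi[j]),
                or_=float(np.exp(b)),
                n_reps=n_ok,
                significant=bool(lo[j] > 0 or hi[j] < 0),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Contingency tables


def chi_square(observed) -> float:
    """Pearson chi-square, no continuity correction.

    Expected counts are the outer product of the margins over the total.
    An empty row or column margin raises :class:`DegenerateTableError`.
    """
    O = np.asarray(observed, dtype=float)
    if O.ndim != 2:
        raise ValueError("observed must be a 2-D table")
    if np.any(O < 0):
        raise ValueError("counts must be non-negative")
    rows = O.sum(axis=1)
    cols = O.sum(axis=0)
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise DegenerateTableError("table has an empty row or column margin")
    E = np.outer(rows, cols) / O.sum()
    return float(((O - E) ** 2 / E).sum())


def _chi_square_batch(tables: np.ndarray) -> np.ndarray:
    # tables: (k, r, c) with common margins; vectorised Pearson statistic
    O = tables.astype(float)
    rows = O.sum(axis=2, keepdims=True)
    cols = O.sum(axis=1, keepdims=True)
    total = O.sum(axis=(1, 2), keepdims=True)
    E = rows * cols / total
    return ((O - E) ** 2 / E).sum(axis=(1, 2))


def simulate_tables(
    observed, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw tables uniformly... precisely: multivariate-hypergeometrically
    with both margins fixed at the observed table's margins.

    Rows are filled sequentially; each row is a multivariate hypergeometric
    draw from the column counts still unallocated.
    """
    O = np.asarray(observed, dtype=int)
    r, c = O.shape
    row_sums = O.sum(axis=1)
    col_sums = O.sum(axis=0)
    out = np.empty((n_sims, r, c), dtype=np.int64)
    if r == 2:
        out[:, 0, :] = rng.multivariate_hypergeometric(col_sums, int(row_sums[0]), size=n_sims)
        out[:, 1, :] = col_sums - out[:, 0, :]
        return out
    for k in range(n_sims):
        remaining = col_sums.copy()
        for i in range(r - 1):
            row = rng.multivariate_hypergeometric(remaining, int(row_sums[i]))
            out[k, i] = row
            remaining -= row
        out[k, r - 1] = remaining
    return out


def mc_pvalue(observed, n_sims: int = 5000, seed: int | np.random.Generator = 0) -> float:
    """Monte-Carlo p-value for independence with both margins fixed.

    p = (1 + #{simulated chi-square >= observed}) / (n_sims + 1).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    obs = chi_square(observed)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sims = _chi_square_batch(simulate_tables(observed, n_sims, rng))
    k = int(np.sum(sims >= obs - 1e-12))
    return (1 + k) / (n_sims + 1)


@dataclass
class ContingencyResult:
    """Observed table with its bootstrap and Monte-Carlo inference."""

    observed: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    chi2: float
    mc_p: float
    n_sims: int
    boot_bias: float
    boot_se: float
    boot_ci_low: float
    boot_ci_high: float
    n_reps: int
    n_failed_reps: int


def crosstab(groups, categories, row_order=None, col_order=None, weights=None) -> tuple[np.ndarray, list, list]:
    """Participant-level labels -> (weighted) r x c count table."""
    g = pd.Series(np.asarray(groups))
    c = pd.Series(np.asarray(categories))
    rows = list(row_order) if row_order is not None else sorted(g.unique())
    cols = list(col_order) if col_order is not None else sorted(c.unique())
    w = np.ones(len(g)) if weights is None else np.asarray(weights, dtype=float)
    table = np.zeros((len(rows), len(cols)))
    for i, r in enumerate(rows):
        for j, cc in enumerate(cols):
            table[i, j] = w[(g == r).to_numpy() & (c == cc).to_numpy()].sum()
    return table, rows, cols


def bootstrap_chi_square(
    groups,
    categories,
    n_reps: int = 5000,
    n_sims: int = 5000,
    seed: int | np.random.Generator = 0,
    *,
    row_order=None,
    col_order=None,
    weights=None,
) -> ContingencyResult:
    """Case-resampling bootstrap of the Pearson chi-square.

    Participants (group, category[, weight]) are resampled with replacement;
    the statistic is recomputed per replicate, giving bias, SE and a 95%
    percentile interval.  The p-value comes from :func:`mc_pvalue` on the
    observed table (weighted tables are rounded for margin simulation).
    Replicates whose table loses a margin are skipped and counted.
    """
    g = np.asarray(groups)
    c = np.asarray(categories)
    w = None if weights is None else np.asarray(weights, dtype=float)
    observed, rows, cols = crosstab(g, c, row_order, col_order, w)
    obs_chi2 = chi_square(observed)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = len(g)
    reps = []
    n_failed = 0
    gi = pd.Categorical(g, categories=rows).codes
    ci = pd.Categorical(c, categories=cols).codes
    r, k = len(rows), len(cols)
    vals = np.ones(n) if w is None else w
    for _ in range(n_reps):
        idx = rng.integers(0, n, n)
        table = np.zeros((r, k))
        np.add.at(table, (gi[idx], ci[idx]), vals[idx])
        if np.any(table.sum(axis=1) <= 0) or np.any(table.sum(axis=0) <= 0):
            n_failed += 1
            continue
        reps.append(chi_square(table))

    reps = np.asarray(reps)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    mc_table = np.rint(observed).astype(int) if w is not None else observed
    return ContingencyResult(
        observed=observed,
        row_labels=[str(x) for x in rows],
        col_labels=[str(x) for x in cols],
        chi2=obs_chi2,
        mc_p=mc_pvalue(mc_table, n_sims, rng),
        n_sims=n_sims,
        boot_bias=float(reps.mean() - obs_chi2),
        boot_se=float(reps.std(ddof=1)),
        boot_ci_low=float(lo),
        boot_ci_high=float(hi),
        n_reps=len(reps),
        n_failed_reps=n_failed,
    )
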