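"""Screening diagnostics for the high-vulnerability category.

The longitudinal outcome is a binary *symptom increase* flag (follow-up SDQ
strictly above baseline).  Treating the high-vulnerability category as a
positive screen, the module reports sensitivity, specificity and positive
predictive value with exact (Clopper–Pearson) binomial intervals, and the
per-category increase probabilities — raw, or model-adjusted at the
subgroup's mean baseline SDQ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import vulnerability_index as vi
from .errors import ValidationError
from .resampling import fit_logistic

SDQ_MAX = 40


def symptom_increase(sdq_baseline, sdq_followup):
    """1 if follow-up SDQ strictly exceeds baseline, 0 if stable or lower,
    missing (None) if either score is missing.  Scores must lie in [0, 40]."""
    def is_missing(v):
        return v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v))

    if is_missing(sdq_baseline) or is_missing(sdq_followup):
        return None
    b, f = float(sdq_baseline), float(sdq_followup)
    for name, v in (("sdq_baseline", b), ("sdq_followup", f)):
        if not 0 <= v <= SDQ_MAX:
            raise ValidationError(f"{name}={v} outside [0, {SDQ_MAX}]")
    return 1 if f > b else 0


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial interval via the beta-quantile characterisation.

    Lower bound is 0 when k == 0 and upper bound is 1 when k == n, by
    definition of the exact interval.
    """
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class Proportion:
    """A ratio with its exact 95% interval; undefined when the denominator is 0."""

    numerator: int
    denominator: int
    value: float | None
    ci_low: float | None
    ci_high: float | None
    defined: bool

    @classmethod
    def of(cls, k: int, n: int) -> "Proportion":
        if n == 0:
            return cls(k, 0, None, None, None, False)
        lo, hi = clopper_pearson(k, n)
        return cls(k, n, k / n, lo, hi, True)


@dataclass
class OutcomeTable:
    """Counts of (vulnerability category x increase / stable-or-decrease)."""

    counts: dict[str, dict[str, int]]  # category -> {"increase": k, "stable": m}
    subgroup: str = "all"

    @classmethod
    def from_data(cls, categories, outcomes, subgroup: str = "all") -> "OutcomeTable":
        counts = {c: {"increase": 0, "stable": 0} for c in vi.CATEGORIES}
        for cat, out in zip(categories, outcomes):
            if cat not in counts or out is None:
                continue
            counts[cat]["increase" if out == 1 else "stable"] += 1
        return cls(counts=counts, subgroup=subgroup)

    def category_n(self, category: str) -> int:
        c = self.counts.get(category, {})
        return c.get("increase", 0) + c.get("stable", 0)

    @property
    def total_increase(self) -> int:
        return sum(c["increase"] for c in self.counts.values())

    @property
    def total_stable(self) -> int:
        return sum(c["stable"] for c in self.counts.values())


@dataclass
class ScreeningMetrics:
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion


def screening_metrics(table: OutcomeTable, positive_category: str = vi.HIGH) -> ScreeningMetrics:
    """Sensitivity, specificity and PPV of the positive (high) category.

    * sensitivity — of all who increased, the fraction flagged high;
    * specificity — of all stable/decreasing, the fraction flagged low or medium;
    * PPV — of all flagged high, the fraction who increased.

    A zero denominator leaves the metric flagged undefined, not an error.
    """
    high_inc = table.counts.get(positive_category, {}).get("increase", 0)
    n_inc = table.total_increase
    n_stable = table.total_stable
    stable_not_high = n_stable - table.counts.get(positive_category, {}).get("stable", 0)
    n_high = table.category_n(positive_category)
    return ScreeningMetrics(
        sensitivity=Proportion.of(high_inc, n_inc),
        specificity=Proportion.of(stable_not_high, n_stable),
        ppv=Proportion.of(high_inc, n_high),
    )


def category_increase_probabilities(
    table: OutcomeTable,
    *,
    adjust: pd.DataFrame | None = None,
) -> dict[str, dict]:
    """Per-category probability of symptom increase with exact intervals.

    Unadjusted mode (``adjust=None``): raw proportions per category with
    Clopper–Pearson intervals; empty categories are omitted.

    Adjusted mode: ``adjust`` is a participant-level frame with columns
    ``category``, ``increase`` and ``sdq_baseline``; a logistic model of
    increase on category dummies (reference: low) plus baseline SDQ is fit,
    and each category's predicted probability is evaluated at the
    subgroup's mean baseline SDQ.  The exact intervals still come from the
    raw per-category counts.
    """
    out: dict[str, dict] = {}
    raw = {}
    for cat in vi.CATEGORIES:
        n = table.category_n(cat)
        if n == 0:
            continue
        raw[cat] = Proportion.of(table.counts[cat]["increase"], n)

    if adjust is None:
        for cat, p in raw.items():
            out[cat] = {"probability": p.value, "ci_low": p.ci_low, "ci_high": p.ci_high,
                        "n": p.denominator, "mode": "raw"}
        return out

    df = adjust.dropna(subset=["increase", "sdq_baseline"])
    df = df[df["category"].isin(vi.CATEGORIES)]
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "medium": (df["category"] == vi.MEDIUM).astype(float),
            "high": (df["category"] == vi.HIGH).astype(float),
            "sdq_baseline": df["sdq_baseline"].astype(float),
        }
    )
    fit = fit_logistic(df["increase"].astype(float), X)
    mean_sdq = float(df["sdq_baseline"].astype(float).mean())
    for cat, p in raw.items():
        x = np.array([1.0, cat == vi.MEDIUM, cat == vi.HIGH, mean_sdq], dtype=float)
        prob = float(1.0 / (1.0 + np.exp(-x @ fit.coef)))
        out[cat] = {"probability": prob, "ci_low": p.ci_low, "ci_high": p.ci_high,
                    "n": p.denominator, "mode": "adjusted_at_mean_baseline"}
    return out
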