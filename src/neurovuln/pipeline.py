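"""End-to-end study pipeline.

Stage order mirrors the study design: build the vulnerability index on the
full baseline sample, test its association with exposure group
(bootstrapped / Monte-Carlo chi-square), restrict to the follow-up
subsample, derive the binary symptom-increase outcome, fit the bootstrapped
logistic model within each exposure group (category dummies with *low* as
the reference, plus baseline SDQ), compute screening diagnostics within the
exposed group, and optionally re-test after propensity-score full matching
and re-fit after excluding participants with unusually high baseline
symptoms.

The longitudinal stages reuse the *baseline-sample* task means/SDs for
standardization: the index is built once, at baseline, and carried forward.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import matching as psm
from . import resampling as rs
from . import screening as scr
from . import synthetic_cohort as sc
from . import vulnerability_index as vi
from .errors import NeurovulnError


@dataclass
class StudyConfig:
    cohort: sc.CohortConfig = field(default_factory=sc.default_config)
    cohort_path: str | None = None  # load instead of simulate, if given
    rules: dict[str, str] | None = None  # defaults to cohort config rules
    n_reps: int = 5000
    n_sims: int = 5000
    seed: int = 0
    do_matching: bool = True
    sensitivity_exclude_baseline_ge: int | None = 20


@dataclass
class RunReport:
    config: dict
    version: str
    seed: int
    index_distribution: dict
    group_association: dict
    logistic: dict  # per subgroup
    screening: dict
    matching: dict | None
    sensitivity: dict | None
    exclusions: list[dict]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True,
                          default=_jsonable)


def _jsonable(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


class PipelineError(NeurovulnError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except NeurovulnError as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def _estimates_dict(estimates: list[rs.BootstrapEstimate]) -> list[dict]:
    return [dataclasses.asdict(e) for e in estimates]


def _contingency_dict(res: rs.ContingencyResult) -> dict:
    d = dataclasses.asdict(res)
    d["observed"] = np.asarray(res.observed).tolist()
    return d


def vulnerability_design(df: pd.DataFrame) -> pd.DataFrame:
    """Model matrix for the symptom-change regression: intercept, medium
    and high dummies (low is the reference category), baseline SDQ."""
    return pd.DataFrame(
        {
            "intercept": 1.0,
            "medium": (df["category"] == vi.MEDIUM).astype(float),
            "high": (df["category"] == vi.HIGH).astype(float),
            "sdq_baseline": df["sdq_baseline"].astype(float),
        },
        index=df.index,
    )


@_stage("logistic")
def _fit_subgroup(df: pd.DataFrame, n_reps: int, seed) -> dict:
    usable = df[(df["category"].isin(vi.CATEGORIES)) & df["increase"].notna()
                & df["sdq_baseline"].notna()]
    if usable["increase"].nunique() < 2 or len(usable) < 10:
        return {"n": int(len(usable)), "estimates": None,
                "note": "outcome constant or subgroup too small"}
    ests = rs.bootstrap_logistic(
        usable["increase"].astype(float).to_numpy(),
        vulnerability_design(usable),
        n_reps=n_reps,
        seed=seed,
    )
    return {"n": int(len(usable)), "estimates": _estimates_dict(ests)}


def run_study(config: StudyConfig) -> RunReport:
    """Execute the full analysis and return a serialisable report."""
    rng = np.random.default_rng(config.seed)
    exclusions: list[dict] = []

    # --- cohort ---
    if config.cohort_path is not None:
        cohort = sc.read_cohort(config.cohort_path)
    else:
        cohort = sc.generate_cohort(config.cohort, seed=config.cohort.seed)
    rules = config.rules or config.cohort.rules

    # --- index on the full baseline sample ---
    try:
        profiles = vi.build_index(cohort, rules)
        task_cols = [c for c in cohort.columns if c.startswith("task_")]
        means, sds = vi.task_scale(cohort[task_cols].rename(
            columns=lambda c: c[len("task_"):]))
    except NeurovulnError as exc:
        raise PipelineError(f"stage 'index': {exc}") from exc
    df = cohort.merge(profiles[["participant_id", "category"]], on="participant_id")
    for pid in df.loc[df["category"] == vi.EXCLUDED, "participant_id"]:
        exclusions.append({"participant_id": pid, "stage": "index",
                           "reason": "fewer than 2 available task metrics"})

    scored = df[df["category"] != vi.EXCLUDED]
    dist = (
        scored.groupby(["group", "category"]).size()
        .unstack(fill_value=0)
        .reindex(index=["NMT", "MT"], columns=list(vi.CATEGORIES), fill_value=0)
    )

    # --- group x category association ---
    try:
        assoc = rs.bootstrap_chi_square(
            scored["group"], scored["category"],
            n_reps=config.n_reps, n_sims=config.n_sims,
            seed=rng, row_order=["NMT", "MT"], col_order=list(vi.CATEGORIES),
        )
    except NeurovulnError as exc:
        raise PipelineError(f"stage 'association': {exc}") from exc

    # --- longitudinal subsample ---
    longitudinal = df.copy()
    longitudinal["increase"] = [
        scr.symptom_increase(b, f)
        for b, f in zip(longitudinal["sdq_baseline"], longitudinal["sdq_followup"])
    ]
    for pid in longitudinal.loc[longitudinal["increase"].isna(), "participant_id"]:
        exclusions.append({"participant_id": pid, "stage": "follow-up",
                           "reason": "missing baseline or follow-up SDQ"})
    followed = longitudinal[longitudinal["increase"].notna()]

    logistic = {
        grp: _fit_subgroup(followed[followed["group"] == grp],
                           config.n_reps, rng)
        for grp in ("MT", "NMT")
    }

    # --- screening within MT ---
    mt = followed[(followed["group"] == "MT") & followed["category"].isin(vi.CATEGORIES)]
    table = scr.OutcomeTable.from_data(mt["category"], mt["increase"], subgroup="MT")
    metrics = scr.screening_metrics(table)
    screening = {
        "outcome_table": table.counts,
        "metrics": {k: dataclasses.asdict(getattr(metrics, k))
                    for k in ("sensitivity", "specificity", "ppv")},
        "category_probabilities": scr.category_increase_probabilities(
            table, adjust=mt[["category", "increase", "sdq_baseline"]]
        ),
    }

    # --- optional propensity-score matching branch ---
    matching = None
    if config.do_matching:
        try:
            spec = psm.MatchSpec()
            scores = psm.estimate_propensity(df, spec)
            result = psm.full_match(scores, df["group"].to_numpy())
            result.balance = psm.balance_table(df, result)
            matched = df.assign(weight=result.weight)
            matched = matched[matched["category"] != vi.EXCLUDED]
            retest = psm.weighted_chi_square(
                matched["group"], matched["category"], matched["weight"],
                n_reps=config.n_reps, n_sims=config.n_sims, seed=rng,
                row_order=["NMT", "MT"], col_order=list(vi.CATEGORIES),
            )
            matching = {
                "n_subclasses": int(len(np.unique(result.subclass))),
                "total_distance": result.total_distance,
                "balance": result.balance.to_dict(orient="records"),
                "weighted_association": _contingency_dict(retest),
            }
        except NeurovulnError as exc:
            raise PipelineError(f"stage 'matching': {exc}") from exc

    # --- optional sensitivity analysis: drop high-baseline participants ---
    sensitivity = None
    thr = config.sensitivity_exclude_baseline_ge
    if thr is not None:
        kept = followed[followed["sdq_baseline"] < thr]
        n_dropped = int((followed["sdq_baseline"] >= thr).sum())
        sensitivity = {
            "threshold": thr,
            "n_excluded": n_dropped,
            "logistic": {"MT": _fit_subgroup(kept[kept["group"] == "MT"],
                                             config.n_reps, rng)},
        }

    cfg = dataclasses.asdict(config)
    cfg["cohort"] = dataclasses.asdict(config.cohort)
    return RunReport(
        config=cfg,
        version=__version__,
        seed=config.seed,
        index_distribution={
            "counts": dist.to_dict(orient="index"),
            "task_means": means,
            "task_sds": sds,
        },
        group_association=_contingency_dict(assoc),
        logistic=logistic,
        screening=screening,
        matching=matching,
        sensitivity=sensitivity,
        exclusions=exclusions,
    )
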