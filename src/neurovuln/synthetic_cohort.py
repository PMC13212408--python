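"""Synthetic cohort generator.

Emulates the statistical structure of a two-group (maltreatment-exposed MT
vs non-exposed NMT) child cohort: demographics with group shifts in IQ,
socio-economic status and baseline symptoms; five continuous task metrics
with per-group means; missing task data and partial follow-up; and a
follow-up symptom score wired so that the probability of a symptom
*increase* depends on the participant's own computed vulnerability category
(per exposure group).  Because the outcome is generated conditionally on the
category the index module actually assigns, parameter-recovery experiments
on the downstream inference are mechanically honest.

All randomness flows from one integer seed; each variable draws from a
sub-stream derived deterministically from the seed and the variable's name,
so regenerating a cohort with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import vulnerability_index as vi
from .errors import ConfigError

MT, NMT = "MT", "NMT"
GROUPS = (MT, NMT)

#: the five task metrics, named after the neurocognitive domain each probes
TASKS = ("dot_probe", "trust", "emotion", "reward_learning", "effort")

SDQ_MAX = 40
SES_MAX = 5


@dataclass(frozen=True)
class Normal:
    """Mean/SD pair for a continuous variable."""

    mean: float
    sd: float


@dataclass
class CohortConfig:
    """Full parameterisation of a synthetic cohort.

    ``demographics`` maps group -> variable -> :class:`Normal` for age,
    pubertal status, IQ, SES and baseline SDQ (the latter two rounded and
    clamped to their ordinal ranges).  ``gender_p_female`` and
    ``ethnicity_p_caucasian`` are per-group category probabilities.
    ``task_params`` maps task -> group -> :class:`Normal`.
    ``outcome_params`` maps group -> vulnerability category -> probability
    that the follow-up SDQ exceeds baseline; the ``excluded`` category
    falls back to the group's ``low`` probability when not given.
    """

    n_mt: int = 85
    n_nmt: int = 90
    demographics: dict[str, dict[str, Normal]] = field(default_factory=dict)
    gender_p_female: dict[str, float] = field(default_factory=dict)
    ethnicity_p_caucasian: dict[str, float] = field(default_factory=dict)
    task_params: dict[str, dict[str, Normal]] = field(default_factory=dict)
    rules: dict[str, str] = field(default_factory=dict)
    task_missingness: dict[str, float] = field(default_factory=dict)
    followup_missingness: dict[str, float] = field(default_factory=dict)
    outcome_params: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_mt < 0:
            raise ConfigError("n_mt must be >= 0")
        if self.n_nmt < 0:
            raise ConfigError("n_nmt must be >= 0")
        for group, params in self.demographics.items():
            for var, nm in params.items():
                if nm.sd <= 0:
                    raise ConfigError(f"demographics[{group}][{var}].sd must be > 0")
        for name, probs in (
            ("gender_p_female", self.gender_p_female),
            ("ethnicity_p_caucasian", self.ethnicity_p_caucasian),
            ("followup_missingness", self.followup_missingness),
        ):
            for group, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{group}] must be in [0, 1]")
        for task, p in self.task_missingness.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"task_missingness[{task}] must be in [0, 1]")
        for task, per_group in self.task_params.items():
            for group, nm in per_group.items():
                if nm.sd <= 0:
                    raise ConfigError(f"task_params[{task}][{group}].sd must be > 0")
        for group, per_cat in self.outcome_params.items():
            for cat, p in per_cat.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"outcome_params[{group}][{cat}] must be in [0, 1]")


def default_config(seed: int = 0) -> CohortConfig:
    """The study-like default cohort: 85 MT / 90 NMT.

    Demographic means/SDs follow the published group summaries (age 12.8 vs
    12.9, IQ 98.5 vs 104.4, SES 3.3 vs 2.9, baseline SDQ 12.4 vs 7.3, shared
    pubertal 2.4).  Task metrics are unit normals with MT shifted 0.45 SD in
    each task's atypical direction; with one-tailed directionality rules and
    10% task missingness this yields a predominantly-low category
    distribution with a visible MT excess in medium/high.  The symptom
    increase probability is high (0.9) only in the MT high-vulnerability
    cell; MT low/medium sit at 0.35/0.45 and NMT is flat at 0.40.
    """
    demographics = {
        MT: {
            "age": Normal(12.8, 2.4),
            "pubertal": Normal(2.4, 0.8),
            "iq": Normal(98.5, 11.4),
            "ses": Normal(3.3, 1.0),
            "sdq_baseline": Normal(12.4, 6.4),
        },
        NMT: {
            "age": Normal(12.9, 2.1),
            "pubertal": Normal(2.4, 0.8),
            "iq": Normal(104.4, 11.0),
            "ses": Normal(2.9, 1.0),
            "sdq_baseline": Normal(7.3, 5.6),
        },
    }
    rules = {
        "dot_probe": vi.HIGH_TAIL,        # stronger threat bias = atypical
        "trust": vi.LOW_TAIL,             # lower trust attribution = atypical
        "emotion": vi.HIGH_TAIL,          # heightened intensity perception = atypical
        "reward_learning": vi.LOW_TAIL,   # poorer volatility adjustment = atypical
        "effort": vi.LOW_TAIL,            # blunted reward sensitivity = atypical
    }
    shift = 0.45
    task_params = {}
    for task, rule in rules.items():
        delta = shift if rule == vi.HIGH_TAIL else -shift
        task_params[task] = {MT: Normal(delta, 1.0), NMT: Normal(0.0, 1.0)}
    return CohortConfig(
        n_mt=85,
        n_nmt=90,
        demographics=demographics,
        gender_p_female={MT: 0.482, NMT: 0.522},
        ethnicity_p_caucasian={MT: 0.388, NMT: 0.444},
        task_params=task_params,
        rules=rules,
        task_missingness={task: 0.10 for task in TASKS},
        followup_missingness={MT: 1 - 57 / 85, NMT: 1 - 47 / 90},
        outcome_params={
            MT: {vi.LOW: 0.35, vi.MEDIUM: 0.45, vi.HIGH: 0.90},
            NMT: {vi.LOW: 0.40, vi.MEDIUM: 0.40, vi.HIGH: 0.40},
        },
        seed=seed,
    )


def _stream(seed: int, tag: str) -> np.random.Generator:
    # deterministic per-variable sub-stream: seed + stable hash of the tag
    key = [np.uint32(seed & 0x7FFFFFFF)] + [np.uint32(b) for b in tag.encode()]
    return np.random.default_rng(np.random.SeedSequence(key))


def _round_clamp(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    return np.clip(np.rint(x), lo, hi).astype(int)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort table; identical ``(config, seed)`` gives identical output.

    The follow-up SDQ is produced in two steps: first a Bernoulli draw of
    *increase vs not* at the probability configured for the participant's
    (group, computed vulnerability category) cell, then an integer score
    consistent with that draw (baseline plus/minus a Poisson jump, clamped
    to the 0–40 scale).
    """
    config.validate()
    if seed is None:
        seed = config.seed

    n = config.n_mt + config.n_nmt
    group = np.array([MT] * config.n_mt + [NMT] * config.n_nmt)
    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:04d}" for i in range(n)],
            "group": group,
        }
    )
    is_mt = group == MT

    def per_group_normal(var: str, round_to: tuple[int, int] | None = None,
                         clip: tuple[float, float] | None = None) -> np.ndarray:
        rng = _stream(seed, var)
        out = np.empty(n)
        for g in GROUPS:
            mask = group == g
            nm = config.demographics[g][var]
            out[mask] = rng.normal(nm.mean, nm.sd, mask.sum())
        if clip is not None:
            out = np.clip(out, *clip)
        if round_to is not None:
            out = _round_clamp(out, *round_to)
        return out

    cohort["age"] = per_group_normal("age", clip=(5.0, 18.0))
    cohort["pubertal"] = per_group_normal("pubertal", clip=(1.0, 4.0))
    cohort["iq"] = per_group_normal("iq")
    cohort["ses"] = per_group_normal("ses", round_to=(0, SES_MAX))
    cohort["sdq_baseline"] = per_group_normal("sdq_baseline", round_to=(0, SDQ_MAX))

    rng_gender = _stream(seed, "gender")
    p_f = np.where(is_mt, config.gender_p_female[MT], config.gender_p_female[NMT])
    cohort["gender"] = np.where(rng_gender.random(n) < p_f, "F", "M")
    rng_eth = _stream(seed, "ethnicity")
    p_c = np.where(is_mt, config.ethnicity_p_caucasian[MT], config.ethnicity_p_caucasian[NMT])
    cohort["ethnicity"] = np.where(rng_eth.random(n) < p_c, "caucasian", "other")

    for task in config.task_params:
        rng = _stream(seed, f"task_{task}")
        vals = np.empty(n)
        for g in GROUPS:
            mask = group == g
            nm = config.task_params[task][g]
            vals[mask] = rng.normal(nm.mean, nm.sd, mask.sum())
        miss = rng.random(n) < config.task_missingness.get(task, 0.0)
        vals[miss] = np.nan
        cohort[f"task_{task}"] = vals

    # outcome wired to the category the index module itself assigns
    profiles = vi.build_index(cohort, config.rules)
    category = profiles["category"].to_numpy()

    rng_fu = _stream(seed, "followup")
    p_miss_fu = np.array([config.followup_missingness.get(g, 0.0) for g in group])
    has_followup = rng_fu.random(n) >= p_miss_fu

    rng_out = _stream(seed, "outcome")
    p_inc = np.empty(n)
    for i, (g, cat) in enumerate(zip(group, category)):
        per_cat = config.outcome_params.get(g, {})
        p_inc[i] = per_cat.get(cat, per_cat.get(vi.LOW, 0.0))
    increase = rng_out.random(n) < p_inc
    jump = rng_out.poisson(2.5, n)

    baseline = cohort["sdq_baseline"].to_numpy()
    followup = np.where(increase, baseline + 1 + jump, baseline - jump)
    followup = np.clip(followup, 0, SDQ_MAX)
    # a baseline already at the ceiling cannot increase; record it as stable
    followup = np.where(increase & (baseline >= SDQ_MAX), baseline, followup)
    cohort["sdq_followup"] = pd.array(
        np.where(has_followup, followup, -1), dtype="Int64"
    )
    cohort.loc[~has_followup, "sdq_followup"] = pd.NA
    return cohort


# ---------------------------------------------------------------------------
# I/O: cohort CSV and YAML config

COHORT_COLUMNS = [
    "participant_id", "group", "age", "gender", "ethnicity", "ses",
    "pubertal", "iq", "sdq_baseline", "sdq_followup",
] + [f"task_{t}" for t in TASKS]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the canonical cohort CSV (missing values as empty fields)."""
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cols += [c for c in cohort.columns if c not in cols]
    cohort[cols].to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-built)."""
    df = pd.read_csv(path, dtype={"participant_id": str, "group": str})
    for col in ("ses", "sdq_baseline", "sdq_followup"):
        if col in df.columns:
            df[col] = pd.array(df[col], dtype="Int64")
    return df


def config_to_yaml(config: CohortConfig, path) -> None:
    def encode(obj):
        if isinstance(obj, Normal):
            return {"mean": obj.mean, "sd": obj.sd}
        if dataclasses.is_dataclass(obj):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(encode(config), fh, sort_keys=False)


def config_from_yaml(path) -> CohortConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    def normals(d: Mapping) -> dict:
        return {
            k: Normal(**v) if isinstance(v, Mapping) and set(v) == {"mean", "sd"} else normals(v)
            for k, v in d.items()
        }

    for key in ("demographics", "task_params"):
        if key in raw:
            raw[key] = normals(raw[key])
    return CohortConfig(**raw)
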