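"""Propensity estimation, optimal full matching, balance, weighted re-test."""

import numpy as np
import pandas as pd
import pytest

from neurovuln import matching as psm
from neurovuln import resampling as rs
from neurovuln import synthetic_cohort as sc
from neurovuln.errors import MatchingError

# --- oracles -------------------------------------------------------------


def _partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in _partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub


def _star_cost(block, x, t):
    tr = [x[i] for i in block if t[i]]
    co = [x[i] for i in block if not t[i]]
    if not tr or not co:
        return None
    if len(tr) == 1:
        return sum(abs(c - tr[0]) for c in co)
    if len(co) == 1:
        return sum(abs(v - co[0]) for v in tr)
    return None  # not a star subclass


def brute_force_full_match(x, t):
    """Exhaustive minimum over all partitions into valid star subclasses."""
    best = np.inf
    for part in _partitions(list(range(len(x)))):
        total = 0.0
        for block in part:
            c = _star_cost(block, x, t)
            if c is None:
                break
            total += c
        else:
            best = min(best, total)
    return best


def greedy_full_match_cost(x, t):
    """Nearest-neighbour full matching: pair each treated greedily, then
    attach leftover units to their nearest opposite-group partner."""
    treated = [i for i in range(len(x)) if t[i]]
    controls = [i for i in range(len(x)) if not t[i]]
    cost = 0.0
    free_c = set(controls)
    anchor_of_c = {}
    for ti in sorted(treated, key=lambda i: x[i]):
        if free_c:
            cj = min(free_c, key=lambda j: abs(x[j] - x[ti]))
            free_c.discard(cj)
            anchor_of_c[cj] = ti
            cost += abs(x[cj] - x[ti])
        else:
            cj = min(controls, key=lambda j: abs(x[j] - x[ti]))
            cost += abs(x[cj] - x[ti])
    for cj in free_c:
        ti = min(treated, key=lambda i: abs(x[cj] - x[i]))
        cost += abs(x[cj] - x[ti])
    return cost


def _random_instance(rng):
    while True:
        n = int(rng.integers(2, 9))
        t = rng.random(n) < 0.5
        if t.any() and not t.all():
            return rng.random(n), t


# --- tests ---------------------------------------------------------------


class TestEstimatePropensity:
    def test_identical_distributions_concentrate_at_base_rate(self):
        cfg = sc.default_config(seed=1)
        cfg.n_mt, cfg.n_nmt = 850, 900
        cfg.demographics["MT"] = dict(cfg.demographics["NMT"])
        cfg.gender_p_female["MT"] = cfg.gender_p_female["NMT"]
        cfg.ethnicity_p_caucasian["MT"] = cfg.ethnicity_p_caucasian["NMT"]
        cohort = sc.generate_cohort(cfg)
        scores = psm.estimate_propensity(cohort)
        base = 850 / 1750
        assert abs(scores.mean() - base) < 0.01
        assert scores.std() < 0.05

    def test_iq_gap_raises_mt_scores(self, default_cohort):
        _, cohort = default_cohort
        scores = psm.estimate_propensity(cohort)
        mt = scores[(cohort["group"] == "MT").to_numpy()]
        nmt = scores[(cohort["group"] == "NMT").to_numpy()]
        assert mt.mean() > nmt.mean()
        assert np.all((scores > 0) & (scores < 1))

    def test_single_group_rejected(self, default_cohort):
        _, cohort = default_cohort
        with pytest.raises(MatchingError):
            psm.estimate_propensity(cohort[cohort["group"] == "MT"])

    def test_separating_covariate_raises_advice(self, default_cohort):
        _, cohort = default_cohort
        boosted = cohort.copy()
        boosted["iq"] = np.where(boosted["group"] == "MT", 80.0, 120.0)
        with pytest.raises(MatchingError, match="covariate"):
            psm.estimate_propensity(boosted, psm.MatchSpec(covariates=("iq",)))


class TestFullMatch:
    def test_singleton_pair(self):
        res = psm.full_match([0.5, 0.5], ["MT", "NMT"])
        assert res.total_distance == 0.0
        assert res.subclass[0] == res.subclass[1]

    def test_documented_small_instance(self):
        # the middle control joins the nearer treated participant
        scores = [0.2, 0.8, 0.21, 0.79, 0.5]
        groups = ["MT", "MT", "NMT", "NMT", "NMT"]
        res = psm.full_match(scores, groups)
        brute = brute_force_full_match(scores, [g == "MT" for g in groups])
        assert res.total_distance == pytest.approx(brute, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            x, t = _random_instance(rng)
            res = psm.full_match(x, t)
            assert res.total_distance == pytest.approx(
                brute_force_full_match(list(x), list(t)), abs=1e-9
            )

    def test_dominates_greedy_matching(self):
        rng = np.random.default_rng(31)
        for _ in range(300):
            n = int(rng.integers(4, 31))
            t = np.zeros(n, dtype=bool)
            t[rng.choice(n, max(1, n // 3), replace=False)] = True
            x = rng.random(n)
            res = psm.full_match(x, t)
            assert res.total_distance <= greedy_full_match_cost(x, t) + 1e-12

    def test_subclass_validity_and_weight_conservation(self):
        rng = np.random.default_rng(40)
        for _ in range(50):
            x, t = _random_instance(rng)
            res = psm.full_match(x, t)
            for sid in np.unique(res.subclass):
                m = res.subclass == sid
                assert t[m].any() and (~t)[m].any()
            assert res.weight[t].sum() == pytest.approx(t.sum())
            assert res.weight[~t].sum() == pytest.approx((~t).sum())
            assert (res.weight > 0).all()

    def test_empty_group_rejected(self):
        with pytest.raises(MatchingError):
            psm.full_match([0.2, 0.4], ["MT", "MT"])


class TestBalanceTable:
    def test_identical_groups_have_zero_smd(self):
        cohort = pd.DataFrame(
            {
                "group": ["MT"] * 10 + ["NMT"] * 10,
                "age": [12.0 + i for i in range(10)] * 2,
                "iq": [100.0 + i for i in range(10)] * 2,
                "gender": ["F", "M"] * 5 + ["F", "M"] * 5,
            }
        )
        res = psm.MatchResult(
            propensity=np.full(20, 0.5), subclass=np.repeat(np.arange(10), 2),
            weight=np.ones(20), total_distance=0.0,
        )
        bal = psm.balance_table(cohort, res, covariates=("age", "iq", "gender"))
        assert np.allclose(bal["before"], 0.0)
        assert np.allclose(bal["after"], 0.0)

    def test_unit_weights_match_unweighted_oracle(self, default_cohort):
        _, cohort = default_cohort
        res = psm.MatchResult(
            propensity=np.full(len(cohort), 0.5),
            subclass=np.zeros(len(cohort), dtype=int),
            weight=np.ones(len(cohort)),
            total_distance=0.0,
        )
        bal = psm.balance_table(cohort, res, covariates=("iq",))
        mt = cohort[cohort["group"] == "MT"]["iq"]
        nmt = cohort[cohort["group"] == "NMT"]["iq"]
        pooled = np.sqrt((mt.std(ddof=1) ** 2 + nmt.std(ddof=1) ** 2) / 2)
        want = (mt.mean() - nmt.mean()) / pooled
        row = bal[bal["covariate"] == "iq"].iloc[0]
        assert row["before"] == pytest.approx(want, abs=1e-10)
        assert row["after"] == pytest.approx(want, abs=1e-10)

    def test_matching_improves_iq_balance_on_average(self):
        befores, afters = [], []
        for seed in range(25):
            cfg = sc.default_config(seed=100 + seed)
            cohort = sc.generate_cohort(cfg)
            scores = psm.estimate_propensity(cohort)
            res = psm.full_match(scores, cohort["group"].to_numpy())
            bal = psm.balance_table(cohort, res, covariates=("iq",))
            befores.append(abs(bal.iloc[0]["before"]))
            afters.append(abs(bal.iloc[0]["after"]))
        assert np.mean(afters) < np.mean(befores)


class TestWeightedChiSquare:
    def test_unit_weights_reduce_to_unweighted(self, table2_participants):
        g, c = table2_participants
        w = np.ones(len(g))
        a = psm.weighted_chi_square(g, c, w, n_reps=150, n_sims=150, seed=9)
        b = rs.bootstrap_chi_square(g, c, n_reps=150, n_sims=150, seed=9, weights=w)
        assert a.chi2 == b.chi2
        assert a.boot_se == b.boot_se and a.mc_p == b.mc_p

    def test_doubling_weights_doubles_statistic(self, table2_participants):
        g, c = table2_participants
        w = np.ones(len(g))
        a = psm.weighted_chi_square(g, c, w, n_reps=50, n_sims=50, seed=2)
        b = psm.weighted_chi_square(g, c, 2 * w, n_reps=50, n_sims=50, seed=2)
        assert b.chi2 == pytest.approx(2 * a.chi2, rel=1e-12)

    def test_nonpositive_weights_rejected(self, table2_participants):
        g, c = table2_participants
        with pytest.raises(ValueError):
            psm.weighted_chi_square(g, c, np.zeros(len(g)), n_reps=10, n_sims=10)

    def test_type_i_error_near_nominal_under_independence(self):
        rng = np.random.default_rng(55)
        rejections = 0
        runs = 200
        for _ in range(runs):
            g = np.where(rng.random(120) < 0.5, "MT", "NMT")
            c = rng.choice(["low", "medium", "high"], 120, p=[0.5, 0.35, 0.15])
            p = rs.mc_pvalue(rs.crosstab(g, c)[0], n_sims=400, seed=rng)
            rejections += p <= 0.05
        assert 0.01 <= rejections / runs <= 0.09
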