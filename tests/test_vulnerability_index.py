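"""Vulnerability-index construction: standardization, flags, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurovuln import vulnerability_index as vi
from neurovuln.errors import DegenerateScaleError


class TestStandardize:
    def test_symmetric_three_point_case(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0]})
        z = vi.standardize(df)
        np.testing.assert_allclose(z["t"], [-1.0, 0.0, 1.0])

    def test_zero_variance_raises_naming_task(self):
        df = pd.DataFrame({"flat_task": [2.0, 2.0, 2.0]})
        with pytest.raises(DegenerateScaleError, match="flat_task"):
            vi.standardize(df)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(3.0, 2.0, 20)
        x[4] = np.nan
        df = pd.DataFrame({"t": x})
        z = vi.standardize(df)
        obs = [v for v in x if not np.isnan(v)]
        mean = sum(obs) / len(obs)
        sd = (sum((v - mean) ** 2 for v in obs) / (len(obs) - 1)) ** 0.5
        for i, v in enumerate(x):
            if np.isnan(v):
                assert np.isnan(z["t"].iloc[i])
            else:
                assert abs(z["t"].iloc[i] - (v - mean) / sd) < 1e-12

    def test_missing_in_missing_out(self):
        df = pd.DataFrame({"t": [1.0, np.nan, 3.0]})
        assert np.isnan(vi.standardize(df)["t"].iloc[1])

    def test_precomputed_scale_reused(self):
        df = pd.DataFrame({"t": [10.0, 20.0]})
        z = vi.standardize(df, means={"t": 0.0}, sds={"t": 10.0})
        np.testing.assert_allclose(z["t"], [1.0, 2.0])


class TestClassifyTask:
    @pytest.mark.parametrize(
        "z,rule,expected",
        [
            (0.0, vi.BOTH_TAILS, vi.NORMATIVE),
            (1.0, vi.BOTH_TAILS, vi.NORMATIVE),  # boundary is inclusive
            (-1.0, vi.BOTH_TAILS, vi.NORMATIVE),
            (1.01, vi.BOTH_TAILS, vi.ATYPICAL),
            (-1.2, vi.HIGH_TAIL, vi.NORMATIVE),
            (-1.2, vi.LOW_TAIL, vi.ATYPICAL),
            (1.2, vi.LOW_TAIL, vi.NORMATIVE),
            (1.2, vi.HIGH_TAIL, vi.ATYPICAL),
        ],
    )
    def test_rule_table(self, z, rule, expected):
        assert vi.classify_task(z, rule) == expected

    def test_enumeration_against_independent_rule_table(self):
        # brute-force cross-check of every rule x sign x magnitude cell
        for rule in vi.RULES:
            for z in (-2.5, -1.0, -0.5, 0.0, 0.5, 1.0, 2.5):
                got = vi.classify_task(z, rule)
                if rule == vi.BOTH_TAILS:
                    want = abs(z) > 1
                elif rule == vi.HIGH_TAIL:
                    want = z > 1
                else:
                    want = z < -1
                assert got == (vi.ATYPICAL if want else vi.NORMATIVE)

    def test_missing_is_flag_not_error(self):
        assert vi.classify_task(float("nan")) == vi.MISSING
        assert vi.classify_task(None) == vi.MISSING

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            vi.classify_task(0.0, "sideways")


FLAG = st.sampled_from([vi.NORMATIVE, vi.ATYPICAL, vi.MISSING])


class TestAggregate:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            (["normative"] * 3 + ["missing"] * 2, vi.LOW),
            (["atypical"] + ["normative"] * 4, vi.MEDIUM),
            (["atypical"] * 3 + ["normative"] * 2, vi.HIGH),
            (["atypical"] + ["missing"] * 4, vi.EXCLUDED),
            (["atypical", "atypical"] + ["missing"] * 3, vi.HIGH),
        ],
    )
    def test_category_rule(self, flags, expected):
        assert vi.aggregate(flags) == expected

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(FLAG, min_size=5, max_size=5))
    def test_partition_is_exhaustive_and_consistent(self, flags):
        cat = vi.aggregate(flags)
        n_avail = sum(f != vi.MISSING for f in flags)
        n_atyp = sum(f == vi.ATYPICAL for f in flags)
        assert cat in (vi.LOW, vi.MEDIUM, vi.HIGH, vi.EXCLUDED)
        assert (cat == vi.EXCLUDED) == (n_avail < 2)
        if n_avail >= 2:
            assert cat == {0: vi.LOW, 1: vi.MEDIUM}.get(n_atyp, vi.HIGH)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(FLAG, min_size=5, max_size=5), st.integers(0, 4))
    def test_atypical_flip_never_lowers_category(self, flags, pos):
        order = {vi.LOW: 0, vi.MEDIUM: 1, vi.HIGH: 2}
        before = vi.aggregate(flags)
        flipped = list(flags)
        if flipped[pos] != vi.NORMATIVE:
            return
        flipped[pos] = vi.ATYPICAL
        after = vi.aggregate(flipped)
        if before == vi.EXCLUDED:
            assert after == vi.EXCLUDED
        else:
            assert order[after] >= order[before]


def _index_oracle(cohort, rules):
    """Straight per-row recomputation with explicit loops (no shared code)."""
    tasks = list(rules)
    stats = {}
    for t in tasks:
        vals = [v for v in cohort[f"task_{t}"] if not pd.isna(v)]
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        stats[t] = (mean, sd)
    cats = []
    for _, row in cohort.iterrows():
        n_avail = n_atyp = 0
        for t in tasks:
            v = row[f"task_{t}"]
            if pd.isna(v):
                continue
            n_avail += 1
            z = (v - stats[t][0]) / stats[t][1]
            rule = rules[t]
            atyp = (
                abs(z) > 1 if rule == "both_tails"
                else z > 1 if rule == "high_tail"
                else z < -1
            )
            n_atyp += atyp
        if n_avail < 2:
            cats.append("excluded")
        elif n_atyp == 0:
            cats.append("low")
        elif n_atyp == 1:
            cats.append("medium")
        else:
            cats.append("high")
    return cats


class TestBuildIndex:
    def test_all_within_one_sd_is_all_low(self):
        # alternating +/-1 scores: sample SD (n-1 denominator) slightly
        # exceeds 1, so every |z| < 1 and everyone is normative everywhere
        vals = np.tile([1.0, -1.0], 25)
        cohort = pd.DataFrame(
            {
                "participant_id": [str(i) for i in range(50)],
                "task_a": vals,
                "task_b": -vals,
            }
        )
        out = vi.build_index(cohort, {"a": vi.BOTH_TAILS, "b": vi.BOTH_TAILS})
        assert (out["category"] == vi.LOW).all()

    def test_matches_independent_oracle(self, default_cohort):
        cfg, cohort = default_cohort
        out = vi.build_index(cohort, cfg.rules)
        assert list(out["category"]) == _index_oracle(cohort, cfg.rules)

    def test_group_relabelling_leaves_categories_unchanged(self, default_cohort):
        cfg, cohort = default_cohort
        swapped = cohort.copy()
        swapped["group"] = swapped["group"].map({"MT": "NMT", "NMT": "MT"})
        a = vi.build_index(cohort, cfg.rules)
        b = vi.build_index(swapped, cfg.rules)
        pd.testing.assert_frame_equal(a, b)

    def test_mt_exceeds_nmt_in_high_category(self):
        from neurovuln import synthetic_cohort as sc

        cfg = sc.default_config(seed=4)
        cfg.n_mt = cfg.n_nmt = 2000
        cohort = sc.generate_cohort(cfg)
        out = vi.build_index(cohort, cfg.rules)
        merged = cohort[["participant_id", "group"]].merge(out, on="participant_id")
        rate = merged.groupby("group")["category"].apply(lambda s: (s == vi.HIGH).mean())
        assert rate["MT"] > rate["NMT"]

    def test_profiles_roundtrip(self, default_cohort):
        cfg, cohort = default_cohort
        frame = vi.build_index(cohort.head(5), cfg.rules)
        profiles = vi.profiles_from_frame(frame)
        assert [p.category for p in profiles] == list(frame["category"])
        assert all(p.n_atypical <= p.n_available <= 5 for p in profiles)
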