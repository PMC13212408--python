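#!/usr/bin/env python
"""Build the cumulative neurocognitive vulnerability index.

Standardizes each task metric over the combined sample, flags scores more
than 1 SD in the task's atypical direction, aggregates to the trinary
category, and writes per-participant profiles plus the group x category
distribution table.
"""

import argparse
import pathlib

import pandas as pd

from neurovuln import synthetic_cohort as sc
from neurovuln import vulnerability_index as vi

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=pathlib.Path, default=pathlib.Path("results"))
args = ap.parse_args()

cohort = sc.read_cohort(args.results / "cohort.csv")
rules = sc.default_config().rules
profiles = vi.build_index(cohort, rules)
profiles.to_csv(args.results / "vulnerability_profiles.csv", index=False)

merged = cohort[["participant_id", "group"]].merge(profiles, on="participant_id")
scored = merged[merged["category"] != vi.EXCLUDED]
dist = pd.crosstab(scored["group"], scored["category"]).reindex(
    index=["NMT", "MT"], columns=list(vi.CATEGORIES), fill_value=0)
dist.to_csv(args.results / "index_distribution.csv")

n_excl = (merged["category"] == vi.EXCLUDED).sum()
print("group x vulnerability category counts:")
print(dist)
print(f"excluded (fewer than 2 available tasks): {n_excl}")
print(f"wrote {args.results / 'vulnerability_profiles.csv'}")
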