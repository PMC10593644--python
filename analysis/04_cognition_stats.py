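#!/usr/bin/env python
"""Group statistics: composite recomputation, pre/post tests, correlations.

Part A recomputes the published baseline cognitive-domain composites from
the printed battery group moments (n=28) under pooled pre+post
standardization.  Part B runs the paired pre/post comparisons and
brain-behavior correlations on the synthetic cohort and reports which
planted effects are detected.  Outputs under results/cohort/ and
results/composites.csv.
"""
import pandas as pd

from dynfnc.cognition import composite_domains
from dynfnc.pipeline import PipelineConfig, run_pipeline
from dynfnc.published_cohort import DOMAINS, RECOMPUTABLE_DOMAINS, synthesize_battery

# Part A: published composite recomputation
comp = composite_domains(synthesize_battery(seed=0), DOMAINS)
means = comp.groupby("domain")[["pre", "post"]].mean()
means.to_csv("results/composites.csv", float_format="%.4f")
print("baseline composite means recomputed from published moments:")
for domain, published in RECOMPUTABLE_DOMAINS.items():
    print(f"  {domain:14s} {means.loc[domain, 'pre']:+.3f}  (published {published:+.2f})")

# Part B: synthetic-cohort group statistics
config = PipelineConfig(outdir="results/cohort", seed=7)
config.cohort.seed = 7
run_pipeline(config, stages=("simulate", "connectivity", "states", "stats"))

rep = pd.read_csv("results/cohort/group_differences.csv")
sfnc = rep[rep.family == "sfnc"].set_index("feature")
print("\nplanted sFNC treatment effects (paired t, p < 0.05 uncorrected):")
for pair in ("rFPN-lFPN", "mVN-pVN"):
    row = sfnc.loc[pair]
    print(f"  {pair}: t = {row.t:+.2f}, p = {row.p:.4f}, "
          f"{'detected' if row.significant else 'not detected'}")
print(f"other sFNC pairs flagged: {int(sfnc.significant.sum()) - 2} of {len(sfnc) - 2} "
      "(false positives at alpha = 0.05, uncorrected)")
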