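"""Rank-test enrichment of mutations in region sets against two nulls.

Per-region mutation rates are compared against (a) each region's own flanks
and (b) chromosome/length-matched random regions, with the Mann-Whitney U
test; fold change is the ratio of pooled rates. The subsample-stability check
repeats the call on random 10-sample sub-cohorts.
"""

from epimut import (SimConfig, enrichment_test, filter_hypermutators,
                    simulate_dataset, subsample_stability)

ds = simulate_dataset(SimConfig(seed=7))
cohort, _ = filter_hypermutators(ds.cohort)

for name, flank in (("mirnas", 5000), ("CTCF", 300), ("H3K27me3", 4000)):
    regions = ds.features[name]
    for null in ("flank", "random"):
        res = enrichment_test(cohort, regions, null_kind=null, flank_bp=flank,
                              genome=ds.genome, seed=1, region_set_name=name)
        print(f"{name:10s} vs {null:6s} null: fold={res.fold:5.2f} "
              f"U={res.U:9.0f} p={res.p_value:.3g}")
print("(a fold near the planted value with small p = enrichment recovered)")

df, summary = subsample_stability(cohort, ds.features["mirnas"], n_samples=10,
                                  n_draws=25, seed=3, null_kind="random",
                                  genome=ds.genome)
print(f"\n10-sample subsample stability over {summary['n_draws']} draws: "
      f"median fold {summary['median_fold']:.2f} "
      f"(IQR {summary['fold_iqr']:.2f}), "
      f"{summary['frac_significant']:.0%} of draws significant at 0.05")
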