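"""CpG observed/expected ratio, mutation occurrence and methylation coupling.

Low CpG O/E marks regions whose CpGs were historically eroded by deamination
of methylated cytosines, so recurrent mutation should anti-correlate with O/E
but not with raw CpG or GC content; and the C->T rate at methylated CpGs
should exceed the unmethylated rate by the planted multiplier.
"""

from dataclasses import replace

from epimut import (SimConfig, cpg_oe_window, methylation_ct_ratio,
                    occurrence_vs_metric, simulate_dataset)

print(f"O/E of a pure-CpG 400bp window: {cpg_oe_window('CG' * 200):.5f}")

# planted O/E-dependent mutation rate (rate ~ exp(-3 * local O/E))
cfg = SimConfig(seed=1, n_chroms=1, chrom_len=600_000, n_genes=30,
                n_mirnas=60, n_peaks={"CTCF": 60},
                peak_len={"CTCF": (150, 400)}, n_ncrnas=8, n_pseudogenes=4,
                cpg_island_count=20, n_samples=15, n_hypermutators=0,
                mu0=1.5e-4, oe_coupling_beta=3.0)
ds = simulate_dataset(cfg)
for metric in ("OE", "CG", "GC"):
    _bins, rho, p = occurrence_vs_metric(ds.cohort.snvs(), ds.genome,
                                         metric=metric)
    print(f"occurrence vs {metric}: Spearman rho={rho:+.3f} p={p:.3g}")
print("(negative, significant rho for OE = the planted coupling recovered)")

# 10x C->T multiplier at methylated CpGs, at ratio-identifiable depth
deep = SimConfig(seed=5, mu0=1e-3, n_samples=40, n_hypermutators=0)
res = methylation_ct_ratio(*(lambda d: (d.cohort, d.methylation, d.genome))(
    simulate_dataset(deep)))
print(f"\nC->T rate ratio methylated/unmethylated CpGs: {res.ratio:.2f} "
      f"(planted 10.0; {res.n_events_methylated}/{res.n_events_unmethylated} "
      "events per stratum)")
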