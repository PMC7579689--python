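"""Composite mutation-density profiles over miRNA bodies and CTCF peaks.

Scales every feature body to a common bin axis with fixed flanks and pools
mutation counts per bin, stratified by substitution class (pyrimidine- vs
purine-reference). Frequencies are mutations per Mb per sample; a body/flank
frequency ratio well above 1 is the profile-level signature of enrichment.
"""

import numpy as np

from epimut import (ProfileSpec, SimConfig, filter_hypermutators,
                    peak_profile, scaled_profile, simulate_dataset)

ds = simulate_dataset(SimConfig(seed=7))
cohort, removed = filter_hypermutators(ds.cohort)
print(f"removed hypermutators: {removed}")

spec = ProfileSpec(flank_bp=5000, body_bins=40, flank_bin_bp=50)
prof = scaled_profile(cohort, ds.features["mirnas"], spec)
freq = prof.frequency_per_class["all"]
body = prof.bin_class == "body"
ratio = freq[body].mean() / freq[~body].mean()
print(f"miRNA profile ({prof.n_features} features, {prof.n_samples} samples): "
      f"body {freq[body].mean():.1f} vs flank {freq[~body].mean():.1f} "
      f"mut/Mb/sample, ratio {ratio:.2f} (planted fold 3.0)")

ctcf = peak_profile(cohort, ds.features["CTCF"], flank_bp=300, spec=spec)
f = ctcf.frequency_per_class["all"]
b = ctcf.bin_class == "body"
print(f"CTCF +/-300bp profile: in-peak/flank ratio "
      f"{f[b].mean() / f[~b].mean():.2f} (planted fold 2.0)")
print("per-class in-peak counts:",
      {c: int(ctcf.counts_per_class[c][b].sum())
       for c in ("ref_CT", "ref_GA", "indel")})
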