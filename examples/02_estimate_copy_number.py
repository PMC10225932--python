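"""Estimate relative mtDNA copy number from simulated off-target depths.

Simulates per-site Poisson depths at ~2.8x with the coverage-spike artifact
between rCRS positions 2,500-3,000, masks the spike, forms the depth ratio
rmtCN = mean(mt)/mean(autosomal), and residualizes log rmtCN on sex, age and
the quadratic-interaction blood-count model to get rlrmtCN.
"""

import numpy as np

from mtcnkit import copynumber, simulate

cfg = simulate.SimulationConfig(n_individuals=800, seed=7)
cohort = simulate.simulate_cohort(cfg)
true_lrmtcn = simulate.simulate_copy_number(cohort, seed=8)
profiles = simulate.simulate_depth(true_lrmtcn, simulate.CoverageConfig(),
                                   seed=9,
                                   individual_ids=cohort["individual_id"].to_numpy())

records = copynumber.estimate_cohort(profiles)  # masks [2500, 3000] by default
r = np.corrcoef(records["lrmtcn"], true_lrmtcn)[0, 1]
print(f"corr(estimated lrmtCN, true lrmtCN) = {r:.3f} at 2.8x coverage")

unmasked = copynumber.estimate_cohort(profiles, spike_region=None)
bias = (unmasked["rmtcn"] / records["rmtcn"]).mean()
print(f"unmasked/masked rmtCN ratio = {bias:.4f} "
      f"(the spike inflates the unmasked estimate)")

records = copynumber.residualize(records, cohort, model="full")
print(f"sd(lrmtCN) = {records['lrmtcn'].std():.3f}  ->  "
      f"sd(rlrmtCN) = {records['rlrmtcn'].std():.3f}")
print("The drop is the variance explained by cell composition, sex and age.")
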