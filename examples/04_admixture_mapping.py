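"""Admixture mapping with an empirical multiple-testing burden.

Local-ancestry tracts are long, so per-marker tests are heavily correlated.
The effective number of tests N_eff comes from autoregressive fits to each
individual's per-chromosome ancestry series (spectral density at frequency
zero); the genome-wide threshold is 0.05/N_eff.
"""

import numpy as np

from mtcnkit import admixture, simulate

cfg = simulate.SimulationConfig(n_individuals=1500, seed=10,
                                generations_since_admixture=8)
cohort = simulate.simulate_cohort(cfg)
marker_map = simulate.uniform_marker_map(n_chromosomes=4,
                                         markers_per_chromosome=250)
local = simulate.simulate_local_ancestry(cohort, marker_map, cfg, seed=11)

# phenotype driven by ancestry at one marker
rng = np.random.default_rng(12)
target = 500
y = 0.3 * local.counts[:, target] + rng.normal(0, 1, len(cohort))

gfrac = admixture.global_ancestry(local)
scan = admixture.local_ancestry_assoc(y, local, gfrac,
                                      cohort["duffy_genotype"].to_numpy())
eff = admixture.effective_tests(local)

best = scan.loc[scan["p"].idxmin()]
print(f"markers tested: {local.n_markers};  N_eff = {eff['n_eff']:.0f};  "
      f"threshold = {eff['threshold']:.2e}")
print(f"top hit at {best['predictor_id']} (planted marker index {target}), "
      f"p = {best['p']:.2e}")
print(f"genome-wide significant: {best['p'] < eff['threshold']}")
print("N_eff is far below the marker count because tracts span many markers.")
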