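"""Mito-nuclear incompatibility: the interaction test, its power, and the
discordance artifact.

An incompatibility would appear as a haplogroup-by-ancestry interaction on a
phenotype. The older "discordance" statistic (fraction of nuclear ancestry
mismatching the mtDNA lineage) is confounded with the ancestry main effect
whenever haplogroups are imbalanced; the demonstration below manufactures a
spurious signal from a pure ancestry effect with zero interaction.
"""

from mtcnkit import mitonuclear

pc = mitonuclear.power_quantitative(n=8311, effect_grid=[0.1, 0.25, 0.5, 1.0],
                                    sigma=0.8, reps=300, seed=30)
print("interaction-test power, quantitative trait (alpha = 3.5e-5):")
print(pc.to_frame().round(3).to_string(index=False))
print("Effect is the ancestry slope (phenotype SDs) whose direction reverses")
print("between haplogroups; the analytic column is the noncentral-chi-square")
print("oracle from each design's interaction-column partial variance.\n")

demo = mitonuclear.discordance_artifact_demo(n=8311, haplogroup_freq=0.8,
                                             reps=200, seed=31)
print(f"artifact demo (pure ancestry effect, zero interaction, 80/20 haplogroups):")
print(f"  discordance-test rejection rate: {demo['discordance_rejection_rate']:.2f}")
print(f"  interaction-test rejection rate: {demo['interaction_rejection_rate']:.2f}")
print("The discordance regression rejects far above the 5% level despite no")
print("incompatibility; the interaction test stays calibrated.")
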