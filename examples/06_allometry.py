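"""ANCOVA homogeneity-of-slopes test for allometric divergence.

Simulates two lineages with different allometric slopes of one morphometric
on body length and asks whether the slope difference is detectable - the
signature of distinct developmental trajectories between species.
"""

import numpy as np

from delimix import SimConfig, sim_traits, slope_heterogeneity

# two lineages, slopes 1.0 vs 1.3 on the log10-log10 scale
cfg = SimConfig(
    n_pops=2, samples_per_pop=100, seed=3,
    allometric_beta=(1.0, 1.3), allometric_alpha=(0.0, 0.0),
    trait_sigma=0.02,
)
traits = sim_traits(cfg)
group = np.repeat(["A", "B"], cfg.samples_per_pop)

res = slope_heterogeneity(
    traits.df["body_length"].to_numpy(), traits.df["L01"].to_numpy(), group
)
print(f"slopes: A={res.slopes['A']:.3f}  B={res.slopes['B']:.3f}")
print(f"homogeneity of slopes: F({res.df1},{res.df2}) = {res.F:.1f}, p = {res.p:.3g}")
print("\na small p rejects a common allometric slope: the two groups grow")
print("along different trajectories, independent evidence of divergence")
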