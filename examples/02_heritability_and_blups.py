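"""Variance components, heritability and environment comparison.

Simulates a 200-genotype x 4-environment x 2-replicate germination
trial with the default generating components (genotype 0.031,
environment 0.015, GxE 0.018, residual 0.003 GI^2), fits the all-random
across-environment model by REML and prints what a multi-environment
trial report would show.
"""

from sproutval import SimulationConfig, simulate_trials, simulate_panel
from sproutval import fit_across_env, fit_within_env, heritability, variance_shares
from sproutval import compare_env_means
from sproutval.phenotype import gi_table
import pandas as pd

cfg = SimulationConfig(rng_seed=4)
_, _, truth = simulate_panel(cfg)
gi = gi_table(simulate_trials(cfg, truth))

blups, vc = fit_across_env(gi)
print(f"sigma2_g   = {vc.sigma2_g:.4f}   (generating 0.031)")
print(f"sigma2_e   = {vc.sigma2_e:.4f}   (generating 0.015)")
print(f"sigma2_gxe = {vc.sigma2_gxe:.4f}   (generating 0.018)")
print(f"sigma2_eps = {vc.sigma2_eps:.4f}   (generating 0.003 + ~0.0045 counting noise)")
print(f"shares (%): {variance_shares(vc)}")
print(f"broad-sense heritability h2 = {heritability(vc):.2f}")

within = []
for env, grp in gi.groupby("environment_id"):
    b, _ = fit_within_env(grp)
    b["environment_id"] = env
    within.append(b)
cmp_ = compare_env_means(pd.concat(within))
print("\nEnvironment means of BLUP GI (Tukey HSD letters, alpha = 0.05):")
for row in cmp_.itertuples(index=False):
    print(f"  {row.environment_id}: {row.mean:.2f} {row.letter}")
print("\nEnvironments sharing a letter do not differ significantly;")
print("h2 near 0.86 says genotype ranking is highly repeatable across sites.")
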