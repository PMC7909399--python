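"""Constrained ordination: which environmental variables explain community
composition?

Hellinger-transforms the counts, forward-selects environmental predictors
with a 199-permutation Monte-Carlo gate at p < 0.05, prunes collinear
variables at VIF > 10, and fits the final redundancy analysis.
"""

from aquassembly import (SimConfig, forward_select, hellinger_transform,
                         preprocess, rarefy, rda_fit, simulate_dataset)

cm, md, _ = simulate_dataset(SimConfig(n_species=300, reads_per_sample=2000,
                                       nu=0.2, seed=3))
cm = preprocess(cm)
cm = rarefy(cm, int(cm.sample_totals.min()), seed=3)
hel = hellinger_transform(cm)
env = md[["salinity", "tdn", "tdp", "wt", "ph", "do", "chl_a"]].astype(float)

trace = forward_select(hel.to_numpy(), env, alpha=0.05, n_perm=199, seed=3)
print("forward selection steps:")
for step in trace.steps:
    print(f"  + {step['variable']:<9} added R2 = {step['added_r2']:.3f} "
          f"(p = {step['p']:.3f})")
print("dropped for VIF > 10:", trace.dropped_for_vif or "none")

fit = rda_fit(hel.to_numpy(), env[trace.selected].to_numpy(),
              n_perm=199, seed=4)
print(f"\nfinal model: R2 = {fit.r2:.3f}, adjusted R2 = {fit.adj_r2:.3f}, "
      f"pseudo-F = {fit.pseudo_f:.2f}, p = {fit.p_value:.3f}")
# Salinity enters first and carries most of the explained variation, as
# expected when niche filtering acts along the salinity gradient.
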