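"""Spatial clonal cartography: gradients, territories, projections.

Uses the default simulated gland to regress burden on ductal distance
(the proximal-to-distal mutation gradient), telomere length on burden
(replicative attrition), flatten the gland by classical MDS, and map
each clone's territory on the ductal graph.
"""

import numpy as np

import glandphylo as gp

sim = gp.simulate_gland(gp.SimulationConfig(seed=8))
samples = sim.samples.set_index("sample_id")

burden = sim.truth.true_burden.reindex(samples.index)
dist = samples["path_distance_um"]

grad = gp.gradient_regression(burden.to_numpy(), dist.to_numpy())
print(
    f"burden gradient: {grad.slope:.3f} mutations/um "
    f"(95% CI {grad.slope_ci[0]:.3f}-{grad.slope_ci[1]:.3f}, R2 {grad.r_squared:.2f})"
)

tel = gp.gradient_regression(samples["telomere_bp"].to_numpy(), burden.to_numpy())
print(
    f"telomere attrition: {tel.slope:.3f} bp/mutation "
    f"(95% CI {tel.slope_ci[0]:.3f}-{tel.slope_ci[1]:.3f})"
)

emb, eigval = gp.mds_2d(samples[["x_um", "y_um", "z_um"]].to_numpy())
explained = eigval[:2].sum() / eigval[eigval > 0].sum()
print(f"2D MDS projection captures {100 * explained:.0f}% of spatial variance")

# territory of the largest embryonic clone
founders = sim.truth.embryonic_cc()
top = founders.sum(axis=1).idxmax()
territory = gp.clone_territory(
    sim.graph, founders.loc[top], samples["duct_node"]
)
print(
    f"founder {top}: contributes >= 10% in {territory.n_samples} microdissections, "
    f"{territory.n_components} contiguous block(s), span {territory.span_um:.0f} um"
)

mc = gp.multiclonal_fraction(founders)
print(f"multiclonal microdissections: {mc.percent}% ({mc.numerator}/{mc.denominator})")
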