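"""Space versus environment: PCNM axes, VIF screening, partial Mantel.

Builds spatial eigenvectors (PCNM) from the geographic distance matrix,
screens environmental variables for collinearity (VIF > 10 removed), and
asks whether community dissimilarity tracks space after controlling for
environment (and vice versa) with partial Mantel tests.
"""

import skbio
from scipy.spatial.distance import pdist, squareform

import assemblage as asm
from assemblage.simulate import demo_config, simulate_metacommunity

dataset = simulate_metacommunity(demo_config("dispersal_limitation", seed=7))
bc = asm.bray_curtis(dataset.table)
geo = asm.geographic_distance(dataset.metadata)

axes = asm.pcnm(geo)
print(f"PCNM: {axes.axes.shape[1]} positive axes, truncation "
      f"{axes.truncation:.1f} km")

retained, vifs = asm.vif_filter(dataset.metadata.env_matrix())
print("variables kept after VIF screening:", retained)

env = dataset.metadata.env_matrix(retained)
env_z = (env - env.mean()) / env.std(ddof=1)
env_dm = skbio.DistanceMatrix(
    squareform(pdist(env_z.to_numpy())), ids=list(env.index)
)
space_dm = asm.pcnm_distance(axes)

space = asm.partial_mantel(bc, space_dm, env_dm, "spearman", 999, seed=8)
envir = asm.partial_mantel(bc, env_dm, space_dm, "spearman", 999, seed=8)
print(f"community ~ space | environment: r = {space.r:+.3f}, p = {space.p_value:.3f}")
print(f"community ~ environment | space: r = {envir.r:+.3f}, p = {envir.p_value:.3f}")
print(
    "\nA stronger partial correlation with space than with environment "
    "corroborates a stochastic (dispersal-driven) assembly interpretation."
)
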