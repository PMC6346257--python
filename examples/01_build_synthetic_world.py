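"""Build a synthetic study world and inspect its structure.

A world is a rectangular pixel grid with nested admin partitions
(region > country > admin1 > admin2), per-year covariate layers, an under-5
population surface, and a true logit-prevalence surface = covariate signal
plus one draw of a Matern (x) AR1 Gaussian process.
"""
import numpy as np

from cgfmap import GPHyperParams, WorldConfig, make_world, simulate_truth

config = WorldConfig(n_rows=20, n_cols=20, years=tuple(range(2000, 2017)))
grid, covs = make_world(config, seed=1)

gp = GPHyperParams(spatial_range=6.0, spatial_var=0.5, ar1_rho=0.8)
beta = np.array([0.3, -0.2, 0.25, 0.15, -0.1])
truth = simulate_truth(grid, covs, gp, beta, seed=1)

print(f"grid: {grid.n_rows}x{grid.n_cols} pixels, {grid.n_years} years")
print(f"countries: {len(np.unique(grid.country_id))}, "
      f"admin2 units: {len(np.unique(grid.admin2_id))}")
print(f"under-5 population per pixel: median "
      f"{np.median(grid.population):.0f}, masked pixels: {grid.mask.sum()}")
print(f"covariates: {covs.names} (static: {covs.is_static.sum()})")
p = truth.prevalence
print(f"true prevalence 2000: mean {p[:, 0].mean():.3f}, "
      f"range [{p[:, 0].min():.3f}, {p[:, 0].max():.3f}]")
# The GP term makes neighbouring pixels correlated: prevalence varies
# smoothly in space with an effective correlation range of ~6 pixels and a
# year-to-year correlation of 0.8.
lag1 = np.corrcoef(truth.logit_prev[:, 0], truth.logit_prev[:, 1])[0, 1]
print(f"lag-1 temporal correlation of the surface: {lag1:.2f}")
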