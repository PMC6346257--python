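"""Turn an areal survey observation into weighted pseudo-points.

Clusters located only to an admin polygon cannot enter a point-referenced
likelihood directly. We sample 10,000 locations inside the polygon with
probability proportional to population, reduce them to k-means centroids,
and down-weight each centroid by its cluster share — so one polygon still
contributes exactly one observation's worth of information.
"""
import pandas as pd

from cgfmap import WorldConfig, make_world
from cgfmap.preprocess import resample_polygon_obs

grid, _ = make_world(WorldConfig(n_rows=12, n_cols=12,
                                 years=(2000, 2001)), seed=4)

obs = pd.Series({"cluster_id": 17, "admin_ref": 2, "year": 2000,
                 "N": 35, "C": 12, "weight": 1.0, "month": 7,
                 "indicator": "stunting", "geometry_type": "polygon"})

pseudo = resample_polygon_obs(obs, grid, n_samples=10_000, k=5, seed=4)
print(pseudo[["cluster_id", "x", "y", "N", "C", "weight"]]
      .round(3).to_string(index=False))
print(f"\nweights sum to {pseudo['weight'].sum():.12f}")
# Each pseudo-point carries the parent's counts (N=35, C=12); its weight
# multiplies the binomial log-likelihood, so the five rows jointly count as
# one cluster. Centroids sit where the polygon's population sits.
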