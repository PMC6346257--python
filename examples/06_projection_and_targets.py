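"""Project prevalence to 2025 and classify pace of progress.

AROC_t = logit(p_t) - logit(p_{t-1}); a recency-weighted mean with weights
w_t ~ (t - 2000)^gamma (gamma = 1, linear) is applied for ten more years on
the logit scale. Pixels are classified against a target: met / behind (with
a pace ratio and required acceleration) / non-decreasing.
"""
import numpy as np

from cgfmap import targets as tg
from cgfmap.util import expit, logit

years = np.arange(2000, 2016)
# three stylised pixels: steady decline, stagnation, deterioration
p_decline = expit(logit(0.40) - 0.06 * (years - 2000))
p_flat = np.full(16, 0.30)
p_rising = expit(logit(0.20) + 0.02 * (years - 2000))

target = 0.242   # e.g. 40% below a 2010 continental stunting aggregate
for name, p in [("declining", p_decline), ("stagnant", p_flat),
                ("rising", p_rising)]:
    aroc = tg.annual_logit_aroc(p)
    mean_aroc = tg.weighted_aroc(aroc, years[1:])
    p2025 = tg.project_prevalence(p[-1], mean_aroc)
    row = tg.pace_and_acceleration(p, years[1:], target).iloc[0]
    print(f"{name:10s} p2015={p[-1]:.3f}  p2025={p2025:.3f}  "
          f"status={row['status']:>14s}  pace={row['pace_ratio']:.0f}%"
          if np.isfinite(row["pace_ratio"]) else
          f"{name:10s} p2015={p[-1]:.3f}  p2025={p2025:.3f}  "
          f"status={row['status']}")
w = tg.ProjectionConfig().weights(years[1:])
print(f"\nlinear AROC weights: w_2001={w[0]:.4f} ... w_2015={w[-1]:.4f} "
      f"(sum={w.sum():.0f})")
# The declining pixel projects well below target by 2025; the stagnant one
# has pace 0% of what is required; the rising one is 'non-decreasing'.
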