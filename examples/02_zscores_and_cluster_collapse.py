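"""From child measurements to cluster-level binomial observations.

Heights/weights are converted to z-scores with the LMS method
(z = ((x/M)^L - 1)/(L*S)), growth failure is the strict z < -2 rule,
exclusion rules drop unusable records, and microdata are collapsed to
per-cluster (N, C) counts — the likelihood unit of the geostatistical model.
"""
import pandas as pd

from cgfmap import anthro

lms = anthro.make_synthetic_lms_tables()

# one child measured below and one above the stunting threshold
ref = lms.set_index(["indicator", "sex", "index"])
L, M, S = ref.loc[("HAZ", "female", 24)]
records = pd.DataFrame([
    {"cluster_id": 1, "sex": "female", "age_months": 24,
     "height_cm": anthro.lms_inverse(-2.6, L, M, S),
     "weight_kg": 10.0, "interview_year": 2010, "interview_month": 4},
    {"cluster_id": 1, "sex": "female", "age_months": 24,
     "height_cm": anthro.lms_inverse(-0.4, L, M, S),
     "weight_kg": 11.0, "interview_year": 2010, "interview_month": 4},
    {"cluster_id": 1, "sex": None, "age_months": 24,      # excluded: no sex
     "height_cm": 80.0, "weight_kg": 10.5,
     "interview_year": 2010, "interview_month": 4},
])

clean, log = anthro.apply_exclusions(records)
print("exclusion log:")
print(log[log["n_excluded"] > 0].to_string(index=False))

obs = anthro.collapse_to_cluster(clean, lms, "stunting")
print("\ncluster observation:")
print(obs.to_string(index=False))
# N = scoreable children, C = children with HAZ strictly below -2:
# the cluster contributes a Binomial(N=2, C=1) term to the model.
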