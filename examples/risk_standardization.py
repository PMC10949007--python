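"""Standardizing distances to risks and combining the three factors.

Risk falls as distance grows: risk = 1 - d/M with M the maximum distance
rounded up to the next highest integer, so even the farthest pair keeps a
strictly positive risk, and zero distance means zero risk (a region poses
no risk to itself).
"""

import pandas as pd

from searisk import DistanceMatrix, RiskMatrix, combine_risks, standardize_risk

# the largest cross-latitude span between any two coastal provinces is
# 84.92 degrees (Arctic <-> Java Transitional)
ids = [1, 27]
span = pd.DataFrame([[0.0, 84.92], [84.92, 0.0]], index=ids, columns=ids)
rm = standardize_risk(DistanceMatrix(span, units="degrees"))
print(f"cap M = {rm.cap} (84.92 rounded up)")
print(f"voyage-path risk of the widest-spanning route: {rm.df.loc[1, 27]:.3f}")
print()


def pair(v, risk_type):
    df = pd.DataFrame([[0.0, v], [v, 0.0]], index=[1, 2], columns=[1, 2])
    return RiskMatrix(df, risk_type=risk_type)


# combining the three factor risks with equal weights, e.g. the values for
# the Cold Temperate NW Atlantic relative to the Northern European Seas
env, dur, path = 0.886, 0.780, 0.803
combined = combine_risks(
    [pair(env, "environmental_similarity"), pair(dur, "voyage_duration"),
     pair(path, "voyage_path")]
)
print(f"environmental {env} + duration {dur} + path {path}")
print(f"combined risk = {combined.df.loc[1, 2]:.3f}  (scale 0-3)")
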