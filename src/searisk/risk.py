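"""Distance-to-risk standardization and risk combination.

Risk decreases as distance increases, so each distance matrix is rescaled
onto an inverted 0–1 scale:

    risk = 1 − d / M,    M = floor(max finite distance) + 1

M is the maximum distance rounded up to the next highest integer in the
matrix's native units, which guarantees the maximum-distance pair keeps a
risk strictly above 0.  Distances of exactly 0 map to risk 0: a region is
not a risk to itself.  Combined risk is the (weighted) elementwise sum of
the environmental-similarity, voyage-duration and voyage-path risks, in
[0, 3] under unit weights.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .matrices import DistanceMatrix, RiskMatrix

_RISK_TYPE_FOR_UNITS = {
    "meters": "voyage_duration",
    "degrees": "voyage_path",
    "unitless": "environmental_similarity",
}


def rounding_cap(distances: np.ndarray) -> float:
    """M = floor(max finite distance) + 1, in the matrix's native units.

    Equals the ceiling for non-integer maxima; for integer maxima it still
    steps up one, keeping the maximum-distance entry strictly positive
    after standardization.
    """
    finite = distances[np.isfinite(distances)]
    positive = finite[finite > 0]
    if positive.size == 0:
        raise ValueError("no finite positive distances to standardize")
    return float(math.floor(float(positive.max())) + 1)


def standardize_risk(d: DistanceMatrix, risk_type: str | None = None) -> RiskMatrix:
    """Convert a distance matrix to a standardized [0, 1) risk matrix.

    NA entries stay NA.  Infinite entries (unreachable pairs) are turned
    into NA with a warning — resolve connectivity (e.g. carve the missing
    canal) before relying on those pairs.
    """
    if risk_type is None:
        risk_type = _RISK_TYPE_FOR_UNITS[d.units]
    v = d.df.values.astype(float).copy()
    if np.isinf(v).any():
        warnings.warn(
            "distance matrix contains unreachable (+inf) pairs; their risk is NA",
            stacklevel=2,
        )
        v[np.isinf(v)] = np.nan
    cap = rounding_cap(v)
    risk = 1.0 - v / cap
    risk[v == 0.0] = 0.0  # includes the diagonal: no self-risk
    out = pd.DataFrame(risk, index=d.df.index, columns=d.df.columns)
    return RiskMatrix(out, risk_type=risk_type, cap=cap)


def combine_risks(
    risks: Sequence[RiskMatrix], weights: Sequence[float] | None = None
) -> RiskMatrix:
    """Weighted elementwise sum of risk matrices (default: equal weight 1).

    All matrices must share labels; NA in any component makes the combined
    entry NA.  With unit weights over the three factor risks the result
    ranges from 0 to 3.
    """
    if not risks:
        raise ValueError("no risk matrices to combine")
    if weights is None:
        weights = [1.0] * len(risks)
    if len(weights) != len(risks):
        raise ValueError("one weight per risk matrix required")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    ref = risks[0].df
    for rm in risks[1:]:
        if not (ref.index.equals(rm.df.index) and ref.columns.equals(rm.df.columns)):
            missing = sorted(
                set(map(str, ref.index)).symmetric_difference(map(str, rm.df.index))
            )
            raise ValueError(f"risk matrices have mismatched labels: {missing}")
    total = sum(w * rm.df for w, rm in zip(weights, risks))
    return RiskMatrix(total, risk_type="combined", cap=None)
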