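"""Comparison of estimated risk to recorded NIS introductions.

Empirical counts of vessel-mediated non-indigenous species (NIS)
introductions are reported against an external biogeographic
classification (Large Marine Ecosystems), while the risk matrices are
indexed by the internal region classification.  A judgment-based
crosswalk table maps between the two: external areas mapping onto one
internal region have their counts summed; a pair of adjacent external
areas matching a pair of adjacent internal regions is combined, summing
counts and averaging each risk type; ambiguous matches are omitted with a
reason.  Matches with a single recorded NIS ("singletons") can be
filtered before regression of counts on risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .matrices import RiskMatrix

RISK_COLUMNS = (
    "environmental_similarity",
    "voyage_duration",
    "voyage_path",
    "combined",
)

ACTIONS = ("sum_counts", "combine_and_average", "omit")


def load_table1() -> pd.DataFrame:
    """Packaged matched table for the Northern European Seas destination.

    Columns: origin_lme, region_label, the three factor risks, combined
    risk and the recorded NIS count, one row per crosswalk match.
    """
    ref = resources.files("searisk") / "data" / "table1_northern_european_seas.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def _split_ids(field) -> list:
    parts = [p.strip() for p in str(field).split(";") if str(p).strip()]
    out = []
    for p in parts:
        try:
            out.append(int(p))
        except ValueError:
            out.append(p)
    return out


def apply_crosswalk(
    records: pd.DataFrame,
    crosswalk: pd.DataFrame,
    risk_matrices: Mapping[str, RiskMatrix],
    destination_region: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match NIS-count records to internal regions and read off risks.

    ``records`` needs columns ``origin_id`` (one external area id per row)
    and ``count``; ``crosswalk`` needs ``external_ids`` and
    ``internal_ids`` (";"-separated), ``action`` (sum_counts |
    combine_and_average | omit) and ``reason`` (required for omit).  Risks
    are read from each matrix's destination column; combine_and_average
    rows average each risk type across the listed internal regions.

    Returns (matched table, omitted table).  Total counts are conserved:
    matched counts + omitted counts = input counts.
    """
    for col in ("origin_id", "count"):
        if col not in records.columns:
            raise ValueError(f"records table lacks column '{col}'")
    counts = {}
    for row in records.itertuples(index=False):
        key = _split_ids(row.origin_id)
        if len(key) != 1:
            raise ValueError(f"each record must carry one origin id, got {row.origin_id}")
        counts[key[0]] = counts.get(key[0], 0) + int(row.count)
        if int(row.count) < 0:
            raise ValueError("NIS counts must be nonnegative")

    owner: dict = {}
    for idx, row in crosswalk.iterrows():
        if row["action"] not in ACTIONS:
            raise ValueError(f"unknown crosswalk action '{row['action']}'")
        for ext in _split_ids(row["external_ids"]):
            if ext in owner:
                raise ValueError(f"external id {ext} appears in multiple crosswalk entries")
            owner[ext] = idx
    unmatched = [e for e in counts if e not in owner]
    if unmatched:
        raise KeyError(f"external ids with no crosswalk entry: {unmatched}")

    matched_rows, omitted_rows = [], []
    for idx, row in crosswalk.iterrows():
        ext_ids = _split_ids(row["external_ids"])
        total = sum(counts.get(e, 0) for e in ext_ids)
        if row["action"] == "omit":
            omitted_rows.append(
                {
                    "external_ids": row["external_ids"],
                    "count": total,
                    "reason": row.get("reason", ""),
                }
            )
            continue
        internal = _split_ids(row["internal_ids"])
        if row["action"] == "sum_counts" and len(internal) != 1:
            raise ValueError("sum_counts entries must map to exactly one internal region")
        if row["action"] == "combine_and_average" and len(internal) < 2:
            raise ValueError("combine_and_average entries need >=2 internal regions")
        entry = {
            "external_ids": row["external_ids"],
            "region_label": ";".join(str(i) for i in internal),
            "count": total,
        }
        for risk_name, rm in risk_matrices.items():
            vals = [float(rm.df.loc[i, destination_region]) for i in internal]
            entry[risk_name] = float(np.mean(vals))
        matched_rows.append(entry)
    matched = pd.DataFrame(matched_rows)
    omitted = pd.DataFrame(omitted_rows, columns=["external_ids", "count", "reason"])
    return matched, omitted


def filter_singletons(
    table: pd.DataFrame, count_col: str = "count"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop matches with exactly one recorded NIS.

    Returns (kept, removed).  Singleton matches are noisy one-off records
    that can confound the correlation among the remaining matches; they
    are reported rather than silently discarded.
    """
    if count_col not in table.columns:
        raise ValueError(f"table lacks count column '{count_col}'")
    singleton = table[count_col] == 1
    kept = table.loc[~singleton].reset_index(drop=True)
    removed = table.loc[singleton].reset_index(drop=True)
    if kept.empty and not table.empty:
        import warnings

        warnings.warn("all matches are singletons; filtered table is empty", stacklevel=2)
    return kept, removed


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares of y on x with intercept, plus R².

    R² = 1 − SS_res/SS_tot, the coefficient of determination of the fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    if np.ptp(y) == 0:
        # flat response: perfect fit by the intercept, zero explained variance
        return LinearFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, n=int(x.size))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=int(x.size),
    )


def regression_report(
    table: pd.DataFrame,
    risk_col: str = "combined",
    count_col: str = "count",
) -> pd.DataFrame:
    """Regress NIS counts on a risk column, with and without singletons.

    Returns one row per variant (all, singletons_omitted) with slope,
    intercept, R² and n.  The singleton-omitted variant is skipped when
    fewer than 2 matches remain or the remaining risks are constant.
    """
    rows = []
    fit_all = fit_linear(table[risk_col], table[count_col])
    rows.append({"variant": "all", **fit_all.__dict__})
    kept, _ = filter_singletons(table, count_col)
    if len(kept) >= 2 and np.ptp(kept[risk_col].values) > 0:
        fit_f = fit_linear(kept[risk_col], kept[count_col])
        rows.append({"variant": "singletons_omitted", **fit_f.__dict__})
    return pd.DataFrame(rows)
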