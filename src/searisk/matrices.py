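"""Labeled square distance and risk matrices with NA awareness.

Matrices are thin wrappers around pandas DataFrames whose row and column
labels are region ids.  Missing entries (excluded regions) are NaN in
memory and the literal ``NA`` in CSV files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VALID_UNITS = ("meters", "degrees", "unitless")
VALID_RISK_TYPES = (
    "environmental_similarity",
    "voyage_duration",
    "voyage_path",
    "combined",
)


def _check_square_labeled(df: pd.DataFrame) -> None:
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"matrix is not square: {df.shape}")
    if not df.index.equals(df.columns):
        raise ValueError("row and column labels differ")


def write_matrix_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled matrix as CSV; NaN becomes the literal NA."""
    df.to_csv(path, na_rep="NA", index_label="region")


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps write->read->write byte-stable
    df = pd.read_csv(path, index_col=0, na_values=["NA"], float_precision="round_trip")
    # region ids are integers whenever possible; fall back to strings
    try:
        df.index = df.index.astype(int)
        df.columns = [int(c) for c in df.columns]
    except (TypeError, ValueError):
        df.index = df.index.astype(str)
        df.columns = [str(c) for c in df.columns]
    df.index.name = None
    return df.astype(float)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise-distance matrix with a units tag.

    ``units`` is "meters" for physical over-water distance, "degrees" for
    cross-latitude distance, "unitless" for environmental distance.
    Diagonal entries are 0; excluded regions are NaN; unreachable pairs may
    be +inf (see :func:`searisk.voyage.unreachable_pairs`).
    """

    df: pd.DataFrame
    units: str = "unitless"
    validate: bool = True

    def __post_init__(self) -> None:
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}")
        self.df = self.df.astype(float)
        if self.validate:
            _check_square_labeled(self.df)
            v = self.df.values
            finite = np.isfinite(v)
            if np.any(v[finite] < 0):
                raise ValueError("distances must be nonnegative")
            diag = np.diag(v)
            if np.any(diag[np.isfinite(diag)] != 0):
                raise ValueError("diagonal must be zero (or NA)")
            if not np.allclose(
                np.where(finite, v, 0.0), np.where(finite.T, v.T, 0.0), equal_nan=True
            ):
                raise ValueError("matrix must be symmetric")

    @property
    def labels(self) -> list:
        return list(self.df.index)

    def to_csv(self, path: str | Path) -> None:
        write_matrix_csv(self.df, path)

    @classmethod
    def from_csv(cls, path: str | Path, units: str = "unitless") -> "DistanceMatrix":
        return cls(read_matrix_csv(path), units=units)


@dataclass
class RiskMatrix:
    """Standardized risk matrix.

    Non-combined risks lie in [0, 1); combined risks in [0, 3] under unit
    weights.  ``cap`` records the rounded-up maximum distance M used by the
    standardization, so any entry can be audited via d = M * (1 - risk).
    """

    df: pd.DataFrame
    risk_type: str
    cap: float | None = None

    def __post_init__(self) -> None:
        if self.risk_type not in VALID_RISK_TYPES:
            raise ValueError(f"risk_type must be one of {VALID_RISK_TYPES}")
        self.df = self.df.astype(float)
        _check_square_labeled(self.df)

    @property
    def labels(self) -> list:
        return list(self.df.index)

    def to_csv(self, path: str | Path) -> None:
        write_matrix_csv(self.df, path)

    @classmethod
    def from_csv(
        cls, path: str | Path, risk_type: str, cap: float | None = None
    ) -> "RiskMatrix":
        return cls(read_matrix_csv(path), risk_type=risk_type, cap=cap)
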