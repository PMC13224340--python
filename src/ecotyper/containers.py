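"""In-memory containers shared across the pipeline.

The central object is :class:`CommunityTable`, a sample x ASV abundance
matrix carrying an explicit transform-state tag so that downstream stages
can assert they received the normalization they expect (raw counts vs.
copy-corrected vs. relative vs. Hellinger).  Sample metadata and genetic
trait tables are plain :class:`pandas.DataFrame` objects with documented
column conventions (see :data:`METADATA_COLUMNS`, :data:`TRAIT_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Valid transform states, in the order they occur along the pipeline.
STATES = ("raw", "copy_corrected", "relative", "hellinger")

#: Expected per-sample metadata columns (dates ISO-8601).
METADATA_COLUMNS = (
    "date",
    "numeric_month",
    "latitude",
    "longitude",
    "temperature",
    "salinity",
    "chlorophyll_a",
)

#: Expected genetic trait columns (per sample or per ASV).
TRAIT_COLUMNS = ("copy_number", "genome_size", "gc_content", "doubling_time")


@dataclass
class CommunityTable:
    """Sample x ASV abundance matrix with a transform-state tag.

    Parameters
    ----------
    data:
        DataFrame with sample IDs as the index and ASV IDs as columns.
        All entries must be non-negative and finite.
    state:
        One of ``raw``, ``copy_corrected``, ``relative``, ``hellinger``.
    """

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("community table contains non-finite entries")
        if values.size and (values < 0).any():
            raise ValueError("community table contains negative entries")

    # -- convenience views ------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, state: str | None = None) -> "CommunityTable":
        return CommunityTable(data=data, state=self.state if state is None else state)

    def validate_state(self, atol: float = 1e-9) -> None:
        """Check the row-sum invariant implied by the current state."""
        values = self.values
        if self.state == "relative":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > atol
            if bad.any():
                raise ValueError(f"{bad.sum()} relative-abundance rows do not sum to 1")
        elif self.state == "hellinger":
            ss = (values**2).sum(axis=1)
            nonzero = values.sum(axis=1) > 0
            bad = nonzero & (np.abs(ss - 1.0) > atol)
            if bad.any():
                raise ValueError(f"{bad.sum()} Hellinger rows do not have unit sum of squares")


def validate_metadata(metadata: pd.DataFrame) -> None:
    """Validate a sample-metadata frame (unique dates, sane coordinates)."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    dates = pd.to_datetime(metadata["date"])
    if dates.duplicated().any():
        raise ValueError("metadata dates are not unique")
    lat = metadata["latitude"].to_numpy(dtype=float)
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude out of [-90, 90]")


def validate_traits(traits: pd.DataFrame) -> None:
    """Validate a trait frame: strictly positive values, GC% in (0, 100)."""
    missing = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    values = traits[list(TRAIT_COLUMNS)].to_numpy(dtype=float)
    if (values <= 0).any() or not np.isfinite(values).all():
        raise ValueError("trait values must be strictly positive and finite")
    gc = traits["gc_content"].to_numpy(dtype=float)
    if ((gc <= 0) | (gc >= 100)).any():
        raise ValueError("gc_content must lie in (0, 100)")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a metric tag."""

    matrix: np.ndarray
    ids: Sequence[str]
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != m.shape[0]:
            raise ValueError("ids length does not match matrix size")
        if np.abs(np.diag(m)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if np.abs(m - m.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if (m < -1e-12).any():
            raise ValueError("distance matrix must be non-negative")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]
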