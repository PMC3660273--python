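"""In-memory containers shared across pipeline stages.

Matrices are thin wrappers around pandas DataFrames: probes (or probe sets)
as rows, samples as columns. Linear-scale intensities stay linear until
summarization; expression indices are log2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["IntensityMatrix", "ExpressionMatrix", "AffinityProfile"]


@dataclass
class IntensityMatrix:
    """Probe-level linear intensities with chip geometry and an exclusion mask.

    Attributes
    ----------
    values : DataFrame
        probes x samples, non-negative linear intensities, unique row ids.
    geometry : DataFrame or None
        per-probe chip coordinates with columns ``x`` and ``y``.
    mask : DataFrame
        boolean, same shape as ``values``; True marks excluded entries.
    """

    values: pd.DataFrame
    geometry: Optional[pd.DataFrame] = None
    mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("IntensityMatrix row ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("IntensityMatrix values must be non-negative")
        if self.mask is None:
            self.mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        else:
            self.mask = self.mask.reindex(
                index=self.values.index, columns=self.values.columns, fill_value=False
            ).astype(bool)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(),
            None if self.geometry is None else self.geometry.copy(),
            self.mask.copy(),
        )

    def masked_values(self) -> pd.DataFrame:
        """Values with masked entries replaced by NaN."""
        return self.values.where(~self.mask)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class ExpressionMatrix:
    """Probe-set level log2 expression indices (rows = probe sets)."""

    values: pd.DataFrame
    design_ref: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("ExpressionMatrix row ids must be unique")

    @property
    def probe_set_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class AffinityProfile:
    """Per-probe-set median-polish row effects (log2), zero-sum per set."""

    effects: dict[str, pd.Series]

    def __getitem__(self, probe_set_id: str) -> pd.Series:
        return self.effects[probe_set_id]

    def __contains__(self, probe_set_id: str) -> bool:
        return probe_set_id in self.effects

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for set_id, eff in self.effects.items():
            for order, (probe_id, value) in enumerate(eff.items()):
                rows.append((set_id, probe_id, order, float(value)))
        return pd.DataFrame(
            rows, columns=["probe_set_id", "probe_id", "probe_order", "affinity_log2"]
        )

    def check_zero_sum(self, tol: float = 1e-6) -> bool:
        return all(abs(float(np.nansum(e.to_numpy()))) < tol for e in self.effects.values())
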