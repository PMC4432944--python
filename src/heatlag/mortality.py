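"""Daily cause-specific mortality counts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MortalitySeries"]


@dataclass
class MortalitySeries:
    """Daily death counts per ICD-10 category on a gap-free daily index.

    ``counts`` columns are the ICD-10 category codes; the aggregated series is
    always the row sum, so aggregate = sum of categories holds by construction.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.counts.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("MortalitySeries requires a DatetimeIndex")
        if idx.has_duplicates or not idx.is_monotonic_increasing:
            raise ValueError("dates must be unique and increasing")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("counts must be finite and non-negative")
        if np.any(vals != np.round(vals)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def aggregate(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.counts.index

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())
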