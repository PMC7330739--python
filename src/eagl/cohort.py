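"""Binary patient-year cohort tables.

One row per patient; one 0/1 column per (condition, year) pair named
``<COND>_Y<k>`` (e.g. ``TBI_Y1``).  This is the observational input to both
structure learning and parameter estimation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .spectral import parse_temporal_label

__all__ = ["CohortTable"]


class CohortTable:
    """An m × (conditions × years) binary observation matrix.

    Column labels must parse as ``<COND>_Y<k>``; values must be 0/1.
    The patient identifier lives in the DataFrame index.
    """

    def __init__(self, data: pd.DataFrame, seed: int | None = None):
        labels = list(data.columns)
        parsed = [parse_temporal_label(c) for c in labels]  # raises on bad label
        arr = data.to_numpy()
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell {arr[r, c]!r} at row {data.index[r]!r}, "
                f"column {labels[c]!r}"
            )
        self.data = data.astype(np.uint8)
        self.seed = seed
        self._parsed = parsed
        # condition order = first-appearance order in the header
        conds: list[str] = []
        for cond, _ in parsed:
            if cond not in conds:
                conds.append(cond)
        self.conditions: tuple[str, ...] = tuple(conds)
        self.years: tuple[int, ...] = tuple(sorted({y for _, y in parsed}))

    # -- accessors ---------------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return self.data.shape[1]

    @property
    def node_labels(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def node_year(self, i: int) -> int:
        return self._parsed[i][1]

    def node_condition(self, i: int) -> str:
        return self._parsed[i][0]

    def condition_index(self, i: int) -> int:
        return self.conditions.index(self._parsed[i][0])

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def column(self, label: str) -> np.ndarray:
        return self.data[label].to_numpy()

    def subset(self, rows: Sequence[int]) -> "CohortTable":
        return CohortTable(self.data.iloc[list(rows)], seed=self.seed)

    def prevalence(self) -> pd.Series:
        """Per-column empirical prevalence (useful for logging sanity checks)."""
        return self.data.mean(axis=0)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CohortTable m={self.m} nodes={self.n}>"
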