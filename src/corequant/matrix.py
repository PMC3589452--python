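"""Protein-by-sample abundance matrices with explicit missingness.

An :class:`AbundanceMatrix` carries its processing level (raw counts,
length-normalised, log, row Z-score, or Z-score after presence/absence
imputation) and a boolean mask of cells that were never observed.  The mask
is recorded when the matrix is built from rolled-up spectral counts and is
never mutated afterwards: the presence/absence imputation overwrites
*values* of gapped rows but downstream code (detection statistics, the
imputation itself) still needs to know which cells were real observations.

The level tag enforces the fixed transform order
``counts -> normalized -> log -> zscore -> zscore_imputed``; applying a
transform to a matrix at the wrong level raises :class:`LevelError`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LEVELS = ("counts", "normalized", "log", "zscore", "zscore_imputed")


class LevelError(ValueError):
    """A transform was applied to a matrix at the wrong processing level."""


class AbundanceMatrix:
    """Protein x sample grid of abundance values at a named level.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with sample ids as columns.  Cells
        may be NaN; at construction NaN cells are taken as missing unless an
        explicit ``missing_mask`` is given.
    level
        One of :data:`LEVELS`.
    missing_mask
        Boolean DataFrame of the same shape; True marks cells with no
        observation.  Defaults to ``values.isna()``.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        level: str,
        missing_mask: pd.DataFrame | None = None,
    ) -> None:
        if level not in LEVELS:
            raise LevelError(f"unknown level {level!r}; expected one of {LEVELS}")
        values = values.astype(float)
        if missing_mask is None:
            missing_mask = values.isna()
        missing_mask = missing_mask.astype(bool)
        if not (
            missing_mask.index.equals(values.index)
            and missing_mask.columns.equals(values.columns)
        ):
            raise ValueError("missing_mask must be aligned with values")
        if level == "counts":
            present = values.to_numpy()[~missing_mask.to_numpy()]
            if present.size and (np.any(present < 0) or np.any(present % 1 != 0)):
                raise ValueError("counts level requires non-negative integer values")
        self.values = values
        self.level = level
        self.missing_mask = missing_mask

    # -- basic introspection -------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def present_values(self) -> np.ndarray:
        """All values at observed (non-missing) cells, as a flat array."""
        arr = self.values.to_numpy()
        return arr[~self.missing_mask.to_numpy()]

    def require_level(self, *expected: str) -> None:
        if self.level not in expected:
            raise LevelError(
                f"operation requires level {' or '.join(expected)}, "
                f"got {self.level!r}"
            )

    def with_values(self, new_values: pd.DataFrame, level: str) -> "AbundanceMatrix":
        """Derived matrix at a new level, carrying the original mask."""
        return AbundanceMatrix(new_values, level, self.missing_mask.copy())

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.level, self.missing_mask.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"AbundanceMatrix(level={self.level!r}, proteins={n}, samples={m})"
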