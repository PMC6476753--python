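"""Symmetric pairwise matrices keyed by individual ids.

All the quantities the Mantel machinery consumes — genetic distance G,
Euclidean distance Dis, elevation-parameter matrices, resistance R_L,
combined resistance ΣR_L, and barrier indicators B_L — share one shape:
a symmetric matrix with zero diagonal over an ordered id list.  This module
provides that container plus lossless TSV round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError


@dataclass
class PairwiseMatrix:
    """A symmetric, zero-diagonal matrix over ordered individuals.

    Parameters
    ----------
    ids
        Ordered individual identifiers.
    values
        ``(n, n)`` symmetric array, diagonal zero.
    role
        What the matrix plays in the analysis, e.g. ``"G"``, ``"Dis"``,
        ``"R_L"``, ``"Sigma_R_L"``, ``"B_L"``, ``"elev_cv"``.
    metadata
        Free-form annotations (land-use class, weight, resistance-base mode).
    """

    ids: list[str]
    values: np.ndarray
    role: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ConfigurationError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ConfigurationError("duplicate ids in pairwise matrix")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ConfigurationError("pairwise matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def upper_triangle(self) -> np.ndarray:
        """Vectorized strict upper triangle (the Mantel data vector)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def subset(self, ids: Sequence[str]) -> "PairwiseMatrix":
        """Restrict to ``ids`` (kept in the given order)."""
        index = {v: i for i, v in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise ConfigurationError(f"ids not in matrix: {missing}")
        sel = np.array([index[i] for i in ids])
        return PairwiseMatrix(
            ids=list(ids),
            values=self.values[np.ix_(sel, sel)],
            role=self.role,
            metadata=dict(self.metadata),
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        # default float formatting is the shortest round-trip repr: lossless
        df.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path, role: str = "") -> "PairwiseMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id",
                         float_precision="round_trip")
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(), role=role)
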