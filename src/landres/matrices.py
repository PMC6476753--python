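"""Pairwise model matrices consumed by the Mantel tests.

From a transect network these builders produce the competing hypotheses of
the analysis: Euclidean distance (``Dis``, the isolation-by-distance null),
the four elevation-parameter matrices, per-class land-use resistance
(``R_L`` = presumed weight x cell count, optionally with the Euclidean
distance added as a base cost), combined resistance (``Sigma_R_L``), and
binary barrier matrices (``B_L`` = class present on the transect or not).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, LandresError
from .pairwise import PairwiseMatrix
from .rasters import LANDUSE_CODES
from .transects import PairNetwork

ELEVATION_PARAMS = ("mean", "maxdiff", "sd", "cv")
RESISTANCE_BASES = ("none", "add_distance")


class DistanceModelMatrix(PairwiseMatrix):
    """A pairwise hypothesis matrix (Dis, elevation stat, R_L, ΣR_L or B_L)."""


@dataclass(frozen=True)
class ResistanceWeightGrid:
    """The presumed per-cell resistance weights screened for every class."""

    weights: tuple[float, ...] = (2, 5, 25, 50, 100)

    def __post_init__(self) -> None:
        if not self.weights:
            raise ConfigurationError("weight grid must be non-empty")
        if any(w <= 0 for w in self.weights):
            raise ConfigurationError("resistance weights must be strictly positive")
        if any(b <= a for a, b in zip(self.weights, self.weights[1:])):
            raise ConfigurationError("resistance weights must be strictly increasing")


def resolve_class(landuse_class) -> int:
    """Accept a class code (int) or name (str) and return the code."""
    if isinstance(landuse_class, str):
        if landuse_class not in LANDUSE_CODES:
            raise LandresError(f"unknown land-use class {landuse_class!r}")
        return LANDUSE_CODES[landuse_class]
    return int(landuse_class)


def _pair_values(network: PairNetwork, fn) -> np.ndarray:
    ids = network.ids
    index = {v: i for i, v in enumerate(ids)}
    values = np.zeros((len(ids), len(ids)))
    for (a, b), profile in network.profiles.items():
        v = fn(profile)
        i, j = index[a], index[b]
        values[i, j] = values[j, i] = v
    return values


def distance_matrix(network: PairNetwork) -> DistanceModelMatrix:
    """Euclidean-distance matrix Dis — the isolation-by-distance null model."""
    values = _pair_values(network, lambda p: p.euclid_km)
    return DistanceModelMatrix(ids=list(network.ids), values=values, role="Dis")


def elevation_matrix(network: PairNetwork, param: str) -> DistanceModelMatrix:
    """Per-pair elevation statistic matrix (mean, maxdiff, sd or cv)."""
    if param not in ELEVATION_PARAMS:
        raise ConfigurationError(
            f"elevation param must be one of {ELEVATION_PARAMS}, got {param!r}"
        )
    attr = f"elev_{param}"
    if param == "cv":
        bad = [p.pair for p in network.profiles.values()
               if not np.isfinite(p.elev_cv)]
        if bad:
            raise LandresError(
                f"cv undefined (non-positive mean elevation) for pairs: {bad[:5]}"
                + ("..." if len(bad) > 5 else "")
            )
    values = _pair_values(network, lambda p: getattr(p, attr))
    np.fill_diagonal(values, 0.0)
    return DistanceModelMatrix(ids=list(network.ids), values=values,
                               role=f"elev_{param}")


def resistance_matrix(network: PairNetwork, landuse_class, weight: float,
                      resistance_base: str = "add_distance") -> DistanceModelMatrix:
    """Resistance matrix R_L for one land-use class at one presumed weight.

    ``entry = weight x (transect cell count of the class)``; with
    ``resistance_base="add_distance"`` the pair's Euclidean distance is added
    as a base cost, which makes the weight a real (not purely scaling)
    parameter.
    """
    if weight <= 0:
        raise ConfigurationError("resistance weight must be > 0")
    if resistance_base not in RESISTANCE_BASES:
        raise ConfigurationError(
            f"resistance_base must be one of {RESISTANCE_BASES}"
        )
    code = resolve_class(landuse_class)
    if code not in network.class_codes:
        raise LandresError(f"class {landuse_class!r} not in network class set")
    base = (lambda p: p.euclid_km) if resistance_base == "add_distance" else (lambda p: 0.0)
    values = _pair_values(
        network, lambda p: base(p) + weight * p.landuse_counts[code]
    )
    return DistanceModelMatrix(
        ids=list(network.ids), values=values, role="R_L",
        metadata={"class": code, "weight": weight,
                  "resistance_base": resistance_base},
    )


def combined_resistance_matrix(network: PairNetwork,
                               members: Sequence[tuple[object, float]],
                               resistance_base: str = "add_distance"
                               ) -> DistanceModelMatrix:
    """Combined resistance ΣR_L over distinct (class, weight) members.

    In ``add_distance`` mode the Euclidean base cost enters once, so a
    single-member combination equals its own resistance matrix; in ``none``
    mode the result is the plain entrywise sum of the member products.
    """
    if not members:
        raise ConfigurationError("combined resistance needs at least one member")
    codes = [resolve_class(c) for c, _ in members]
    if len(set(codes)) != len(codes):
        raise ConfigurationError(f"duplicate classes in combination: {codes}")
    if resistance_base not in RESISTANCE_BASES:
        raise ConfigurationError(
            f"resistance_base must be one of {RESISTANCE_BASES}"
        )
    base = (lambda p: p.euclid_km) if resistance_base == "add_distance" else (lambda p: 0.0)
    weights = {code: w for code, (_, w) in zip(codes, members)}
    values = _pair_values(
        network,
        lambda p: base(p) + sum(w * p.landuse_counts[c] for c, w in weights.items()),
    )
    return DistanceModelMatrix(
        ids=list(network.ids), values=values, role="Sigma_R_L",
        metadata={"members": sorted(weights.items()),
                  "resistance_base": resistance_base},
    )


def barrier_matrix(network: PairNetwork, landuse_class) -> DistanceModelMatrix:
    """Binary barrier matrix B_L: 1 iff the class occurs on the transect."""
    code = resolve_class(landuse_class)
    if code not in network.class_codes:
        raise LandresError(f"class {landuse_class!r} not in network class set")
    values = _pair_values(network, lambda p: float(p.landuse_presence[code]))
    return DistanceModelMatrix(
        ids=list(network.ids), values=values, role="B_L",
        metadata={"class": code},
    )
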