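"""Random-walk flow analytics on state networks.

Models a trajectory (e.g. a passenger itinerary) as a discrete-time
random walk on a state network.  Three-leg connectivity is the
probability of reaching a destination within three steps with the
destination made absorbing; three-leg displacement is the expected
great-circle distance from the origin after three steps.  Gains of a
concise memory network over the first-order network are reported on a
log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import StateNetwork

__all__ = [
    "WalkMatrix",
    "GeoTable",
    "build_transition_matrix",
    "three_leg_connectivity",
    "three_leg_displacement",
    "haversine",
    "log_gain",
    "load_geo_table",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class WalkMatrix:
    """Row-stochastic transition matrix over state nodes."""

    T: np.ndarray
    states: list[tuple[int, str, int]]  # (state_id, physical, alpha)
    index: dict[int, int]  # state_id -> row
    physical_map: dict[str, list[int]]

    def __post_init__(self) -> None:
        if np.any(self.T < 0):
            raise ValueError("transition probabilities must be nonnegative")
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of T must sum to 1")

    def rows_of(self, physical: str) -> list[int]:
        return [self.index[sid] for sid in self.physical_map[physical]]


@dataclass
class GeoTable:
    """Physical node label -> (latitude, longitude) in degrees."""

    coords: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for label, (lat, lon) in self.coords.items():
            if not (abs(lat) <= 90 and abs(lon) <= 180):
                raise ValueError(f"invalid coordinates for {label!r}: ({lat}, {lon})")

    def __contains__(self, label: str) -> bool:
        return label in self.coords

    def __getitem__(self, label: str) -> tuple[float, float]:
        return self.coords[label]


def load_geo_table(file: str | Path) -> GeoTable:
    """Read a CSV with header ``label,lat,lon``."""
    df = pd.read_csv(file, dtype={"label": str})
    if not {"label", "lat", "lon"} <= set(df.columns):
        raise ValueError("geo CSV must have columns label, lat, lon")
    return GeoTable({row.label: (float(row.lat), float(row.lon)) for row in df.itertuples()})


def build_transition_matrix(net: StateNetwork) -> WalkMatrix:
    """Out-weight-normalized walk matrix; dangling states get unit self-loops."""
    ids = [sid for sid, _, _ in net.states]
    index = {sid: row for row, sid in enumerate(ids)}
    m = len(ids)
    T = np.zeros((m, m))
    for s, t, w in net.edges:
        T[index[s], index[t]] += w
    rowsums = T.sum(axis=1)
    dangling = rowsums <= 0
    T[dangling, :] = 0.0
    T[np.flatnonzero(dangling), np.flatnonzero(dangling)] = 1.0
    rowsums = T.sum(axis=1)
    T = T / rowsums[:, None]
    return WalkMatrix(T=T, states=list(net.states), index=index, physical_map=dict(net.physical_map))


def _single_state_row(walk: WalkMatrix, label: str, role: str) -> int:
    rows = walk.rows_of(label)
    if len(rows) != 1:
        raise ValueError(
            f"{role} {label!r} has {len(rows)} state nodes; connectivity analysis "
            "is restricted to physical nodes with a single state"
        )
    return rows[0]


def three_leg_connectivity(walk: WalkMatrix, o: str, d: str) -> float:
    """Probability of reaching ``d`` from ``o`` in three or fewer steps.

    All states of ``d`` are made absorbing (their rows become unit
    self-loops) and the cube of the modified matrix is read at the
    origin-destination entry, which accumulates arrivals at any step
    up to the third.
    """
    if o == d:
        raise ValueError("origin and destination must differ")
    o_row = _single_state_row(walk, o, "origin")
    d_row = _single_state_row(walk, d, "destination")
    Td = walk.T.copy()
    Td[d_row, :] = 0.0
    Td[d_row, d_row] = 1.0
    return float(np.linalg.matrix_power(Td, 3)[o_row, d_row])


def three_leg_displacement(walk: WalkMatrix, o: str, geo: GeoTable) -> float:
    """Expected great-circle distance (km) from ``o`` after three steps.

    States of the same physical node pool their occupation probability
    before distances are taken.
    """
    o_row = _single_state_row(walk, o, "origin")
    dist3 = np.linalg.matrix_power(walk.T, 3)[o_row]
    pooled: dict[str, float] = {}
    for (sid, phys, _), p in zip(walk.states, dist3):
        if p > 0:
            pooled[phys] = pooled.get(phys, 0.0) + float(p)
    if o not in geo:
        raise KeyError(f"missing coordinates for origin {o!r}")
    missing = sorted(label for label in pooled if label not in geo)
    if missing:
        raise KeyError(f"missing coordinates for reachable nodes: {missing}")
    return sum(p * haversine(geo[o], geo[label]) for label, p in pooled.items())


def haversine(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    for lat, lon in (p1, p2):
        if not (abs(lat) <= 90 and abs(lon) <= 180):
            raise ValueError(f"invalid coordinates ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(math.radians, (*p1, *p2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def log_gain(value_c: float, value_fo: float) -> float:
    """log10 ratio of a concise-network quantity to its first-order value."""
    if value_c <= 0 or value_fo <= 0:
        raise ValueError("gain requires strictly positive values")
    return math.log10(value_c / value_fo)
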