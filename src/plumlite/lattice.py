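"""Shared lat/lon lattice conventions.

All gridded fields live on a regular angular lattice with cell *centres* at
odd multiples of ``resolution/2`` (so a 0.5-degree grid has centres at
0.25, 0.75, ...).  A point belongs to the cell whose half-open interval
``[edge, edge + resolution)`` contains it, in both coordinates.
"""

from __future__ import annotations

import numpy as np

KM_PER_DEGREE = 111.32  # mean meridional arc length
HA_PER_KM2 = 100.0


def centre(index: int | np.ndarray, resolution: float) -> np.ndarray:
    """Coordinate of a cell centre from its integer lattice index."""
    return (np.asarray(index) + 0.5) * resolution


def index_of(coord, resolution: float) -> np.ndarray:
    """Integer lattice index owning a coordinate (half-open convention)."""
    return np.floor(np.asarray(coord, dtype=float) / resolution).astype(int)


def is_on_lattice(coord, resolution: float, tol: float = 1e-9) -> np.ndarray:
    """True where a coordinate sits exactly on a cell centre."""
    r = np.asarray(coord, dtype=float) / resolution - 0.5
    return np.abs(r - np.round(r)) < tol


def cell_area_ha(lat_deg, resolution: float) -> np.ndarray:
    """Area of a lattice cell centred at ``lat_deg``, in hectares.

    Spherical-rectangle approximation: meridional extent is constant, zonal
    extent shrinks with cos(latitude).
    """
    lat = np.asarray(lat_deg, dtype=float)
    side_km = KM_PER_DEGREE * resolution
    return side_km * side_km * np.cos(np.deg2rad(lat)) * HA_PER_KM2
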