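"""Explanatory distance matrices and spatial interpolation.

The linguistic dissimilarity index scores a language pair 0-4 by the deepest
shared level of the 4-level classification (language, subgroup, family,
phylum); great-circle distances use the haversine formula on a 6371 km
sphere; IDW interpolates site statistics onto a lon/lat grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import DataModelError, LabeledMatrix, LanguageHierarchy, PopulationMetadata

EARTH_RADIUS_KM = 6371.0

AGGREGATIONS = ("min", "max", "mean")


def language_pair_distance(a: str, b: str, h: LanguageHierarchy) -> int:
    """0 same language; 1 same subgroup; 2 same family; 3 same phylum; 4 else.

    A null subgroup never matches another subgroup: two distinct languages
    attached directly at the family level score 2.
    """
    if a == b:
        return 0
    sub_a, sub_b = h.subgroup(a), h.subgroup(b)
    if sub_a is not None and sub_a == sub_b:
        return 1
    if h.family(a) == h.family(b):
        return 2
    if h.phylum(a) == h.phylum(b):
        return 3
    return 4


def linguistic_distance_matrix(
    metadata: Sequence[PopulationMetadata],
    hierarchy: LanguageHierarchy,
    aggregation: str = "min",
) -> LabeledMatrix:
    """Site-by-site linguistic dissimilarity (d_LAN), values in {0..4}.

    Multilingual sites are aggregated over all cross-site language pairs;
    the default ``min`` treats any shared language as a communication
    channel (``max`` and ``mean`` are sensitivity options).
    """
    if aggregation not in AGGREGATIONS:
        raise DataModelError(f"aggregation {aggregation!r} not in {AGGREGATIONS}")
    hierarchy.validate(metadata)
    n = len(metadata)
    values = np.zeros((n, n))
    langs = [sorted(m.languages) for m in metadata]
    for i in range(n):
        for j in range(i + 1, n):
            pairs = [
                language_pair_distance(a, b, hierarchy)
                for a in langs[i]
                for b in langs[j]
            ]
            if aggregation == "min":
                d = min(pairs)
            elif aggregation == "max":
                d = max(pairs)
            else:
                d = float(np.mean(pairs))
            values[i, j] = values[j, i] = d
    return LabeledMatrix([m.site for m in metadata], values, kind="linguistic")


def haversine_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (broadcasting)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def greatcircle_matrix(metadata: Sequence[PopulationMetadata]) -> LabeledMatrix:
    """Pairwise great-circle distances among sites, in km (d_GEO)."""
    lat = np.array([m.latitude for m in metadata])
    lon = np.array([m.longitude for m in metadata])
    values = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(values, 0.0)
    return LabeledMatrix([m.site for m in metadata], values, kind="geographic")


def log_distance(d: LabeledMatrix, floor_km: float = 1.0) -> LabeledMatrix:
    """Elementwise ln(max(d, floor)) off the diagonal; diagonal stays 0.

    The floor (default 1 km) guards co-located sites; only off-diagonal
    pairs enter downstream regressions.
    """
    if floor_km <= 0:
        raise DataModelError("floor_km must be positive")
    if (d.values < 0).any():
        raise DataModelError("negative distances cannot be log-transformed")
    values = np.log(np.maximum(d.values, floor_km))
    np.fill_diagonal(values, 0.0)
    return LabeledMatrix(d.labels, values, kind="derived")


@dataclass
class IdwGrid:
    """Gridded IDW interpolation of site values.

    ``values`` is (n_lat, n_lon) with rows ordered north to south for .asc
    export; every interpolated cell lies within the input value range.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    cell_size: float
    power: float
    k_neighbors: int
    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray
    nodata: float = -9999.0

    def to_ascii_grid(self) -> str:
        """ESRI ASCII grid text (rows north to south)."""
        header = (
            f"ncols {self.values.shape[1]}\n"
            f"nrows {self.values.shape[0]}\n"
            f"xllcorner {self.lon_min}\n"
            f"yllcorner {self.lat_min}\n"
            f"cellsize {self.cell_size}\n"
            f"NODATA_value {self.nodata}\n"
        )
        body = "\n".join(
            " ".join(f"{v:.6g}" for v in row) for row in self.values[::-1]
        )
        return header + body + "\n"

    def to_xyz_rows(self) -> list[tuple[float, float, float]]:
        rows = []
        for i, lat in enumerate(self.lats):
            for j, lon in enumerate(self.lons):
                rows.append((lon, lat, float(self.values[i, j])))
        return rows


def idw_interpolate(
    sites: Iterable[tuple[float, float, float]],
    lat_range: tuple[float, float],
    lon_range: tuple[float, float],
    cell_size: float = 1.0,
    power: float = 2.0,
    k_neighbors: int = 12,
) -> IdwGrid:
    """Inverse-distance-weighted interpolation of (lat, lon, value) sites.

    Each cell centre takes the d^(-power) weighted mean of its k nearest
    sites (great-circle distance); a cell within 1e-6 km of a site takes
    that site's value exactly.
    """
    pts = list(sites)
    if not pts:
        raise DataModelError("IDW needs at least one site")
    if power <= 0:
        raise DataModelError("IDW power must be positive")
    slat = np.array([p[0] for p in pts])
    slon = np.array([p[1] for p in pts])
    sval = np.array([p[2] for p in pts])
    k = min(k_neighbors, len(pts))
    lats = np.arange(lat_range[0] + cell_size / 2.0, lat_range[1], cell_size)
    lons = np.arange(lon_range[0] + cell_size / 2.0, lon_range[1], cell_size)
    grid = np.empty((lats.size, lons.size))
    for i, lat in enumerate(lats):
        d = haversine_km(lat, lons[:, None], slat[None, :], slon[None, :])
        # k nearest sites per cell in this row
        idx = np.argpartition(d, k - 1, axis=1)[:, :k]
        dk = np.take_along_axis(d, idx, axis=1)
        vk = sval[idx]
        exact = dk.min(axis=1) < 1e-6
        with np.errstate(divide="ignore", invalid="ignore"):
            w = dk ** (-power)
            smooth = (w * vk).sum(axis=1) / w.sum(axis=1)
        row = np.where(exact, vk[np.arange(lons.size), dk.argmin(axis=1)], smooth)
        grid[i] = row
    return IdwGrid(
        lat_min=lat_range[0],
        lat_max=lat_range[1],
        lon_min=lon_range[0],
        lon_max=lon_range[1],
        cell_size=cell_size,
        power=power,
        k_neighbors=k,
        lats=lats,
        lons=lons,
        values=grid,
    )
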