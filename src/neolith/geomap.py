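"""Geographic interpolation of genetic distances (gene-geography surfaces).

Nei distances from a reference (ancient) sample to geolocated modern
populations are interpolated onto a regular latitude/longitude grid with
inverse-distance weighting (IDW) over great-circle distances, then binned
into display classes: a run of fixed-width "green" intervals near zero and
geometrically widening intervals towards the far ("orange") end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import nei_distance
from .haplotypes import HaplogroupScheme, PopulationSample, hg_frequency_vector

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
#: Default grid: 0.5 degree cells over Europe and the Near East.
DEFAULT_BOUNDS = (30.0, 75.0, -15.0, 65.0)  # lat_min, lat_max, lon_min, lon_max
DEFAULT_CELL = 0.5


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (vectorized over either argument)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def reference_distances(
    reference: PopulationSample,
    populations: list[PopulationSample],
    scheme: HaplogroupScheme | None = None,
) -> pd.DataFrame:
    """Nei distance from the reference to each geolocated population.

    One row per population (population, lat, lon, distance); populations
    without coordinates are excluded with a warning.
    """
    ref_freq = hg_frequency_vector(reference, scheme).to_numpy()
    rows = []
    for pop in populations:
        if pop.coordinates is None:
            logger.warning("population %s has no coordinates; excluded", pop.name)
            continue
        freq = hg_frequency_vector(pop, scheme).to_numpy()
        rows.append({
            "population": pop.name,
            "lat": pop.coordinates[0],
            "lon": pop.coordinates[1],
            "distance": nei_distance(ref_freq, freq),
        })
    return pd.DataFrame(rows)


@dataclass
class GeoGrid:
    """Interpolated surface on a regular lat/lon grid.

    ``values`` is (n_lat, n_lon) with NaN on masked cells (no data point
    within the search radius); latitudes ascend along axis 0.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    cell_size: float
    values: np.ndarray
    method: str = "IDW"

    @property
    def lats(self) -> np.ndarray:
        return self.lat_min + self.cell_size * (np.arange(self.values.shape[0]) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + self.cell_size * (np.arange(self.values.shape[1]) + 0.5)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# method={self.method} bounds={self.lat_min},{self.lat_max},"
                f"{self.lon_min},{self.lon_max} cell={self.cell_size}\n"
            )
            pd.DataFrame(self.values, index=self.lats, columns=self.lons).to_csv(
                fh, sep="\t"
            )


def interpolate_surface(
    points: pd.DataFrame,
    bounds: tuple[float, float, float, float] = DEFAULT_BOUNDS,
    cell_size: float = DEFAULT_CELL,
    power: float = 2.0,
    search_radius_km: float = 2000.0,
    mask: np.ndarray | None = None,
) -> GeoGrid:
    """Inverse-distance-weighted surface from (lat, lon, distance) points.

    The cell containing a data point takes that point's value exactly
    (nearest point wins on ties); other cells average the values of points
    within ``search_radius_km``, weighted by great-circle distance to the
    ``-power``; cells with an empty neighborhood are NaN-masked.  An optional
    boolean ``mask`` (True = masked, e.g. sea) is applied on top.
    """
    if points.empty:
        raise ValueError("need >= 1 data point")
    lat_min, lat_max, lon_min, lon_max = bounds
    n_lat = int(round((lat_max - lat_min) / cell_size))
    n_lon = int(round((lon_max - lon_min) / cell_size))
    lats = lat_min + cell_size * (np.arange(n_lat) + 0.5)
    lons = lon_min + cell_size * (np.arange(n_lon) + 0.5)
    plat = points["lat"].to_numpy()
    plon = points["lon"].to_numpy()
    pval = points["distance"].to_numpy(dtype=float)

    grid_lat = np.repeat(lats, n_lon)
    grid_lon = np.tile(lons, n_lat)
    # (cells, points) great-circle distances
    d = haversine_km(grid_lat[:, None], grid_lon[:, None], plat[None, :],
                     plon[None, :])
    with np.errstate(divide="ignore"):
        w = np.where(d <= search_radius_km, d**-power, 0.0)
    values = np.full(n_lat * n_lon, np.nan)
    wsum = w.sum(axis=1)
    ok = wsum > 0
    # a cell center coinciding with a data point yields an infinite weight;
    # the exactness pass below overwrites that cell with the point's value
    with np.errstate(invalid="ignore"):
        values[ok] = (w[ok] * pval[None, :]).sum(axis=1) / wsum[ok]

    # exactness: the cell containing a data point takes that point's value
    for k in range(len(pval)):
        i = int((plat[k] - lat_min) // cell_size)
        j = int((plon[k] - lon_min) // cell_size)
        if 0 <= i < n_lat and 0 <= j < n_lon:
            cell = i * n_lon + j
            values[cell] = pval[k]

    grid_values = values.reshape(n_lat, n_lon)
    if mask is not None:
        grid_values = np.where(mask, np.nan, grid_values)
    return GeoGrid(lat_min, lat_max, lon_min, lon_max, cell_size, grid_values)


def classify_intervals(
    grid: GeoGrid, green_step: float = 0.02, n_green: int = 5, widen: float = 1.6
) -> tuple[np.ndarray, pd.DataFrame]:
    """Bin the surface into display classes.

    The first ``n_green`` classes have fixed width ``green_step`` starting at
    0; beyond that, class widths grow geometrically by ``widen`` until the
    maximum value is covered.  Returns (class raster with -1 for masked
    cells, legend of breakpoints).
    """
    if green_step <= 0:
        raise ValueError("green_step must be positive")
    finite = grid.values[np.isfinite(grid.values)]
    vmax = float(finite.max()) if finite.size else 0.0
    breaks = [green_step * i for i in range(1, n_green + 1)]
    width = green_step * widen
    while breaks[-1] < vmax:
        breaks.append(breaks[-1] + width)
        width *= widen
    edges = np.array(breaks)
    classes = np.full(grid.values.shape, -1, dtype=int)
    ok = np.isfinite(grid.values)
    classes[ok] = np.digitize(grid.values[ok], edges, right=False) + 1
    legend = pd.DataFrame({
        "class": np.arange(1, len(edges) + 1),
        "lower": np.concatenate([[0.0], edges[:-1]]),
        "upper": edges,
    })
    return classes, legend


def plot_surface(grid: GeoGrid, points: pd.DataFrame | None = None, path=None):
    """Render the surface as an equirectangular heatmap (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 5))
    im = ax.imshow(
        grid.values, origin="lower",
        extent=(grid.lon_min, grid.lon_max, grid.lat_min, grid.lat_max),
        cmap="RdYlGn_r", aspect="auto",
    )
    if points is not None:
        ax.scatter(points["lon"], points["lat"], s=8, c="black")
    fig.colorbar(im, ax=ax, label="genetic distance")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
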