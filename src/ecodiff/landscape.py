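"""Spatial domain for nearshore diffusion models.

A :class:`Landscape` is a rectangular raster of square cells holding a
water/land mask and the covariate rasters that drive motility and density
dependence: a shallow-depth indicator, distance to shore, seafloor slope,
shoreline complexity, cumulative swimming distance to towns, and two
management-area indicators (a protected bay and commercial-fisheries
closures).  Conventions fixed here and used everywhere else in the package:
row-major 0-based indices, cell-centre coordinates, distances in metres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.ndimage import binary_dilation
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

#: Covariates that are {0,1} indicators and are never standardized.
INDICATOR_COVARIATES = ("depth_ind", "glba_ind", "fish_ind")

#: Canonical covariate names entering the motility / density-dependence
#: log-linear predictors, in model order.
COVARIATE_NAMES = (
    "depth_ind",
    "dist_shore",
    "slope",
    "shore_complex",
    "town_dist",
    "glba_ind",
    "fish_ind",
)

_FOUR_NEIGHBORS = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Epicenter:
    """A release site seeding one Gaussian kernel of the initial intensity.

    Parameters
    ----------
    row, col
        Grid indices of the release site (must be a water cell).
    theta
        Abundance scale: expected number of individuals contributed by this
        site's kernel (the kernel is normalized over the water domain).
    kappa_m
        Kernel dispersion (metres); controls the initial isotropic spread.
    label
        Free-text site name.
    """

    row: int
    col: int
    theta: float
    kappa_m: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError(f"epicenter {self.label!r}: theta must be > 0")
        if not self.kappa_m > 0:
            raise ValueError(f"epicenter {self.label!r}: kappa must be > 0")


@dataclass
class Landscape:
    """Gridded study domain with covariates.

    ``covariates`` maps covariate name to a 2-D float raster; values are
    meaningful on water cells (land cells may hold anything, by convention 0
    or NaN).  ``standardization`` records the (mean, sd) applied to each
    non-indicator covariate so the identical scaling can be reused.
    """

    cell_size_m: float
    water_mask: np.ndarray
    covariates: dict[str, np.ndarray]
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    towns: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.water_mask = np.asarray(self.water_mask, dtype=bool)
        shp = self.water_mask.shape
        for name, ras in self.covariates.items():
            ras = np.asarray(ras, dtype=float)
            if ras.shape != shp:
                raise ValueError(f"covariate {name!r} shape {ras.shape} != {shp}")
            if not np.all(np.isfinite(ras[self.water_mask])):
                raise ValueError(f"covariate {name!r} non-finite on water cells")
            self.covariates[name] = ras

    # -- basic geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.water_mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.water_mask.shape[1]

    @property
    def area_per_cell(self) -> float:
        return self.cell_size_m**2

    @property
    def n_water(self) -> int:
        return int(self.water_mask.sum())

    @property
    def boundary_mask(self) -> np.ndarray:
        """Water cells adjacent (4-neighbourhood) to land or the array edge.

        Zero-flux conditions apply across every water/non-water interface;
        this mask is informational (maps, diagnostics).
        """
        land = ~self.water_mask
        padded = np.pad(land, 1, constant_values=True)
        near_edge = binary_dilation(padded, structure=_FOUR_NEIGHBORS)[1:-1, 1:-1]
        return self.water_mask & near_edge

    def water_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.water_mask)

    # -- design matrix ---------------------------------------------------
    def motility_design(self) -> np.ndarray:
        """(n_water, 8) design matrix for the log-motility predictor.

        Columns: 1, depth_ind, dist_shore, slope*depth_ind, shore_complex,
        town_dist, glba_ind, fish_ind.  Slope enters only through its
        interaction with the shallow-depth indicator.
        """
        w = self.water_mask
        c = self.covariates
        cols = [
            np.ones(w.sum()),
            c["depth_ind"][w],
            c["dist_shore"][w],
            c["slope"][w] * c["depth_ind"][w],
            c["shore_complex"][w],
            c["town_dist"][w],
            c["glba_ind"][w],
            c["fish_ind"][w],
        ]
        return np.column_stack(cols)

    def capacity_design(self) -> np.ndarray:
        """(n_water, 3) design matrix for log density dependence: 1, glba, fish."""
        w = self.water_mask
        c = self.covariates
        return np.column_stack([np.ones(w.sum()), c["glba_ind"][w], c["fish_ind"][w]])

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the landscape as CSV grids plus a YAML sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "water_mask.csv", self.water_mask.astype(int), fmt="%d", delimiter=",")
        for name, ras in self.covariates.items():
            np.savetxt(path / f"cov_{name}.csv", ras, delimiter=",")
        meta = {
            "cell_size_m": float(self.cell_size_m),
            "covariates": sorted(self.covariates),
            "standardization": {k: [float(v[0]), float(v[1])] for k, v in self.standardization.items()},
            "towns": [[int(r), int(c)] for r, c in self.towns],
        }
        (path / "landscape.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path: str | Path) -> "Landscape":
        path = Path(path)
        meta = yaml.safe_load((path / "landscape.yaml").read_text())
        water = np.loadtxt(path / "water_mask.csv", delimiter=",").astype(bool)
        covs = {
            name: np.loadtxt(path / f"cov_{name}.csv", delimiter=",").reshape(water.shape)
            for name in meta["covariates"]
        }
        return cls(
            cell_size_m=meta["cell_size_m"],
            water_mask=water,
            covariates=covs,
            standardization={k: (v[0], v[1]) for k, v in meta.get("standardization", {}).items()},
            towns=[tuple(t) for t in meta.get("towns", [])],
        )


# ---------------------------------------------------------------------------
# covariate construction
# ---------------------------------------------------------------------------

def shoreline_cells(water_mask: np.ndarray) -> np.ndarray:
    """Water cells with at least one land cell among their 4-neighbours.

    The array edge does not count as land: an all-water raster has no
    shoreline.  (The alternative convention — land cells adjacent to water —
    is available via ``shoreline_cells(~mask)`` on the complement.)
    """
    water = np.asarray(water_mask, dtype=bool)
    land = ~water
    padded = np.pad(land, 1, constant_values=False)
    near_land = binary_dilation(padded, structure=_FOUR_NEIGHBORS)[1:-1, 1:-1]
    return water & near_land


def shoreline_complexity(
    water_mask: np.ndarray, radius_m: float, cell_size_m: float
) -> np.ndarray:
    """Count shoreline cells within ``radius_m`` of each cell centre.

    The neighbourhood is the Euclidean disc of centre-to-centre distance
    ``radius_m``; straighter coastlines give lower counts, convoluted
    fjord-like coastlines higher counts.

    Raises
    ------
    ValueError
        If the radius is smaller than one cell width (the disc would
        contain nothing beyond the cell itself).
    """
    if radius_m < cell_size_m:
        raise ValueError(
            f"radius {radius_m} m smaller than one cell ({cell_size_m} m): neighborhood empty"
        )
    shore = shoreline_cells(water_mask).astype(float)
    k = int(np.floor(radius_m / cell_size_m))
    offs = np.arange(-k, k + 1)
    di, dj = np.meshgrid(offs, offs, indexing="ij")
    disc = (np.hypot(di, dj) * cell_size_m <= radius_m).astype(float)
    from scipy.ndimage import convolve

    out = convolve(shore, disc, mode="constant", cval=0.0)
    return np.rint(out)


def _water_graph(water_mask: np.ndarray, cell_size_m: float) -> tuple[coo_matrix, np.ndarray]:
    """8-connected weighted graph over water cells (diagonals cost sqrt(2)*h)."""
    water = np.asarray(water_mask, dtype=bool)
    nr, nc = water.shape
    idx = -np.ones(water.shape, dtype=np.int64)
    idx[water] = np.arange(water.sum())
    rows, cols, wts = [], [], []
    steps = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]
    # explicit loop construction (clarity over speed; grids here are small)
    for i in range(nr):
        for j in range(nc):
            if not water[i, j]:
                continue
            for di, dj, w in steps:
                ii, jj = i + di, j + dj
                if 0 <= ii < nr and 0 <= jj < nc and water[ii, jj]:
                    rows.append(idx[i, j])
                    cols.append(idx[ii, jj])
                    wts.append(w * cell_size_m)
    n = int(water.sum())
    g = coo_matrix((wts, (rows, cols)), shape=(n, n))
    return g, idx


def snap_to_water(water_mask: np.ndarray, loc: tuple[int, int]) -> tuple[int, int]:
    """Nearest water cell (Euclidean, centre-to-centre) to a grid location."""
    water = np.asarray(water_mask, dtype=bool)
    if water[loc]:
        return (int(loc[0]), int(loc[1]))
    if not water.any():
        raise ValueError("no water cells on the raster")
    wi, wj = np.nonzero(water)
    d2 = (wi - loc[0]) ** 2 + (wj - loc[1]) ** 2
    k = int(np.argmin(d2))
    return (int(wi[k]), int(wj[k]))


def cumulative_town_distance(
    water_mask: np.ndarray,
    towns: Sequence[tuple[int, int]],
    cell_size_m: float,
) -> np.ndarray:
    """Sum over towns of the shortest swimmable path to each water cell.

    Paths move through water cells with 8-connectivity; diagonal steps cost
    sqrt(2) x cell size.  Towns on land are snapped to the nearest water
    cell.  Water cells unreachable from a town take that town's maximum
    finite in-domain distance, keeping later standardization finite.
    """
    towns = list(towns)
    if not towns:
        raise ValueError("at least one town is required")
    water = np.asarray(water_mask, dtype=bool)
    g, idx = _water_graph(water, cell_size_m)
    sources = [idx[snap_to_water(water, t)] for t in towns]
    dist = _csgraph_dijkstra(g.tocsr(), directed=False, indices=sources)
    # unreachable cells: per-town max finite distance
    for k in range(dist.shape[0]):
        row = dist[k]
        finite = np.isfinite(row)
        if not finite.all():
            row[~finite] = row[finite].max()
    total = dist.sum(axis=0)
    out = np.zeros(water.shape, dtype=float)
    out[water] = total
    return out


def standardize_covariates(landscape: Landscape) -> Landscape:
    """Centre and scale non-indicator covariates to mean 0, sd 1 over water.

    Indicator covariates are returned bit-identical.  The (mean, sd) pairs
    are recorded on the returned landscape for exact reuse; covariates that
    already carry a recorded standardization are re-scaled from their raw
    values is *not* supported — apply this once to raw covariates (the
    operation is idempotent up to floating tolerance).
    """
    if landscape.n_water < 2:
        raise ValueError("need at least 2 water cells to standardize")
    w = landscape.water_mask
    new_covs: dict[str, np.ndarray] = {}
    stats: dict[str, tuple[float, float]] = {}
    for name, ras in landscape.covariates.items():
        if name in INDICATOR_COVARIATES:
            new_covs[name] = ras
            continue
        mu = float(ras[w].mean())
        sd = float(ras[w].std(ddof=0))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"covariate {name!r} has zero variance over water cells")
        scaled = np.where(w, (ras - mu) / sd, 0.0)
        new_covs[name] = scaled
        stats[name] = (mu, sd)
    return dataclasses.replace(landscape, covariates=new_covs, standardization=stats)


def destandardize(landscape: Landscape) -> Landscape:
    """Invert :func:`standardize_covariates` using the recorded constants."""
    covs = {}
    for name, ras in landscape.covariates.items():
        if name in landscape.standardization:
            mu, sd = landscape.standardization[name]
            covs[name] = np.where(landscape.water_mask, ras * sd + mu, 0.0)
        else:
            covs[name] = ras
    return dataclasses.replace(landscape, covariates=covs, standardization={})
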