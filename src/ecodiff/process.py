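"""Logistic ecological diffusion: fields, homogenization, propagation.

The process model is the PDE

    d/dt lambda(s,t) = laplacian( delta(s) * lambda(s,t) )
                       + gamma * lambda(s,t) * (1 - lambda(s,t)/K(s)),

with motility delta(s) (m^2/yr, inversely proportional to residence time)
and local density dependence K(s), both log-linear in landscape covariates,
and an initial condition that is a sum of Gaussian kernels centred on the
release epicenters.  Intensities lambda and capacities K are expressed per
fine grid cell (the fine cell is the areal integration unit), so the total
expected abundance is a plain sum over water cells.

The solver works on the substituted state c = delta * lambda.  On the fine
grid the zero-flux (reflective) discretization is

    d lambda_i / dt = sum_{j ~ i, water} (c_j - c_i) / a^2,

where a is the cell size; missing neighbours (land, offshore boundary, array
edge) contribute nothing, which is the mirror ghost-cell Neumann condition.
Homogenization coarsens by a factor 1/epsilon: each coarse cell carries the
harmonic mean delta_bar of its fine-cell motilities and the arithmetic mean
reaction coefficient avg(1/(delta*K)), and the same flux form is applied
between coarse water cells.  Because fluxes are antisymmetric, total
abundance is conserved to rounding when gamma = 0, for any mix of partial
land/water coarse cells.  Time stepping is backward-Euler for diffusion
(unconditionally stable; the propagator is a nonnegative M-matrix inverse,
so the state stays nonnegative) followed by an exact per-cell logistic
reaction step; a forward-Euler reaction scheme is available for
order-of-accuracy experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from ._kernels import run_dense, run_sparse
from .landscape import Epicenter, Landscape

DAYS_PER_YEAR = 365.0

# Above this many coarse water cells the solver switches from a precomputed
# dense propagator (fast matvec loop) to a sparse LU factorization.
DENSE_LIMIT = 1500


@dataclass
class ProcessParams:
    """All parameters of the growth-and-spread process.

    beta : 8 log-motility coefficients (intercept, depth, distance to shore,
        slope x depth, shoreline complexity, town distance, protected bay,
        fisheries closures)
    alpha : 3 log density-dependence coefficients (intercept, protected bay,
        fisheries closures)
    gamma : intrinsic growth rate, per year
    epicenters : release sites (theta_j, kappa_j, d_j)
    """

    beta: np.ndarray
    alpha: np.ndarray
    gamma: float
    epicenters: list[Epicenter]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.beta.shape != (8,):
            raise ValueError("beta must have 8 coefficients")
        if self.alpha.shape != (3,):
            raise ValueError("alpha must have 3 coefficients")
        if not (np.isfinite(self.beta).all() and np.isfinite(self.alpha).all()):
            raise ValueError("non-finite coefficients")
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError("gamma must be positive and finite")
        if not self.epicenters:
            raise ValueError("at least one epicenter required")

    @property
    def theta(self) -> np.ndarray:
        return np.array([e.theta for e in self.epicenters])

    @property
    def kappa_m(self) -> np.ndarray:
        return np.array([e.kappa_m for e in self.epicenters])


_MAX_LOG = 700.0  # exp overflow guard


def _field_from_design(landscape: Landscape, X: np.ndarray, coef: np.ndarray, what: str) -> np.ndarray:
    eta = X @ np.asarray(coef, dtype=float)
    if eta.max(initial=-np.inf) > _MAX_LOG:
        k = int(np.argmax(eta))
        wi, wj = landscape.water_indices()
        raise ValueError(
            f"{what}: exp overflow at cell ({wi[k]}, {wj[k]}), linear predictor {eta[k]:.2f}"
        )
    out = np.full(landscape.water_mask.shape, np.nan)
    out[landscape.water_mask] = np.exp(eta)
    return out


def motility_field(landscape: Landscape, beta: Sequence[float]) -> np.ndarray:
    """Motility raster delta(s) = exp(X beta), m^2/yr; NaN on land.

    Covariates must already be standardized (indicators excepted); slope
    enters only through its interaction with the shallow-depth indicator.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (8,):
        raise ValueError("beta must have 8 coefficients")
    return _field_from_design(landscape, landscape.motility_design(), beta, "motility_field")


def carrying_capacity_field(landscape: Landscape, alpha: Sequence[float]) -> np.ndarray:
    """Density-dependence raster K(s) = exp(alpha0 + alpha1 glba + alpha2 fish),
    expected individuals per fine cell at local equilibrium; NaN on land."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (3,):
        raise ValueError("alpha must have 3 coefficients")
    return _field_from_design(landscape, landscape.capacity_design(), alpha, "carrying_capacity_field")


def initial_intensity(landscape: Landscape, epicenters: Sequence[Epicenter]) -> np.ndarray:
    """Initial intensity surface: sum of water-normalized Gaussian kernels.

    Each epicenter contributes theta_j * k_j(s) / Z_j with
    k_j(s) = exp(-||s - d_j||^2 / kappa_j^2) and Z_j the sum of k_j over the
    water domain, so the total initial abundance is exactly sum_j theta_j.
    Returns a per-cell raster, zero on land.
    """
    water = landscape.water_mask
    if not epicenters:
        raise ValueError("at least one epicenter required")
    wi, wj = landscape.water_indices()
    a = landscape.cell_size_m
    lam0 = np.zeros(water.shape, dtype=float)
    for e in epicenters:
        if not water[e.row, e.col]:
            raise ValueError(f"epicenter {e.label!r} at ({e.row},{e.col}) is not on water")
        d2 = ((wi - e.row) ** 2 + (wj - e.col) ** 2) * a**2
        kern = np.exp(-d2 / e.kappa_m**2)
        z = kern.sum()
        if not z > 0:
            raise ValueError(f"epicenter {e.label!r}: kernel numerically zero over water")
        lam0[wi, wj] += e.theta * kern / z
    return lam0


# ---------------------------------------------------------------------------
# homogenization
# ---------------------------------------------------------------------------


class GridOperator:
    """Fine-to-coarse structure reused across solves.

    Precomputes, for a given water mask and coarsening factor: the map from
    fine water cells to coarse water cells, per-coarse fine-water counts,
    the sparse aggregation matrix, and the flux graph Laplacian between
    4-adjacent coarse water cells.
    """

    def __init__(self, water_mask: np.ndarray, cell_size_m: float, epsilon: float):
        inv = 1.0 / epsilon
        factor = int(round(inv))
        if abs(inv - factor) > 1e-9 or factor < 1:
            raise ValueError("1/epsilon must be a positive integer")
        water = np.asarray(water_mask, dtype=bool)
        nr, nc = water.shape
        pr = (-nr) % factor
        pc = (-nc) % factor
        padded = np.pad(water, ((0, pr), (0, pc)), constant_values=False)
        ncr, ncc = padded.shape[0] // factor, padded.shape[1] // factor

        self.epsilon = float(epsilon)
        self.factor = factor
        self.cell_size_m = float(cell_size_m)
        self.fine_shape = water.shape
        self.water_mask = water
        self.coarse_shape = (ncr, ncc)

        # coarse cell id of every fine cell
        fi, fj = np.nonzero(water)
        ci = fi // factor
        cj = fj // factor
        counts = np.zeros((ncr, ncc), dtype=np.int64)
        np.add.at(counts, (ci, cj), 1)
        self.n_fine_2d = counts
        self.coarse_water_mask = counts > 0
        cw_flat_ids = -np.ones((ncr, ncc), dtype=np.int64)
        cw_flat_ids[self.coarse_water_mask] = np.arange(self.coarse_water_mask.sum())
        self.coarse_ids_2d = cw_flat_ids
        self.n_coarse = int(self.coarse_water_mask.sum())
        self.coarse_of_fine = cw_flat_ids[ci, cj]  # (n_water,)
        self.n_fine = counts[self.coarse_water_mask].astype(float)  # (n_coarse,)

        n_water = fi.size
        self.agg = sp.csr_matrix(
            (np.ones(n_water), (self.coarse_of_fine, np.arange(n_water))),
            shape=(self.n_coarse, n_water),
        )

        # graph Laplacian among 4-adjacent coarse water cells (unit weights)
        rows, cols = [], []
        cwm = self.coarse_water_mask
        for di, dj in ((0, 1), (1, 0)):
            src = cwm[: ncr - di, : ncc - dj] & cwm[di:, dj:]
            si, sj = np.nonzero(src)
            a_id = cw_flat_ids[si, sj]
            b_id = cw_flat_ids[si + di, sj + dj]
            rows.extend([a_id, b_id])
            cols.extend([b_id, a_id])
        if rows:
            rows = np.concatenate(rows)
            cols = np.concatenate(cols)
            adj = sp.csr_matrix(
                (np.ones(rows.size), (rows, cols)), shape=(self.n_coarse, self.n_coarse)
            )
        else:
            adj = sp.csr_matrix((self.n_coarse, self.n_coarse))
        deg = np.asarray(adj.sum(axis=1)).ravel()
        self.laplacian = (adj - sp.diags(deg)).tocsr()
        # dense copy for the small-grid fast path (propagator precomputation)
        self.laplacian_dense = self.laplacian.toarray() if self.n_coarse <= DENSE_LIMIT else None

    def to_coarse_2d(self, vec: np.ndarray, fill: float = np.nan) -> np.ndarray:
        out = np.full(self.coarse_shape, fill)
        out[self.coarse_water_mask] = vec
        return out


@dataclass
class HomogenizedGrid:
    """Coarse-scale representation of the diffusion operator.

    delta_bar is the harmonic mean of fine motilities within each coarse
    cell; reaction_coef the arithmetic mean of 1/(delta*K).  Fine-scale
    delta is retained for downscaling the coarse solution
    (lambda_fine = c_coarse / delta_fine).
    """

    op: GridOperator
    delta_bar: np.ndarray  # (n_coarse,)
    reaction_coef: np.ndarray  # (n_coarse,)
    delta_fine: np.ndarray  # (n_water,)
    capacity_fine: np.ndarray  # (n_water,)

    @property
    def epsilon(self) -> float:
        return self.op.epsilon

    @property
    def coarse_cell_size_m(self) -> float:
        return self.op.cell_size_m * self.op.factor

    @property
    def coarse_water_mask(self) -> np.ndarray:
        return self.op.coarse_water_mask

    @property
    def delta_bar_2d(self) -> np.ndarray:
        return self.op.to_coarse_2d(self.delta_bar)

    @property
    def reaction_coef_2d(self) -> np.ndarray:
        return self.op.to_coarse_2d(self.reaction_coef)


def coarsen_fields(op: GridOperator, delta_w: np.ndarray, K_w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Homogenized coefficients from fine water-cell vectors."""
    inv_delta = 1.0 / delta_w
    delta_bar = op.n_fine / (op.agg @ inv_delta)
    reaction = (op.agg @ (inv_delta / K_w)) / op.n_fine
    return delta_bar, reaction


def homogenize(
    delta: np.ndarray,
    K: np.ndarray,
    epsilon: float,
    water_mask: np.ndarray | None = None,
    cell_size_m: float = 400.0,
) -> HomogenizedGrid:
    """Coarsen fine-scale motility and capacity rasters by 1/epsilon.

    Coarse cells with no fine water cells are coarse land.  Raster
    dimensions not divisible by 1/epsilon are padded with land.
    """
    delta = np.asarray(delta, dtype=float)
    K = np.asarray(K, dtype=float)
    if water_mask is None:
        water_mask = np.isfinite(delta) & (delta > 0)
    op = GridOperator(water_mask, cell_size_m, epsilon)
    delta_w = delta[op.water_mask]
    K_w = K[op.water_mask]
    if not (np.all(delta_w > 0) and np.all(np.isfinite(delta_w))):
        raise ValueError("delta must be positive and finite on water cells")
    if not (np.all(K_w > 0) and np.all(np.isfinite(K_w))):
        raise ValueError("K must be positive and finite on water cells")
    delta_bar, reaction = coarsen_fields(op, delta_w, K_w)
    return HomogenizedGrid(op=op, delta_bar=delta_bar, reaction_coef=reaction,
                           delta_fine=delta_w, capacity_fine=K_w)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


@dataclass
class IntensitySeries:
    """Yearly intensity snapshots on fine and coarse grids.

    lambda_fine[t] is the expected abundance per fine cell (zero on land);
    lambda_coarse[t] is the coarse solver state expressed as mean abundance
    per fine-cell-equivalent within each coarse water cell.
    """

    years: np.ndarray
    lambda_fine: np.ndarray  # (n_years, nr, nc)
    lambda_coarse: np.ndarray  # (n_years, ncr, ncc)
    dt_days: float
    water_mask: np.ndarray = field(repr=False, default=None)

    def total_abundance_intensity(self) -> np.ndarray:
        """Sum of lambda over water cells, one value per stored year."""
        return self.lambda_fine.reshape(self.lambda_fine.shape[0], -1).sum(axis=1)

    def year_index(self, year: int) -> int:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise ValueError(f"year {year} not stored (have {self.years.tolist()})")
        return int(idx[0])


def cell_intensity(series: IntensitySeries, cell: tuple[int, int], year: int) -> float:
    """Expected abundance in one fine water cell at one stored year.

    The fine cell is the integration unit of the continuous intensity, so
    this is a direct lookup of the cell-integrated lambda_{i,t}.
    """
    if series.water_mask is not None and not series.water_mask[cell]:
        raise ValueError(f"cell {cell} is not a water cell")
    t = series.year_index(year)
    return float(series.lambda_fine[t][cell])


class DiffusionSolver:
    """Backward-Euler / exact-logistic stepper on a homogenized grid.

    Built once per grid structure; :meth:`solve` accepts per-solve fields so
    MCMC can re-solve cheaply under proposed parameters.  For small coarse
    grids the backward-Euler propagator is precomputed as a dense matrix and
    the stepping loop is numba-compiled; larger grids use a sparse LU
    factorization.
    """

    def __init__(self, op: GridOperator, dt_days: float = 1.0, scheme: str = "exact"):
        if dt_days <= 0:
            raise ValueError("dt_days must be positive")
        if scheme not in ("exact", "euler"):
            raise ValueError("scheme must be 'exact' or 'euler'")
        self.op = op
        self.dt_days = float(dt_days)
        self.steps_per_year = max(1, int(round(DAYS_PER_YEAR / dt_days)))
        self.dt_years = 1.0 / self.steps_per_year
        self.scheme = scheme

    def solve_coarse(
        self,
        delta_bar: np.ndarray,
        reaction: np.ndarray,
        c0: np.ndarray,
        gamma: float,
        n_years: int,
    ) -> np.ndarray:
        """Advance c = delta*lambda; returns (n_years+1, n_coarse) yearly snapshots."""
        op = self.op
        a2 = op.cell_size_m**2
        d = delta_bar / (op.n_fine * a2)  # per-year rate scale
        g = float(np.exp(gamma * self.dt_years))
        gamma_dt = gamma * self.dt_years
        euler = self.scheme == "euler"
        if op.n_coarse <= DENSE_LIMIT:
            A = -self.dt_years * d[:, None] * op.laplacian_dense
            np.fill_diagonal(A, A.diagonal() + 1.0)
            M = np.linalg.inv(A)
            out = run_dense(M, c0, reaction, g, gamma_dt, self.steps_per_year, n_years, euler)
        else:
            A = sp.identity(op.n_coarse, format="csr") - self.dt_years * sp.diags(d) @ op.laplacian
            lu = splu(A.tocsc())
            out = run_sparse(lu.solve, c0, reaction, g, gamma_dt, self.steps_per_year, n_years, euler)
        if not np.all(np.isfinite(out)):
            bad = int(np.nonzero(~np.isfinite(out).all(axis=1))[0][0])
            raise FloatingPointError(f"non-finite state at year index {bad}")
        if out.min() < -1e-10:
            bad = int(np.nonzero((out < -1e-10).any(axis=1))[0][0])
            raise FloatingPointError(f"negative state beyond tolerance at year index {bad}")
        np.maximum(out, 0.0, out=out)
        return out


def propagate(
    initial: np.ndarray,
    hom: HomogenizedGrid,
    gamma: float,
    years: Sequence[int],
    dt_days: float = 1.0,
    scheme: str = "exact",
) -> IntensitySeries:
    """Integrate the logistic ecological diffusion PDE.

    Parameters
    ----------
    initial
        Fine-grid per-cell intensity at year 0 (nonnegative; zero on land).
    hom
        Homogenized grid from :func:`homogenize`.
    gamma
        Intrinsic growth rate per year (>= 0; zero gives pure diffusion).
    years
        Integer year offsets (>= 0) at which to store snapshots.
    dt_days
        Time step of the solver, in days.
    """
    op = hom.op
    initial = np.asarray(initial, dtype=float)
    if initial.shape != op.fine_shape:
        raise ValueError("initial raster shape mismatch")
    if initial.min() < 0:
        raise ValueError("initial intensity must be nonnegative")
    years = np.asarray(sorted(int(y) for y in years))
    if years.size == 0 or years[0] < 0:
        raise ValueError("years must be nonnegative integers")
    lam0_w = initial[op.water_mask]
    m0 = op.agg @ lam0_w
    c0 = hom.delta_bar * m0 / op.n_fine
    solver = DiffusionSolver(op, dt_days=dt_days, scheme=scheme)
    snaps = solver.solve_coarse(hom.delta_bar, hom.reaction_coef, c0, float(gamma), int(years[-1]))

    nr, nc = op.fine_shape
    lam_fine = np.zeros((years.size, nr, nc))
    lam_coarse = np.full((years.size,) + op.coarse_shape, np.nan)
    wi, wj = np.nonzero(op.water_mask)
    for k, y in enumerate(years):
        c = snaps[y]
        lam_fine[k, wi, wj] = c[op.coarse_of_fine] / hom.delta_fine
        lam_coarse[k][op.coarse_water_mask] = c / hom.delta_bar
    return IntensitySeries(
        years=years,
        lambda_fine=lam_fine,
        lambda_coarse=lam_coarse,
        dt_days=dt_days,
        water_mask=op.water_mask,
    )
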