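"""Post-hoc quantities: spread rates, total abundance, predictive checks.

Asymptotic colonization rates come from traveling-wave theory for the
logistic reaction-diffusion model: a steep initial front (steepness
1/kappa_j^2 exceeding sqrt(gamma/delta_bar)) converges to the minimum wave
speed 2*sqrt(delta_bar*gamma), while a flatter front retains its shape and
travels at delta_bar/kappa_j^2 + gamma*kappa_j^2.  Maps are computed on the
homogenized grid with the single global gamma and the local delta_bar, in
km/yr.

Total abundance for a posterior draw sums (i) known true abundances, (ii)
posterior latent abundances where counts were observed, and (iii) fresh
negative-binomial draws around the draw's intensity surface everywhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import FitContext, PosteriorChains
from .landscape import Epicenter, Landscape
from .observation import SurveyData
from .process import HomogenizedGrid

M2_PER_KM2 = 1.0e6


def front_regime(kappa_km: float, gamma: float, delta_bar_km2: float) -> str:
    """Classify the initial wave front as 'steep' or 'flat'.

    Steep iff 1/kappa^2 >= sqrt(gamma/delta_bar) (equality counts as steep;
    at that point the two rate formulas coincide).  kappa in km, gamma per
    year, delta_bar in km^2/yr — the reference length unit of the steepness
    convention is the kilometre.
    """
    if kappa_km <= 0 or gamma <= 0 or delta_bar_km2 <= 0:
        raise ValueError("kappa, gamma, delta_bar must be positive")
    return "steep" if 1.0 / kappa_km**2 >= np.sqrt(gamma / delta_bar_km2) else "flat"


def steep_front_rate(delta_bar_km2, gamma: float):
    """Minimum (steep-front) asymptotic spread rate, km/yr: 2*sqrt(delta*gamma)."""
    return 2.0 * np.sqrt(np.asarray(delta_bar_km2, dtype=float) * gamma)


def flat_front_rate(delta_bar_km2, gamma: float, kappa_km: float):
    """Flat-front asymptotic spread rate, km/yr: delta/kappa^2 + gamma*kappa^2."""
    return np.asarray(delta_bar_km2, dtype=float) / kappa_km**2 + gamma * kappa_km**2


def epicenter_regimes(hom: HomogenizedGrid, gamma: float, epicenters: list[Epicenter]) -> dict[str, str]:
    """Per-epicenter front regime, evaluating delta_bar at the coarse cell
    containing each release site."""
    out = {}
    f = hom.op.factor
    ids = hom.op.coarse_ids_2d
    for j, e in enumerate(epicenters):
        cid = ids[e.row // f, e.col // f]
        if cid < 0:
            raise ValueError(f"epicenter {e.label!r} falls on a coarse land cell")
        db_km2 = hom.delta_bar[cid] / M2_PER_KM2
        out[e.label or str(j)] = front_regime(e.kappa_m / 1000.0, gamma, db_km2)
    return out


@dataclass
class SpreadRateMap:
    """Asymptotic spread rates (km/yr) on the homogenized grid."""

    rates: np.ndarray  # coarse raster, NaN on coarse land
    regime: str
    kappa_km: float | None
    summary: dict

    def histogram(self, bins=30) -> pd.DataFrame:
        vals = self.rates[np.isfinite(self.rates)]
        h, edges = np.histogram(vals, bins=bins)
        return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": h})


def spread_rate_map(
    hom: HomogenizedGrid,
    gamma: float,
    regime: str = "steep",
    kappa_km: float | None = None,
) -> SpreadRateMap:
    """Map of asymptotic spread rates over coarse water cells.

    ``regime='steep'`` uses the minimum rate 2*sqrt(delta_bar*gamma);
    ``regime='flat'`` needs the front dispersion kappa (km).  Summary
    reports min/median/max over coarse water cells.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    db_km2 = hom.delta_bar / M2_PER_KM2
    if regime == "steep":
        vals = steep_front_rate(db_km2, gamma)
    elif regime == "flat":
        if kappa_km is None or kappa_km <= 0:
            raise ValueError("flat regime requires a positive kappa_km")
        vals = flat_front_rate(db_km2, gamma, kappa_km)
    else:
        raise ValueError("regime must be 'steep' or 'flat'")
    rates = hom.op.to_coarse_2d(vals)
    summary = {
        "min": float(np.min(vals)),
        "median": float(np.median(vals)),
        "max": float(np.max(vals)),
    }
    return SpreadRateMap(rates=rates, regime=regime, kappa_km=kappa_km, summary=summary)


# ---------------------------------------------------------------------------
# total abundance
# ---------------------------------------------------------------------------


def _chain_state(chains: PosteriorChains, chain: int, it: int) -> dict:
    d = chains.draws
    return {
        "gamma": float(d["gamma"][chain, it]),
        "beta": d["beta"][chain, it],
        "alpha": d["alpha"][chain, it],
        "theta": d["theta"][chain, it],
        "kappa": d["kappa"][chain, it],
        "tau": float(d["tau"][chain, it]),
        "p": {int(y): float(d["p"][chain, it, k]) for k, y in enumerate(chains.p_years)},
    }


def total_abundance(
    chains: PosteriorChains,
    data: SurveyData,
    landscape: Landscape,
    epicenters: list[Epicenter],
    years,
    n_draws: int = 50,
    level: float = 0.95,
    seed: int = 0,
    context: FitContext | None = None,
) -> pd.DataFrame:
    """Posterior time series of total abundance over the whole domain.

    For each of ``n_draws`` posterior draws (evenly thinned across chains)
    the PDE is re-solved and, per year, the total is the sum of known true
    abundances, sampled latent abundances at count-observed cells, and fresh
    NB draws everywhere unsurveyed.  Returns per-year mean and equal-tailed
    interval at ``level``.
    """
    ctx = context or FitContext(
        data, landscape, epicenters,
        epsilon=chains.config.epsilon, dt_days=chains.config.dt_days, scheme=chains.config.scheme,
    )
    years = sorted(int(y) for y in years)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    n_total = chains.n_chains * chains.n_kept
    n_draws = min(n_draws, n_total)
    sel = np.linspace(0, n_total - 1, n_draws).astype(int)

    w = landscape.water_mask
    widx = -np.ones(w.shape, dtype=np.int64)
    widx[w] = np.arange(w.sum())

    # per-year index bookkeeping (guard against double counting)
    true_by_year: dict[int, np.ndarray] = {}
    truevals_by_year: dict[int, float] = {}
    for yr, g in data.true_counts.groupby("year"):
        idx = widx[g["cell_row"].to_numpy(int), g["cell_col"].to_numpy(int)]
        true_by_year[int(yr)] = idx
        truevals_by_year[int(yr)] = float(g["N"].sum())
    count_rows_by_year = {int(yr): g.index.to_numpy() for yr, g in data.counts.groupby("year")}
    countidx_by_year = {
        int(yr): widx[g["cell_row"].to_numpy(int), g["cell_col"].to_numpy(int)]
        for yr, g in data.counts.groupby("year")
    }
    for yr in set(true_by_year) & set(countidx_by_year):
        if np.intersect1d(true_by_year[yr], countidx_by_year[yr]).size:
            raise ValueError(f"cells double-counted between counts and true_counts in year {yr}")

    totals = np.zeros((n_draws, len(years)))
    for kk, flat in enumerate(sel):
        chain, it = divmod(int(flat), chains.n_kept)
        state = _chain_state(chains, chain, it)
        lam_full = ctx.solve_lambda_full(state, years)
        if lam_full is None:
            totals[kk] = np.nan
            continue
        tau = state["tau"]
        for ti, yr in enumerate(years):
            tot = truevals_by_year.get(yr, 0.0)
            observed = np.zeros(lam_full.shape[1], dtype=bool)
            if yr in true_by_year:
                observed[true_by_year[yr]] = True
            if yr in count_rows_by_year:
                rows = count_rows_by_year[yr]
                observed[countidx_by_year[yr]] = True
                tot += float(chains.latent_N[chain, it, rows].sum())
            lam_un = lam_full[ti][~observed]
            pnb = tau / (tau + np.maximum(lam_un, 0.0))
            tot += float(rng.negative_binomial(tau, np.minimum(pnb, 1.0)).sum())
            totals[kk, ti] = tot
    lo = (1.0 - level) / 2.0
    return pd.DataFrame(
        {
            "year": years,
            "mean": np.nanmean(totals, axis=0),
            "lower": np.nanquantile(totals, lo, axis=0),
            "upper": np.nanquantile(totals, 1 - lo, axis=0),
        }
    )


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------


def posterior_predictive_check(
    chains: PosteriorChains,
    data: SurveyData,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Pointwise posterior predictive coverage of the observed counts.

    For every count observation and every stored draw, a replicate count is
    simulated through the full observation layer (NB abundance then binomial
    thinning); the observation is flagged if it falls outside the
    equal-tailed predictive interval.  Returns the number and fraction of
    observations outside, plus the per-observation table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    n_chains, n_kept, n_obs = chains.lambda_obs.shape
    n_draws = n_chains * n_kept
    if n_draws < 100:
        warnings.warn(f"only {n_draws} posterior draws; predictive interval endpoints are unstable")
    if n_obs == 0:
        return {"n_obs": 0, "n_outside": 0, "fraction_outside": 0.0, "table": pd.DataFrame()}

    y = data.counts["count"].to_numpy(int)
    years = data.counts["year"].to_numpy(int)
    slot = {int(t): k for k, t in enumerate(chains.p_years)}
    yslot = np.array([slot[int(t)] for t in years])

    lam = chains.lambda_obs.reshape(n_draws, n_obs)
    tau = chains.flat("tau")[:, None]
    p = chains.flat("p")[:, yslot]
    pnb = tau / (tau + np.maximum(lam, 1e-300))
    Nrep = rng.negative_binomial(np.broadcast_to(tau, lam.shape), np.minimum(pnb, 1.0))
    yrep = rng.binomial(Nrep, p)
    a = (1.0 - level) / 2.0
    lo = np.quantile(yrep, a, axis=0)
    hi = np.quantile(yrep, 1.0 - a, axis=0)
    outside = (y < lo) | (y > hi)
    table = pd.DataFrame(
        {
            "cell_row": data.counts["cell_row"],
            "cell_col": data.counts["cell_col"],
            "year": years,
            "count": y,
            "pred_lower": lo,
            "pred_upper": hi,
            "outside": outside,
        }
    )
    return {
        "n_obs": int(n_obs),
        "n_outside": int(outside.sum()),
        "fraction_outside": float(outside.mean()),
        "table": table,
    }
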