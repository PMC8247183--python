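"""Synthetic studies: landscape, latent truth, and all three survey types.

The generator emulates the structure of a multi-decade aerial monitoring
program for a recolonizing nearshore predator: a patchy fjord-like water
domain with depth/shore covariates and two management areas, a
multi-epicenter release, latent abundance following the logistic diffusion
process with negative-binomial cell-level noise, and three survey
instruments — stratified design-based transects with intensive search units
(ISUs), distribution surveys of shallow habitat, and photographic surveys
with an informative detection prior.  Everything is reproducible from
(seed, config); the config is the manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .landscape import (
    Epicenter,
    Landscape,
    cumulative_town_distance,
    shoreline_cells,
    shoreline_complexity,
    standardize_covariates,
)
from .observation import PHOTO_BETA, ObsParams, SurveyData, sample_abundance, sample_count
from .process import (
    IntensitySeries,
    ProcessParams,
    carrying_capacity_field,
    homogenize,
    initial_intensity,
    motility_field,
    propagate,
)

# Posterior means reported for the Southeast Alaska fit; packaged as the
# reference parameter set.  kappa is in the source's
# length units (km here); theta in individuals.
REF_BETA = (16.36, -1.77, 0.29, 0.22, 0.17, 0.45, -0.24, -1.34)
REF_ALPHA = (-1.66, 3.16, 1.87)
REF_GAMMA = 0.29
REF_TAU = 0.03
REF_THETA = (147.53, 9.75, 9.96, 98.90, 10.01, 96.18, 98.82)
REF_KAPPA_KM = (28.78, 2.54, 9.11, 0.63, 2.23, 8.49, 9.23)
REF_EPICENTER_LABELS = ("MI", "BI", "NI", "KB", "YB", "YI", "CS")


def reference_posterior_means() -> dict:
    """Reference posterior-mean parameter values as a plain dict."""
    return {
        "beta": np.array(REF_BETA),
        "alpha": np.array(REF_ALPHA),
        "gamma": REF_GAMMA,
        "tau": REF_TAU,
        "theta": np.array(REF_THETA),
        "kappa_km": np.array(REF_KAPPA_KM),
    }


@dataclass
class StudyConfig:
    """Full generating configuration of a synthetic study (the manifest).

    Defaults describe the desk-scale study: a 40x40 grid of 400 m cells
    (16 x 16 km), homogenization factor 5 (2 km coarse cells), 20 years with
    8 surveyed years, seven release epicenters with reference-shaped
    parameters (theta scaled to the small domain; kappa of 0.8-3 km), and a
    3:1 shallow-stratum transect design with ISUs.
    """

    n_rows: int = 40
    n_cols: int = 40
    cell_size_m: float = 400.0
    epsilon: float = 0.2
    dt_days: float = 1.0
    n_years: int = 20
    design_years: tuple = (4, 7, 10, 13, 16)
    distribution_years: tuple = (1, 2)
    photo_years: tuple = (19,)
    # landscape shape
    water_frac: float = 0.55
    smooth_sigma: tuple = (4.0, 1.6)
    shallow_frac: float = 0.40
    offshore_dist_m: float = 5000.0
    depth_cut_m: float = 100.0
    n_towns: int = 3
    min_water_cells: int = 300
    # process truth
    n_epicenters: int = 7
    theta_scale: float = 0.1
    kappa_m: tuple = (3000.0, 800.0, 1500.0, 1000.0, 800.0, 1500.0, 1500.0)
    beta: tuple = REF_BETA
    alpha: tuple = REF_ALPHA
    gamma: float = REF_GAMMA
    # observation truth
    tau: float = REF_TAU
    p_design: tuple = (0.80, 0.75, 0.85, 0.70, 0.78)
    p_distribution: tuple = (0.65, 0.70)
    # survey design
    transect_frac: float = 0.5
    stratum_incl: float = 0.9
    stratum_ratio: float = 3.0
    isu_rate: float = 0.3
    max_isu_group: int = 20
    photo_col_frac: float = 0.6

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kw = {}
        for k, v in d.items():
            if k not in fields:
                continue
            kw[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kw)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)  # 4-connectivity, matching the solver stencil
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def generate_landscape(
    seed: int,
    n_rows: int = 40,
    n_cols: int = 40,
    config: StudyConfig | None = None,
) -> Landscape:
    """Random fjord-like landscape with all model covariates, standardized.

    Correlated (anisotropically smoothed) noise is thresholded to carve a
    connected water domain; depth grows away from shore, with the shallow
    (<40 m) fraction pinned at the configured value; open-water cells beyond
    the offshore distance or depth limits are removed from the domain
    (reflective boundary of the nearshore system); towns sit on the
    shoreline and two disjoint rectangular management areas define the
    protected-bay and fisheries-closure indicators.
    """
    cfg = config or StudyConfig(n_rows=n_rows, n_cols=n_cols)
    ss = np.random.SeedSequence([seed, 2025])
    for attempt, child in enumerate(ss.spawn(30)):
        rng = np.random.default_rng(child)
        try:
            return _generate_landscape_once(rng, n_rows, n_cols, cfg)
        except ValueError:
            continue
    raise RuntimeError("could not generate a connected water domain in 30 attempts")


def _generate_landscape_once(rng: np.random.Generator, nr: int, nc: int, cfg: StudyConfig) -> Landscape:
    a = cfg.cell_size_m
    z = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), sigma=cfg.smooth_sigma, mode="nearest")
    water = z < np.quantile(z, cfg.water_frac)
    water = _largest_component(water)

    # depth: grows with distance from land, multiplicative correlated noise,
    # scaled so the configured fraction of water cells is shallower than 40 m
    dist_land = ndimage.distance_transform_edt(water) * a
    noise = np.exp(ndimage.gaussian_filter(rng.standard_normal((nr, nc)), 2.0, mode="nearest"))
    score = (dist_land + 0.5 * a) * noise
    ref = np.quantile(score[water], cfg.shallow_frac)
    depth = 40.0 * score / ref

    # nearshore-system boundary: drop exposed deep / far-offshore water
    keep = water & ~((dist_land > cfg.offshore_dist_m) | (depth > cfg.depth_cut_m))
    water = _largest_component(keep)
    if water.sum() < cfg.min_water_cells:
        raise ValueError("water domain too small")

    dist_shore = ndimage.distance_transform_edt(water) * a
    gy, gx = np.gradient(depth, a)
    slope = np.hypot(gy, gx)
    shore_cx = shoreline_complexity(water, radius_m=1000.0, cell_size_m=a)

    shore = np.argwhere(shoreline_cells(water))
    if len(shore) < cfg.n_towns:
        raise ValueError("not enough shoreline for towns")
    towns = [tuple(shore[i]) for i in rng.choice(len(shore), size=cfg.n_towns, replace=False)]
    town_dist = cumulative_town_distance(water, towns, a)

    glba = np.zeros((nr, nc))
    fish = np.zeros((nr, nc))
    glba[: nr // 3, : nc // 3] = 1.0
    fish[2 * nr // 3 :, 2 * nc // 3 :] = 1.0
    glba *= water
    fish *= water
    if glba.sum() < 5 or fish.sum() < 5:
        raise ValueError("management areas empty")

    land = Landscape(
        cell_size_m=a,
        water_mask=water,
        covariates={
            "depth_ind": (depth < 40.0).astype(float) * water,
            "dist_shore": np.where(water, dist_shore, 0.0),
            "slope": np.where(water, slope, 0.0),
            "shore_complex": np.where(water, shore_cx, 0.0),
            "town_dist": town_dist,
            "glba_ind": glba,
            "fish_ind": fish,
        },
        towns=[(int(r), int(c)) for r, c in towns],
    )
    return standardize_covariates(land)


def place_epicenters(
    landscape: Landscape,
    seed: int,
    n: int,
    theta: np.ndarray,
    kappa_m: np.ndarray,
    labels=REF_EPICENTER_LABELS,
) -> list[Epicenter]:
    """Spread n release sites over water by farthest-point sampling."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    cells = np.argwhere(landscape.water_mask)
    chosen = [cells[rng.integers(len(cells))]]
    for _ in range(n - 1):
        d2 = np.min(
            [np.sum((cells - c) ** 2, axis=1) for c in chosen], axis=0
        )
        chosen.append(cells[int(np.argmax(d2))])
    return [
        Epicenter(row=int(r), col=int(c), theta=float(theta[j]), kappa_m=float(kappa_m[j]),
                  label=labels[j % len(labels)])
        for j, (r, c) in enumerate(chosen)
    ]


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


@dataclass
class Truth:
    """Generating truth: parameters, intensity surface, latent abundances."""

    params: ProcessParams
    obs: ObsParams
    series: IntensitySeries
    N: np.ndarray  # (n_years, nr, nc) latent true abundance


def desk_params(config: StudyConfig, epicenters: list[Epicenter]) -> ProcessParams:
    return ProcessParams(
        beta=np.array(config.beta),
        alpha=np.array(config.alpha),
        gamma=config.gamma,
        epicenters=epicenters,
    )


def _true_detection(config: StudyConfig, rng: np.random.Generator) -> dict[int, float]:
    p = {}
    for y, pt in zip(config.design_years, config.p_design):
        p[int(y)] = float(pt)
    for y, pt in zip(config.distribution_years, config.p_distribution):
        p[int(y)] = float(pt)
    a, b = PHOTO_BETA
    for y in config.photo_years:
        p[int(y)] = float(rng.beta(a, b))
    return p


def generate_truth(
    landscape: Landscape,
    params: ProcessParams,
    obs: ObsParams,
    n_years: int,
    seed: int,
    epsilon: float = 0.2,
    dt_days: float = 1.0,
) -> Truth:
    """Propagate the PDE under ``params`` and draw latent abundances.

    Latent N is drawn for every (water cell, year) from the NB observation
    layer around the cell intensity; surveys later thin these.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    delta = motility_field(landscape, params.beta)
    K = carrying_capacity_field(landscape, params.alpha)
    lam0 = initial_intensity(landscape, params.epicenters)
    hom = homogenize(delta, K, epsilon, landscape.water_mask, landscape.cell_size_m)
    series = propagate(lam0, hom, params.gamma, years=range(n_years), dt_days=dt_days)
    nr, nc = landscape.water_mask.shape
    N = np.zeros((n_years, nr, nc), dtype=np.int64)
    w = landscape.water_mask
    for t in range(n_years):
        N[t][w] = sample_abundance(series.lambda_fine[t][w], obs.tau, rng)
    return Truth(params=params, obs=obs, series=series, N=N)


# ---------------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------------


def _records(cells: np.ndarray, year: int, y: np.ndarray, survey_type: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_row": cells[:, 0],
            "cell_col": cells[:, 1],
            "year": year,
            "count": y,
            "survey_type": survey_type,
        }
    )


def simulate_design_survey(
    truth: Truth,
    landscape: Landscape,
    year: int,
    config: StudyConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stratified strip-transect survey with intensive search units.

    Columns of the grid are transect strips; within flown strips, cells in
    the shallow stratum are surveyed with the configured inclusion
    probability and other cells at 1/ratio of it.  Surveyed cells yield
    binomially thinned counts.  Groups of 1..max_isu_group trigger an ISU at
    the configured rate: the circling recount reveals the true abundance, so
    the cell is recorded as a true-abundance observation (and as an ISU
    record) rather than as a thinned count.

    Returns (counts, isu, true_counts) tables.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13, int(year)]))
    w = landscape.water_mask
    shallow = landscape.covariates["depth_ind"] > 0.5
    if not (shallow & w).any() or not (~shallow & w).any():
        raise ValueError("a sampling stratum is empty")
    cols_flown = rng.random(landscape.n_cols) < config.transect_frac
    incl = np.where(shallow, config.stratum_incl, config.stratum_incl / config.stratum_ratio)
    surveyed = w & cols_flown[None, :] & (rng.random(w.shape) < incl)
    cells = np.argwhere(surveyed)
    p_t = truth.obs.p[int(year)]
    Nc = truth.N[year][surveyed]
    y = sample_count(Nc, p_t, rng)
    isu_mask = (y >= 1) & (y <= config.max_isu_group) & (rng.random(y.shape) < config.isu_rate)

    counts = _records(cells[~isu_mask], year, y[~isu_mask], "design")
    isu = pd.DataFrame({"year": int(year), "initial": y[isu_mask], "final": Nc[isu_mask]})
    true_counts = pd.DataFrame(
        {
            "cell_row": cells[isu_mask, 0],
            "cell_col": cells[isu_mask, 1],
            "year": int(year),
            "N": Nc[isu_mask],
        }
    )
    return counts, isu, true_counts


def simulate_distribution_survey(
    truth: Truth, landscape: Landscape, year: int, config: StudyConfig, seed: int
) -> pd.DataFrame:
    """Survey of favorable (shallow) habitat: every shallow water cell is
    visited and yields a thinned count."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17, int(year)]))
    w = landscape.water_mask
    surveyed = w & (landscape.covariates["depth_ind"] > 0.5)
    cells = np.argwhere(surveyed)
    y = sample_count(truth.N[year][surveyed], truth.obs.p[int(year)], rng)
    return _records(cells, int(year), y, "distribution")


def simulate_photo_survey(
    truth: Truth, landscape: Landscape, year: int, config: StudyConfig, seed: int
) -> pd.DataFrame:
    """Photographic transect survey, already aggregated to the fine grid.

    The year's detection probability was drawn once from the informative
    Beta prior when the truth was generated.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 19, int(year)]))
    w = landscape.water_mask
    cols_flown = rng.random(landscape.n_cols) < config.photo_col_frac
    surveyed = w & cols_flown[None, :]
    cells = np.argwhere(surveyed)
    y = sample_count(truth.N[year][surveyed], truth.obs.p[int(year)], rng)
    return _records(cells, int(year), y, "photo")


# ---------------------------------------------------------------------------
# whole studies
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    landscape: Landscape
    truth: Truth
    surveys: SurveyData
    seed: int
    manifest: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.landscape.save(path / "landscape")
        self.surveys.save(path / "surveys")
        (path / "manifest.yaml").write_text(yaml.safe_dump(self.manifest))


def generate_study(seed: int, config: StudyConfig | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study from a seed and a config."""
    cfg = config or StudyConfig()
    land = generate_landscape(seed, cfg.n_rows, cfg.n_cols, cfg)
    theta = np.array(REF_THETA[: cfg.n_epicenters]) * cfg.theta_scale
    kappa = np.array(cfg.kappa_m[: cfg.n_epicenters])
    epis = place_epicenters(land, seed, cfg.n_epicenters, theta, kappa)
    params = desk_params(cfg, epis)
    p_rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    obs = ObsParams(p=_true_detection(cfg, p_rng), tau=cfg.tau)
    truth = generate_truth(land, params, obs, cfg.n_years, seed, epsilon=cfg.epsilon, dt_days=cfg.dt_days)

    counts_list, isu_list, true_list = [], [], []
    for year in cfg.distribution_years:
        counts_list.append(simulate_distribution_survey(truth, land, year, cfg, seed))
    for year in cfg.design_years:
        c, i, t = simulate_design_survey(truth, land, year, cfg, seed)
        counts_list.append(c)
        isu_list.append(i)
        true_list.append(t)
    for year in cfg.photo_years:
        counts_list.append(simulate_photo_survey(truth, land, year, cfg, seed))

    surveys = SurveyData(
        counts=pd.concat(counts_list, ignore_index=True) if counts_list else None,
        true_counts=pd.concat(true_list, ignore_index=True) if true_list else None,
        isu=pd.concat(isu_list, ignore_index=True) if isu_list else None,
    )
    manifest = {"seed": int(seed), "config": cfg.to_dict()}
    return SyntheticStudy(landscape=land, truth=truth, surveys=surveys, seed=int(seed), manifest=manifest)


def regenerate_from_manifest(manifest: dict) -> SyntheticStudy:
    """Rebuild a study bit-identically from its manifest."""
    return generate_study(int(manifest["seed"]), StudyConfig.from_dict(manifest["config"]))
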