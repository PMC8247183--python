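"""Process model: fields, initial condition, homogenization, propagation."""

import numpy as np
import pytest

import ecodiff as ed
from ecodiff.landscape import COVARIATE_NAMES
from tests.conftest import corridor_landscape


def homogeneous_landscape(nr, nc, cell_m=400.0, water=None):
    if water is None:
        water = np.ones((nr, nc), dtype=bool)
    covs = {name: np.zeros((nr, nc)) for name in COVARIATE_NAMES}
    return ed.Landscape(cell_size_m=cell_m, water_mask=water, covariates=covs)


class TestFields:
    def test_zero_coefficients_give_unit_fields(self):
        land = homogeneous_landscape(5, 5)
        np.testing.assert_allclose(ed.motility_field(land, np.zeros(8)), 1.0)
        np.testing.assert_allclose(ed.carrying_capacity_field(land, np.zeros(3)), 1.0)

    def test_reference_coefficients_arithmetic(self):
        # a shallow cell inside a fisheries closure, all scaled covariates 0
        land = homogeneous_landscape(3, 3)
        land.covariates["depth_ind"][1, 1] = 1.0
        land.covariates["fish_ind"][1, 1] = 1.0
        beta = np.array([16.36, -1.77, 0.29, 0.22, 0.17, 0.45, -0.24, -1.34])
        delta = ed.motility_field(land, beta)
        assert delta[1, 1] == pytest.approx(np.exp(16.36 - 1.77 - 1.34), rel=1e-12)
        assert delta[0, 0] == pytest.approx(np.exp(16.36), rel=1e-12)

    def test_capacity_ordering_protected_gt_closure_gt_plain(self):
        land = homogeneous_landscape(3, 3)
        land.covariates["glba_ind"][0, 0] = 1.0
        land.covariates["fish_ind"][1, 1] = 1.0
        alpha = np.array([-1.66, 3.16, 1.87])
        K = ed.carrying_capacity_field(land, alpha)
        assert K[0, 0] == pytest.approx(np.exp(1.50), rel=1e-12)
        assert K[1, 1] == pytest.approx(np.exp(0.21), rel=1e-12)
        assert K[2, 2] == pytest.approx(np.exp(-1.66), rel=1e-12)
        assert K[0, 0] > K[1, 1] > K[2, 2]

    def test_negative_closure_coefficient_lowers_motility(self):
        land = homogeneous_landscape(2, 2)
        land.covariates["fish_ind"][0, 0] = 1.0
        beta = np.zeros(8)
        beta[7] = -1.34
        delta = ed.motility_field(land, beta)
        assert delta[0, 0] < delta[1, 1]

    def test_nominal_regional_capacity_hand_sum(self):
        water = np.zeros((1, 3), dtype=bool)
        water[0] = True
        land = homogeneous_landscape(1, 3, water=water)
        land.covariates["glba_ind"][0, 0] = 1.0
        K = ed.carrying_capacity_field(land, np.array([0.5, 1.0, 0.0]))
        assert np.nansum(K) == pytest.approx(np.exp(1.5) + 2 * np.exp(0.5), rel=1e-12)

    def test_overflow_rejected_with_cell_location(self):
        land = homogeneous_landscape(2, 2)
        beta = np.zeros(8)
        beta[0] = 800.0
        with pytest.raises(ValueError, match="overflow"):
            ed.motility_field(land, beta)


class TestInitialIntensity:
    def test_total_equals_theta_single(self, open_water_landscape):
        epi = [ed.Epicenter(row=15, col=15, theta=123.4, kappa_m=1200.0)]
        lam0 = ed.initial_intensity(open_water_landscape, epi)
        assert lam0.sum() == pytest.approx(123.4, rel=1e-12)

    def test_seven_kernels_additivity_reference_thetas(self, open_water_landscape):
        thetas = [147.53, 9.75, 9.96, 98.90, 10.01, 96.18, 98.82]
        rng = np.random.default_rng(1)
        epis = [
            ed.Epicenter(row=int(rng.integers(30)), col=int(rng.integers(30)), theta=t, kappa_m=900.0)
            for t in thetas
        ]
        lam0 = ed.initial_intensity(open_water_landscape, epis)
        assert lam0.sum() == pytest.approx(sum(thetas), rel=1e-12)

    def test_quadrature_matches_gaussian_integral(self):
        # sum of the kernel x cell area vs the closed form pi*kappa^2
        land = homogeneous_landscape(101, 101, cell_m=400.0)
        kappa = 3 * 400.0
        epi = ed.Epicenter(row=50, col=50, theta=1.0, kappa_m=kappa)
        wi, wj = land.water_indices()
        d2 = ((wi - 50) ** 2 + (wj - 50) ** 2) * 400.0**2
        z = np.exp(-d2 / kappa**2).sum() * 400.0**2
        assert z == pytest.approx(np.pi * kappa**2, rel=0.01)

    def test_epicenter_on_land_rejected(self):
        water = np.ones((4, 4), dtype=bool)
        water[1, 1] = False
        land = homogeneous_landscape(4, 4, water=water)
        with pytest.raises(ValueError, match="not on water"):
            ed.initial_intensity(land, [ed.Epicenter(row=1, col=1, theta=1.0, kappa_m=500.0)])


class TestHomogenize:
    def test_constant_fields_are_fixed_points(self):
        delta = np.full((10, 10), 3.0)
        K = np.full((10, 10), 2.0)
        hom = ed.homogenize(delta, K, epsilon=0.2, water_mask=np.ones((10, 10), bool), cell_size_m=400.0)
        np.testing.assert_allclose(hom.delta_bar, 3.0)
        np.testing.assert_allclose(hom.reaction_coef, 1.0 / 6.0)

    def test_harmonic_mean_of_two_values(self):
        # one coarse cell, fine deltas split evenly between 1 and 4
        delta = np.ones((2, 2))
        delta[:, 1] = 4.0
        K = np.ones((2, 2))
        hom = ed.homogenize(delta, K, epsilon=0.5, water_mask=np.ones((2, 2), bool), cell_size_m=400.0)
        assert hom.delta_bar.shape == (1,)
        assert hom.delta_bar[0] == pytest.approx(2.0 / (1.0 / 1.0 + 1.0 / 4.0), rel=1e-12)
        assert hom.reaction_coef[0] == pytest.approx(np.mean([1.0, 1.0, 0.25, 0.25]), rel=1e-12)

    def test_padding_with_land_when_not_divisible(self):
        delta = np.full((7, 9), 2.0)
        K = np.ones((7, 9))
        hom = ed.homogenize(delta, K, epsilon=0.25, water_mask=np.ones((7, 9), bool), cell_size_m=400.0)
        assert hom.op.coarse_shape == (2, 3)
        assert hom.coarse_water_mask.all()

    def test_epsilon_one_is_identity(self):
        rng = np.random.default_rng(0)
        delta = np.exp(rng.normal(size=(6, 6)))
        K = np.exp(rng.normal(size=(6, 6)))
        water = rng.random((6, 6)) < 0.8
        hom = ed.homogenize(delta, K, epsilon=1.0, water_mask=water, cell_size_m=400.0)
        np.testing.assert_allclose(hom.delta_bar, delta[water])
        np.testing.assert_allclose(hom.reaction_coef, 1.0 / (delta[water] * K[water]))


def _setup_propagation(land, beta0=np.log(4.0e6), gamma=0.3, epsilon=1.0, theta=50.0, kappa=1200.0,
                       row=None, col=None):
    beta = np.zeros(8)
    beta[0] = beta0
    delta = ed.motility_field(land, beta)
    K = ed.carrying_capacity_field(land, np.array([np.log(2.0), 0.0, 0.0]))
    hom = ed.homogenize(delta, K, epsilon, land.water_mask, land.cell_size_m)
    nr, nc = land.water_mask.shape
    epi = [ed.Epicenter(row=nr // 2 if row is None else row, col=nc // 2 if col is None else col,
                        theta=theta, kappa_m=kappa)]
    lam0 = ed.initial_intensity(land, epi)
    return lam0, hom


class TestPropagate:
    def test_mass_conserved_without_growth(self, open_water_landscape):
        lam0, hom = _setup_propagation(open_water_landscape)
        series = ed.propagate(lam0, hom, gamma=1e-300, years=range(0, 51, 10), dt_days=5.0)
        totals = series.total_abundance_intensity()
        np.testing.assert_allclose(totals, totals[0], rtol=1e-6)

    def test_single_cell_matches_logistic_closed_form(self):
        land = homogeneous_landscape(1, 1)
        lam0, hom = _setup_propagation(land, theta=0.05, kappa=600.0)
        gamma, K = 0.3, 2.0
        l0 = lam0[0, 0]
        years = np.arange(0, 21, 5)
        series = ed.propagate(lam0, hom, gamma, years, dt_days=1.0)
        expected = K / (1.0 + ((K - l0) / l0) * np.exp(-gamma * years))
        np.testing.assert_allclose(series.lambda_fine[:, 0, 0], expected, rtol=1e-4)

    def test_euler_reaction_order_of_accuracy(self):
        # halving dt should cut the explicit-reaction error by ~2-4x
        land = homogeneous_landscape(1, 1)
        lam0, hom = _setup_propagation(land, theta=0.05, kappa=600.0)
        gamma, K = 0.3, 2.0
        l0 = lam0[0, 0]
        t = 20
        exact = K / (1.0 + ((K - l0) / l0) * np.exp(-gamma * t))
        errs = []
        for dt in (8.0, 4.0, 2.0):
            s = ed.propagate(lam0, hom, gamma, [t], dt_days=dt, scheme="euler")
            errs.append(abs(s.lambda_fine[0, 0, 0] - exact))
        assert 1.8 < errs[0] / errs[1] < 4.5
        assert 1.8 < errs[1] / errs[2] < 4.5

    def test_long_run_equilibrium_is_K(self, open_water_landscape):
        lam0, hom = _setup_propagation(open_water_landscape, gamma=0.5)
        gamma = 0.5
        series = ed.propagate(lam0, hom, gamma, [0, 40], dt_days=5.0)  # gamma*t = 20
        K = 2.0
        lam_end = series.lambda_fine[-1][open_water_landscape.water_mask]
        np.testing.assert_allclose(lam_end, K, rtol=1e-3)

    def test_never_exceeds_capacity_when_started_below(self, open_water_landscape):
        lam0, hom = _setup_propagation(open_water_landscape, theta=100.0)
        series = ed.propagate(lam0, hom, 0.4, range(0, 30, 5), dt_days=5.0)
        assert series.lambda_fine.max() <= 2.0 * (1 + 1e-9) or series.lambda_fine.max() <= lam0.max()
        assert series.lambda_fine.min() >= 0.0

    def test_homogenized_matches_fine_scale_solution(self):
        """Coarse (eps=1/5) vs direct fine-scale solve on a heterogeneous
        40x40 landscape: relative L1 error under 5% at every output year.

        The landscape has cell-scale motility variation (log-delta white
        noise, sd 0.5 around the reference magnitude) — the regime
        homogenization is built for — plus land blocks, and the run stays in
        the growth phase (where the analysis of a recolonizing population
        lives).  The initial kernel is resolved at the coarse scale.
        """
        rng = np.random.default_rng(7)
        nr = nc = 40
        water = np.ones((nr, nc), dtype=bool)
        water[0:10, 15:20] = False
        water[25:40, 0:5] = False
        delta = np.exp(np.log(1.28e7) + 0.5 * rng.standard_normal((nr, nc)))
        K = np.full((nr, nc), 5.0)
        lam0 = np.zeros((nr, nc))
        wi, wj = np.nonzero(water)
        d2 = ((wi - 20) ** 2 + (wj - 25) ** 2) * 400.0**2
        kern = np.exp(-d2 / 3000.0**2)
        lam0[wi, wj] = 50.0 * kern / kern.sum()
        years = range(1, 11)
        hom_c = ed.homogenize(delta, K, 0.2, water, 400.0)
        hom_f = ed.homogenize(delta, K, 1.0, water, 400.0)
        coarse = ed.propagate(lam0, hom_c, 0.29, years, dt_days=2.0)
        fine = ed.propagate(lam0, hom_f, 0.29, years, dt_days=2.0)
        for k in range(len(coarse.years)):
            l1 = np.abs(coarse.lambda_fine[k][water] - fine.lambda_fine[k][water]).sum()
            assert l1 / fine.lambda_fine[k][water].sum() < 0.05

    def test_negative_initial_rejected(self, open_water_landscape):
        lam0, hom = _setup_propagation(open_water_landscape)
        lam0[0, 0] = -1.0
        with pytest.raises(ValueError, match="nonnegative"):
            ed.propagate(lam0, hom, 0.3, [0, 1])


class TestFrontSpeed:
    def test_steep_front_matches_fisher_kpp_speed(self):
        """A compact release in a homogeneous 1-D corridor travels at the
        minimum logistic wave speed 2*sqrt(delta*gamma) (within 10%).

        Convergence to the asymptotic speed carries a slow O(1/(gamma*t))
        correction, so the run uses gamma*t up to ~35 and fits the late
        window.
        """
        land = corridor_landscape(450)
        delta_val, gamma, K = 5.8e6, 1.0, 2.0  # m^2/yr, 1/yr, per cell
        lam0, hom = _setup_propagation(land, beta0=np.log(delta_val), col=10, theta=60.0, kappa=2000.0)
        years = np.arange(3, 36)
        series = ed.propagate(lam0, hom, gamma, years, dt_days=2.0)
        x = _front_positions(series, land, level=K / 2)
        speed = np.polyfit(years[12:], x[12:], 1)[0]
        expected = 2.0 * np.sqrt(delta_val * gamma)
        assert speed == pytest.approx(expected, rel=0.10)

    def test_flat_front_speed_exceeds_minimum(self):
        """An exponential front with steepness s below sqrt(gamma/delta)
        keeps its shape and travels at delta*s + gamma/s (within 10%)."""
        land = corridor_landscape(450)
        delta_val, gamma, K = 5.8e6, 1.0, 2.0
        s = 0.5 * np.sqrt(gamma / delta_val)  # flat regime (per metre)
        beta = np.zeros(8)
        beta[0] = np.log(delta_val)
        delta = ed.motility_field(land, beta)
        Kf = ed.carrying_capacity_field(land, np.array([np.log(K), 0.0, 0.0]))
        hom = ed.homogenize(delta, Kf, 1.0, land.water_mask, land.cell_size_m)
        xs = np.arange(450) * land.cell_size_m
        lam0 = np.minimum(K, K * np.exp(-s * xs)).reshape(1, -1)
        years = np.arange(2, 19)
        series = ed.propagate(lam0, hom, gamma, years, dt_days=2.0)
        x = _front_positions(series, land, level=K / 2)
        speed = np.polyfit(years[4:], x[4:], 1)[0]
        expected = delta_val * s + gamma / s
        assert speed == pytest.approx(expected, rel=0.10)
        assert expected > 2.0 * np.sqrt(delta_val * gamma)


def _front_positions(series, land, level):
    """Interpolated x-position where the profile crosses `level` (metres)."""
    out = []
    xs = np.arange(land.water_mask.shape[1]) * land.cell_size_m
    for k in range(len(series.years)):
        prof = series.lambda_fine[k, 0]
        above = prof >= level
        assert above[0] and not above[-1], "front left the domain"
        i = int(np.nonzero(~above)[0][0]) - 1
        frac = (prof[i] - level) / (prof[i] - prof[i + 1])
        out.append(xs[i] + frac * land.cell_size_m)
    return np.array(out)


class TestCellIntensity:
    def test_uniform_density_identical_cells_and_partition_sum(self, open_water_landscape):
        lam0, hom = _setup_propagation(open_water_landscape, theta=90.0, kappa=1e9)
        series = ed.propagate(lam0, hom, 1e-300, [0, 3], dt_days=5.0)
        w = open_water_landscape.water_mask
        vals = series.lambda_fine[1][w]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-9)
        assert vals.sum() == pytest.approx(90.0, rel=1e-9)
        assert ed.cell_intensity(series, (3, 4), 3) == pytest.approx(vals[0])

    def test_land_cell_rejected(self, small_landscape):
        params_land = small_landscape
        li, lj = np.argwhere(~params_land.water_mask)[0]
        lam0 = np.zeros(params_land.water_mask.shape)
        wi, wj = params_land.water_indices()
        lam0[wi[0], wj[0]] = 1.0
        delta = ed.motility_field(params_land, np.concatenate([[np.log(4e6)], np.zeros(7)]))
        K = ed.carrying_capacity_field(params_land, np.zeros(3))
        hom = ed.homogenize(delta, K, 1.0, params_land.water_mask, params_land.cell_size_m)
        series = ed.propagate(lam0, hom, 0.2, [0, 1], dt_days=5.0)
        with pytest.raises(ValueError, match="water"):
            ed.cell_intensity(series, (int(li), int(lj)), 1)
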