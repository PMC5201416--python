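"""Spatial reaction-diffusion model: geometry, scenarios, solver physics."""

import numpy as np
import pytest

from il2field.doseresponse import default_profiles
from il2field.spatial import (
    MOLEC_UM3_TO_PM,
    Geometry,
    ModelParams,
    ScenarioSpec,
    SweepResult,
    Tissue,
    activation_fractions,
    assign_producers,
    calibrate_threshold,
    compare_scenarios,
    compute_k,
    place_cells,
    run_dose_sweep,
    solve_field,
    steady_state_field,
)


class TestComputeK:
    def test_half_saturation_identity(self):
        assert compute_k(0.1, 0.01, 0.01) == pytest.approx(0.2)
        # without internalization k reduces to the dissociation constant
        assert compute_k(0.1, 0.05, 0.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            compute_k(0.0, 0.1, 0.1)

    def test_params_expose_exact_identity(self):
        p = ModelParams(k_on=0.25, k_off=1.0, k_deg=3.0)
        assert p.k == (3.0 + 1.0) / 0.25


class TestPlaceCells:
    def test_determinism_and_geometry(self, small_geometry):
        a = place_cells(small_geometry, seed=1)
        b = place_cells(small_geometry, seed=1)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.population, b.population)
        r = np.hypot(a.centers[:, 0], a.centers[:, 1])
        assert np.all(r < small_geometry.domain_radius - small_geometry.cell_radius)
        # pairwise non-overlap
        d = np.sqrt(((a.centers[:, None] - a.centers[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * small_geometry.cell_radius
        n_treg = np.sum(a.population == "Treg")
        assert n_treg == round(small_geometry.treg_fraction * small_geometry.n_cells)

    def test_mean_nn_distance_matches_random_placement(self):
        """Mean nearest-neighbor distance matches an independent Monte-Carlo
        oracle of hard-core sequential random placement on the same disc."""
        geo = Geometry(domain_radius=150.0, n_cells=30, dx=4.0)
        r_eff = geo.domain_radius - geo.cell_radius - geo.dx
        min_d = 2 * geo.cell_radius + geo.min_gap

        def oracle_mean_nn(rng, n_rep=30):
            means = []
            for _ in range(n_rep):
                pts = []
                while len(pts) < geo.n_cells:
                    r = r_eff * np.sqrt(rng.random())
                    a = 2 * np.pi * rng.random()
                    p = (r * np.cos(a), r * np.sin(a))
                    if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_d ** 2
                           for q in pts):
                        pts.append(p)
                arr = np.asarray(pts)
                d = np.sqrt(((arr[:, None] - arr[None]) ** 2).sum(-1))
                np.fill_diagonal(d, np.inf)
                means.append(d.min(axis=1).mean())
            return np.mean(means)

        target = oracle_mean_nn(np.random.default_rng(99))
        means = []
        for seed in range(10):
            t = place_cells(geo, seed=seed)
            d = np.sqrt(((t.centers[:, None] - t.centers[None]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            means.append(d.min(axis=1).mean())
        assert np.mean(means) == pytest.approx(target, rel=0.15)

    def test_infeasible_density_errors(self):
        with pytest.raises(ValueError):
            Geometry(domain_radius=50.0, n_cells=500)


class TestAssignProducers:
    @pytest.mark.parametrize("a", [0.0, 0.1, 0.5, 1.0])
    def test_equal_total_secretion_between_modes(self, small_geometry, profiles, a):
        tissue = place_cells(small_geometry, seed=2)
        il2_max = 3.6e4
        b = assign_producers(tissue, profiles, ScenarioSpec("binary", a, 3), il2_max)
        g = assign_producers(tissue, profiles, ScenarioSpec("graded", a, 3), il2_max)
        assert abs(b.secretion_rate.sum() - g.secretion_rate.sum()) <= il2_max
        assert not b.producer[b.population == "Treg"].any()
        if a == 0.0:
            assert b.secretion_rate.sum() == g.secretion_rate.sum() == 0.0

    def test_binary_producers_uniform_over_th(self, small_geometry, profiles):
        """Producer choice is a uniformly random Th subset: each Th cell is
        selected with equal frequency over many seeds."""
        tissue = place_cells(small_geometry, seed=4)
        th = tissue.population == "Th"
        counts = np.zeros(tissue.n_cells)
        n_rep = 300
        for seed in range(n_rep):
            t = assign_producers(tissue, profiles, ScenarioSpec("binary", 0.5, seed),
                                 il2_max=1.0)
            counts += t.producer
        phi = profiles.phi.value(0.5)
        expect = round(phi * th.sum()) / th.sum()
        freq = counts[th] / n_rep
        se = np.sqrt(expect * (1 - expect) / n_rep)
        assert np.all(np.abs(freq - expect) < 5 * se)
        assert counts[~th].sum() == 0


def _solved(geometry, params, profiles, a=0.5, seed=5, **kw):
    t = place_cells(geometry, seed=seed)
    t = assign_producers(t, profiles, ScenarioSpec("binary", a, seed + 1),
                         il2_max=params.il2_max)
    return solve_field(t, params, profiles, a=a, dx=geometry.dx, **kw)


class TestSolveField:
    def test_no_producers_field_stays_zero(self, small_geometry, params, profiles):
        t = place_cells(small_geometry, seed=1)
        res = solve_field(t, params, profiles, a=0.0, t_end=6.0, dt=0.2,
                          dx=small_geometry.dx)
        assert res.secreted == 0.0
        assert np.all(res.final_field == 0.0)
        assert np.all(res.uptake == 0.0)

    def test_mass_balance_and_positivity(self, small_geometry, params, profiles):
        res = _solved(small_geometry, params, profiles, t_end=24.0, dt=0.1,
                      record_times=[6.0, 12.0])
        assert res.mass_balance_error < 0.005
        assert res.final_field.min() >= 0.0
        for _, field in res.fields:
            assert field.min() >= 0.0
        parts = res.consumed + res.degraded + res.rim_loss + res.residual_mass
        assert parts == pytest.approx(res.secreted, rel=1e-9)

    def test_producers_accumulate_no_uptake(self, small_geometry, params, profiles):
        res = _solved(small_geometry, params, profiles, t_end=12.0, dt=0.2)
        assert np.all(res.uptake[res.producer] == 0.0)
        assert res.uptake[~res.producer].max() > 0.0

    def test_single_producer_matches_poisson_disc_solution(self):
        """Quasi-steady profile of one secreting cell with no sinks equals the
        2D Poisson solution with a line source and absorbing rim."""
        params = ModelParams(d_ur=0.0)
        R = 100.0
        tissue = Tissue(domain_radius=R, centers=np.array([[0.0, 0.0]]),
                        radius=5.0, population=np.array(["Th"], dtype=object),
                        producer=np.array([True]),
                        secretion_rate=np.array([params.il2_max]))
        grid, u = steady_state_field(tissue, params, dx=2.0)
        q2d = params.il2_max * MOLEC_UM3_TO_PM / params.slab_thickness
        r = np.hypot(grid.x, grid.y)
        sel = (r > 2 * tissue.radius) & (r < 0.7 * R)
        analytic = q2d / (2 * np.pi * params.diffusion) * np.log(R / r[sel])
        assert np.max(np.abs(u[sel] - analytic) / analytic) < 0.05

    def test_consumption_saturates_at_high_concentration(self, small_geometry,
                                                         profiles):
        """When u >> k the per-cell uptake rate approaches IL2R_max * g."""
        params = ModelParams(il2_max=3.6e9, d_ur=0.0)   # flood the domain
        res = _solved(small_geometry, params, profiles, a=1.0, t_end=30.0, dt=0.1)
        cons = ~res.producer
        expect = {"Th": params.il2r_max["Th"], "Treg": params.il2r_max["Treg"]}
        # u >> k holds while secretion lasts (0-18 h); once it stops the
        # absorbing rim empties the small domain within minutes (tau ~
        # R^2/4D = 0.07 h), so the saturated-uptake window is the rising
        # half of T_rec: integral over 0..18 h = 9 h
        g_int = 9.0
        for pop in ("Th", "Treg"):
            sel = cons & (res.population == pop)
            assert np.median(res.uptake[sel]) == pytest.approx(
                expect[pop] * g_int, rel=0.1)

    def test_too_coarse_grid_rejected(self, small_geometry, params, profiles):
        t = place_cells(small_geometry, seed=1)
        with pytest.raises(ValueError):
            solve_field(t, params, profiles, a=0.5, dx=8.0)


class TestActivation:
    def test_threshold_extremes_and_monotonicity(self, rng):
        uptake = rng.exponential(100.0, size=300)
        pops = np.where(rng.random(300) < 0.2, "Treg", "Th").astype(object)
        assert activation_fractions(uptake, pops, 0.0)["Th"] == 1.0
        assert activation_fractions(uptake, pops, np.inf)["Treg"] == 0.0
        ths = np.sort(rng.uniform(0, 500, 20))
        fr = [activation_fractions(uptake, pops, t)["Th"] for t in ths]
        assert all(b <= a for a, b in zip(fr, fr[1:]))


@pytest.fixture(scope="module")
def tiny_sweep(profiles):
    params = ModelParams()
    geo = Geometry(domain_radius=100.0, n_cells=60, treg_fraction=0.15, dx=4.0)
    return params, run_dose_sweep("binary", [0.0, 0.25, 1.0], 2, params, geo,
                                  profiles, seed=9, t_end=30.0, dt=0.2)


class TestCalibration:
    def test_recovers_known_threshold(self, tiny_sweep):
        """Observations generated from the model at a known threshold are
        refit to an equivalent threshold: near-zero SSE, fractions matching
        within the search's plateau resolution."""
        _, sweep = tiny_sweep
        theta_true = float(np.median(np.concatenate(
            [r.uptake[r.uptake > 0] for r in sweep.uptakes[-1]])))
        observed = sweep.fractions(theta_true)
        fit = calibrate_threshold(sweep, observed)
        assert fit.sse <= 0.01
        refit = sweep.fractions(fit.threshold)
        for pop in observed:
            assert np.allclose(refit[pop], observed[pop], atol=0.06)

    def test_all_zero_observations_push_threshold_up(self, tiny_sweep):
        _, sweep = tiny_sweep
        fit = calibrate_threshold(sweep, {"Th": [0, 0, 0], "Treg": [0, 0, 0]})
        fr = sweep.fractions(fit.threshold)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)
        assert np.all(fr["Th"] == 0) and np.all(fr["Treg"] == 0)

    def test_empty_observations_error(self, tiny_sweep):
        _, sweep = tiny_sweep
        with pytest.raises(ValueError):
            calibrate_threshold(sweep, {})

    def test_identical_sweeps_give_identical_metrics(self, tiny_sweep):
        _, sweep = tiny_sweep
        clone = SweepResult(mode="graded", a_grid=sweep.a_grid,
                            uptakes=sweep.uptakes)
        rep = compare_scenarios(sweep, clone, threshold=100.0)
        b = rep[rep["mode"] == "binary"].drop(columns="mode").reset_index(drop=True)
        g = rep[rep["mode"] == "graded"].drop(columns="mode").reset_index(drop=True)
        assert b.equals(g)
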