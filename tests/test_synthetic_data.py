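"""Generators: closed-form agreement, reproducibility, ground-truth checks."""

import numpy as np
import pytest

from ribomech.landscape import FreeEnergySurface
from ribomech.ph_profiles import model_single_pka
from ribomech.sampling_fe import UmbrellaWindow, alchemical_ddg
from ribomech.synthetic_data import (
    GaussianComponent,
    KineticsSpec,
    LangevinSpec,
    SurfaceSpec,
    gen_alchemical_samples,
    gen_biased_trajectories,
    gen_ph_rate_data,
    gen_surface,
    gen_time_course,
    mtr1_surface_spec,
)
from .oracles import dijkstra_minimax, fep_forward
from .conftest import grid_index


class TestTimeCourses:
    def test_no_reaction_at_time_zero(self):
        spec = KineticsSpec(0.60, 0.01, 0.8, 1.0, (0.0, 1.0, 2.0), 0.0, 0)
        assert gen_time_course(spec).fractions[0] == 0.0

    def test_plateau_at_long_times(self):
        spec = KineticsSpec(0.60, 0.01, 0.8, 1.0, (1.0, 1e4), 0.0, 0)
        assert gen_time_course(spec).fractions[-1] == pytest.approx(1.0, abs=1e-6)

    def test_half_completion_of_fast_phase(self):
        # t = ln2 / k_fast for the unmodified-ribozyme rate 0.60 /min
        t_half = np.log(2) / 0.60
        spec = KineticsSpec(0.60, 0.01, 0.8, 1.0, (t_half,), 0.0, 0)
        y = gen_time_course(spec).fractions[0]
        expected = 0.5 * 0.8 * 1.0 + 0.2 * (1 - np.exp(-0.01 * t_half))
        assert y == pytest.approx(expected, abs=1e-10)

    def test_noise_free_matches_model_everywhere(self):
        t = np.geomspace(0.1, 100, 30)
        spec = KineticsSpec(0.5, 0.002, 0.7, 0.95, tuple(t), 0.0, 0)
        y = gen_time_course(spec).fractions
        expected = 0.95 * (0.7 * (1 - np.exp(-0.5 * t))
                           + 0.3 * (1 - np.exp(-0.002 * t)))
        np.testing.assert_allclose(y, expected, atol=1e-10)

    def test_seeded_reproducibility(self):
        spec = KineticsSpec(0.6, 0.01, 0.8, 1.0, tuple(np.linspace(1, 30, 10)),
                            0.02, 99)
        a = gen_time_course(spec).fractions
        b = gen_time_course(spec).fractions
        np.testing.assert_array_equal(a, b)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            KineticsSpec(0.01, 0.60, 0.8, 1.0, (1.0,), 0.0, 0)  # k_fast < k_slow
        with pytest.raises(ValueError):
            KineticsSpec(0.6, 0.01, 1.4, 1.0, (1.0,), 0.0, 0)
        with pytest.raises(ValueError):
            KineticsSpec(0.6, 0.01, 0.8, 1.0, (2.0, 1.0), 0.0, 0)


class TestPhRateData:
    def test_half_rate_at_pka(self):
        ds = gen_ph_rate_data(1.0, 6.4, [6.4], cv=0.0, n_reps=1)
        assert ds.data["k_obs"].iloc[0] == pytest.approx(0.5, rel=1e-12)

    def test_fully_protonated_limit(self):
        ds = gen_ph_rate_data(1.0, 6.4, [2.0], cv=0.0, n_reps=1)
        assert ds.data["k_obs"].iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_noise_free_equals_model_pointwise(self):
        grid = np.arange(5.5, 8.51, 0.5)
        ds = gen_ph_rate_data(0.84, 6.4, grid, cv=0.0, n_reps=3, seed=1)
        for rep in range(3):
            sub = ds.data[ds.data["replicate"] == rep].sort_values("pH")
            np.testing.assert_allclose(
                sub["k_obs"], model_single_pka(grid, 0.84, 6.4), atol=1e-12)

    def test_lognormal_noise_median_unbiased(self):
        grid = [6.0]
        ds = gen_ph_rate_data(1.0, 3.0, grid, cv=0.2, n_reps=4000, seed=7)
        med = np.median(ds.data["k_obs"])
        assert med == pytest.approx(model_single_pka(6.0, 1.0, 3.0), rel=0.02)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError, match="cv"):
            gen_ph_rate_data(1.0, 6.4, [6.0], cv=-0.1)


class TestSurfaces:
    def test_single_bowl_minimum_at_origin(self):
        spec = SurfaceSpec((GaussianComponent(0.0, 0.0, -5.0, 1.0, 1.0),),
                           extent_pt=(-2, 2), extent_at=(-2, 2), grid_spacing=0.05)
        surf = gen_surface(spec)
        i, j = np.unravel_index(np.argmin(surf.values), surf.values.shape)
        assert surf.axis_pt[i] == pytest.approx(0.0, abs=0.05)
        assert surf.values.min() == pytest.approx(0.0, abs=1e-12)

    def test_mirrored_spec_is_point_reflection(self):
        comps = (GaussianComponent(-1.0, -1.5, -4.0, 0.7, 0.7),
                 GaussianComponent(1.0, 1.5, -6.0, 0.7, 0.7))
        mirrored = tuple(GaussianComponent(-c.center_pt, -c.center_at, c.depth,
                                           c.width_pt, c.width_at) for c in comps)
        kw = dict(extent_pt=(-3, 3), extent_at=(-3, 3), grid_spacing=0.1)
        a = gen_surface(SurfaceSpec(comps, **kw))
        b = gen_surface(SurfaceSpec(mirrored, **kw))
        np.testing.assert_allclose(a.values, b.values[::-1, ::-1], atol=1e-9)

    def test_preset_barrier_matches_grid_path_oracle(self, mtr1_surface):
        barrier, _ = dijkstra_minimax(
            mtr1_surface.values,
            grid_index(mtr1_surface, (-1.5, -2.5)),
            grid_index(mtr1_surface, (1.5, 2.5)))
        assert barrier == pytest.approx(16.3, abs=0.15)

    def test_preset_barrier_is_configurable(self):
        surf = gen_surface(mtr1_surface_spec(barrier=12.0))
        barrier, _ = dijkstra_minimax(
            surf.values, grid_index(surf, (-1.5, -2.5)),
            grid_index(surf, (1.5, 2.5)))
        assert barrier == pytest.approx(12.0, abs=0.15)

    def test_empty_component_list_rejected(self):
        with pytest.raises(ValueError, match="component"):
            SurfaceSpec(())

    def test_component_outside_grid_warns(self):
        spec = SurfaceSpec((GaussianComponent(0.0, 0.0, -5.0, 1.0, 1.0),
                            GaussianComponent(10.0, 0.0, 2.0, 1.0, 1.0)),
                           extent_pt=(-2, 2), extent_at=(-2, 2))
        with pytest.warns(UserWarning, match="outside"):
            gen_surface(spec)


@pytest.fixture(scope="module")
def harmonic_surface():
    k = 2.0
    ax = np.linspace(-2.5, 2.5, 101)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    return FreeEnergySurface(ax, ax, 0.5 * k * (xx**2 + yy**2))


class TestLangevin:
    def test_stationary_gaussian_statistics(self, harmonic_surface):
        # var = kT (k_surface + k_bias)^-1 for a harmonic surface + bias
        kT, k_s, k_b = 0.5925, 2.0, 10.0
        w = UmbrellaWindow((0.0, 0.0), (k_b, k_b), n_samples=50000)
        (traj,) = gen_biased_trajectories(
            harmonic_surface, [w],
            LangevinSpec(kT=kT, step_size=0.002, n_steps=50000, seed=1))
        var_expected = kT / (k_s + k_b)
        se_mean = np.sqrt(var_expected / 2000)  # generous effective n
        assert np.abs(traj.samples.mean(axis=0)).max() < 3 * se_mean * 3
        np.testing.assert_allclose(traj.samples.var(axis=0), var_expected,
                                   rtol=0.15)

    def test_zero_temperature_collapse(self, harmonic_surface):
        w = UmbrellaWindow((0.5, 0.5), (50.0, 50.0))
        (traj,) = gen_biased_trajectories(
            harmonic_surface, [w],
            LangevinSpec(kT=1e-6, step_size=0.002, n_steps=2000, seed=1))
        # biased minimum of 0.5*k_s x^2 + 0.5*k_b (x-c)^2
        x_min = 50.0 * 0.5 / (50.0 + 2.0)
        np.testing.assert_allclose(traj.samples[-1], [x_min, x_min], atol=1e-3)
        assert traj.samples.std(axis=0).max() < 1e-2

    def test_identical_seeds_bit_identical(self, harmonic_surface):
        w = UmbrellaWindow((0.0, 0.0), (10.0, 10.0))
        spec = LangevinSpec(kT=0.6, n_steps=2000, seed=42)
        a = gen_biased_trajectories(harmonic_surface, [w], spec)[0].samples
        b = gen_biased_trajectories(harmonic_surface, [w], spec)[0].samples
        assert np.array_equal(a, b)

    def test_overlarge_step_errors_with_advice(self, harmonic_surface):
        w = UmbrellaWindow((0.0, 0.0), (500.0, 500.0))
        with pytest.raises(ValueError, match="step_size"):
            gen_biased_trajectories(
                harmonic_surface, [w],
                LangevinSpec(kT=0.6, step_size=5.0, n_steps=500, seed=0))


class TestAlchemical:
    def test_null_transformation(self):
        ds = gen_alchemical_samples(0.0, 25, 300, seed=3)
        ddg, se = alchemical_ddg(ds)
        assert abs(ddg) < 3 * se

    def test_known_difference_recovered(self):
        # 2.86 kcal/mol is the 2.1-pKa-unit shift at 298.15 K
        ds = gen_alchemical_samples(2.86, 25, 400, seed=11)
        ddg, se = alchemical_ddg(ds)
        assert abs(ddg - 2.86) < 3 * se

    def test_two_windows_match_fep_oracle(self):
        from ribomech.constants import RT
        ds = gen_alchemical_samples(1.0, 2, 4000, overlap=2.0, seed=5)
        ddg, se = alchemical_ddg(ds)
        n = 4000
        w_f = ds.u_kn[1, :n] - ds.u_kn[0, :n]  # forward work from state 0
        ddg_fep = fep_forward(w_f) * RT(ds.temperature)
        assert abs(ddg - ddg_fep) < 3 * se

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gen_alchemical_samples(1.0, 5, 100, overlap=0.0)
        with pytest.raises(ValueError, match="windows"):
            gen_alchemical_samples(1.0, 1, 100)
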