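"""Thickness, diffusion and bending-rigidity estimators."""

import numpy as np
import pytest

import memfission as mf
from memfission import membrane as mb


class TestBlockStatistics:
    def test_constant_series_has_zero_error(self):
        mean, se = mf.block_statistics(np.full(50, 3.3), n_blocks=5)
        assert mean == pytest.approx(3.3) and se == 0.0

    def test_hand_computed_two_blocks(self):
        mean, se = mf.block_statistics([1.0, 1.0, 2.0, 2.0], n_blocks=2)
        assert mean == pytest.approx(1.5)
        assert se == pytest.approx(0.5)

    def test_iid_normal_calibration(self):
        # for iid data the block stderr should estimate 1/sqrt(N); 20 blocks
        # keep the χ² spread of the estimate itself inside a factor 1.5
        hits = 0
        for seed in range(100):
            v = np.random.default_rng(seed).standard_normal(10_000)
            _, se = mf.block_statistics(v, n_blocks=20)
            if 1 / 1.5 <= se * np.sqrt(10_000) <= 1.5:
                hits += 1
        assert hits >= 95

    def test_too_few_blocks_raises(self):
        with pytest.raises(ValueError):
            mf.block_statistics([1.0, 2.0, 3.0], n_blocks=1)


class TestThickness:
    @pytest.mark.parametrize("sep", [36.33, 39.15, 37.58, 40.69])
    @pytest.mark.parametrize("grid", [(1, 1), (40, 40)])
    def test_exact_plane_separation(self, sep, grid):
        series = mf.gen_flat_bilayer(300, thickness=sep, z_jitter=0.0, seed=4)
        labels = mf.assign_leaflets_series(series)
        res = mf.grid_thickness(series, labels, *grid)
        assert res.mean == pytest.approx(sep, abs=1e-9)
        assert res.stderr == 0.0

    def test_jittered_mean_within_error(self):
        series = mf.gen_flat_bilayer(100, thickness=36.33, z_jitter=0.5,
                                     seed=1, n_frames=20)
        labels = mf.assign_leaflets_series(series)
        res = mf.grid_thickness(series, labels)
        assert abs(res.mean - 36.33) <= max(3 * res.stderr, 0.05)

    def test_translation_and_relabeling_invariance(self, flat_bilayer):
        labels = mf.assign_leaflets_series(flat_bilayer)
        base = mf.grid_thickness(flat_bilayer, labels).mean
        shifted = mf.FrameSeries(flat_bilayer.times,
                                 flat_bilayer.coords + [13.0, -7.0, 100.0],
                                 flat_bilayer.boxes, flat_bilayer.particles)
        lab2 = mf.assign_leaflets_series(shifted)
        assert mf.grid_thickness(shifted, lab2).mean == pytest.approx(base)
        # reverse particle order
        perm = np.arange(flat_bilayer.n_particles)[::-1]
        from memfission.trajectory_io import ParticleTable
        p = flat_bilayer.particles
        table = ParticleTable(np.arange(len(p)), p.lipid_id[perm],
                              p.species[perm], p.bead_role[perm])
        rev = mf.FrameSeries(flat_bilayer.times,
                             flat_bilayer.coords[:, perm, :],
                             flat_bilayer.boxes, table)
        lab3 = mf.assign_leaflets_series(rev)
        assert mf.grid_thickness(rev, lab3).mean == pytest.approx(base)

    def test_degenerate_grid_equals_global_com(self, flat_bilayer):
        labels = mf.assign_leaflets_series(flat_bilayer)
        res = mf.grid_thickness(flat_bilayer, labels, 1, 1)
        tags = flat_bilayer.provenance["leaflet_tags"]
        z = flat_bilayer.coords[0, :, 2]
        expect = z[tags == 1].mean() - z[tags == -1].mean()
        assert res.mean == pytest.approx(expect)


class TestMSD:
    def test_three_four_five(self):
        coords = np.zeros((2, 1, 3))
        coords[1, 0] = [3.0, 4.0, 0.0]
        from tests.test_trajectory_io import make_series
        s = make_series(coords, np.tile([100.0, 100, 100], (2, 1)),
                        times=[0.0, 50.0])
        msd = mf.lateral_msd(s, max_lag_fraction=1.0)
        assert msd.msd[0] == 0.0
        assert msd.msd[1] == pytest.approx(25.0)
        assert msd.lag_times[1] == pytest.approx(50.0)

    def test_static_series_is_zero(self):
        from tests.test_trajectory_io import make_series
        s = make_series(np.ones((20, 5, 3)), np.tile([50.0, 50, 50], (20, 1)))
        msd = mf.lateral_msd(s)
        np.testing.assert_allclose(msd.msd, 0.0, atol=1e-12)

    def test_nonuniform_spacing_rejected(self):
        from tests.test_trajectory_io import make_series
        s = make_series(np.zeros((3, 2, 3)), np.tile([50.0, 50, 50], (3, 1)),
                        times=[0.0, 1.0, 3.0])
        with pytest.raises(ValueError, match="spacing"):
            mf.lateral_msd(s)

    def test_brownian_msd_matches_4dt(self, brownian_series):
        u = mf.unwrap_coordinates(brownian_series, axes=("x", "y"))
        msd = mf.lateral_msd(u)
        D = brownian_series.provenance["spec"]["parameters"]["D"] * 1e-4
        n = brownian_series.n_particles
        for lag in range(1, 11):
            tau = msd.lag_times[lag]
            expect = 4 * D * tau
            # var of a χ²-like MSD estimate over n independent lipids
            se = expect * np.sqrt(2.0 / (2 * n))
            assert abs(msd.msd[lag] - expect) <= 3 * se


class TestFitDiffusion:
    def _curve(self, slope, intercept=0.0):
        t = np.arange(0.0, 101.0, 1.0)
        return mb.MSDCurve(lag_times=t, msd=slope * t + intercept,
                           n_pairs=np.full(t.size, 100))

    def test_closed_form(self):
        est = mf.fit_diffusion(self._curve(0.04), (10.0, 90.0))
        assert est.D_L == pytest.approx(100.0)
        assert est.r_squared == pytest.approx(1.0)

    def test_intercept_absorbed(self):
        est = mf.fit_diffusion(self._curve(0.04, 2.0), (10.0, 90.0))
        assert est.D_L == pytest.approx(100.0)

    def test_negative_slope_clamped(self):
        est = mf.fit_diffusion(self._curve(-0.01), (10.0, 90.0))
        assert est.D_L == 0.0 and est.negative_slope

    @pytest.mark.parametrize("D", [10.0, 50.0, 100.0])
    def test_brownian_recovery(self, D):
        series = mf.gen_brownian_lipids(n=1000, D=D, n_frames=500, seed=11)
        u = mf.unwrap_coordinates(series, axes=("x", "y"))
        msd = mf.lateral_msd(u)
        est = mf.fit_diffusion(msd)
        assert abs(est.D_L - D) / D <= 0.05


class TestHeightField:
    def test_flat_field_is_zero(self, flat_bilayer):
        labels = mf.assign_leaflets_series(flat_bilayer)
        hf = mf.height_field(flat_bilayer, labels, grid_m=8)
        np.testing.assert_allclose(hf.grids, 0.0, atol=1e-9)

    def test_single_cosine_mode_recovered(self):
        # beads at cell centres carrying h = A cos(2πx/L)
        L, M, A = 320.0, 32, 5.0
        series, fields = mf.gen_helfrich_membrane(L=L, grid_m=M, K_C=1e9,
                                                  n_frames=2, seed=0)
        x = (np.arange(M) + 0.5) * (L / M)
        imposed = A * np.cos(2 * np.pi * x / L)
        coords = series.coords.copy()
        per_leaflet = M * M
        grid_h = np.repeat(imposed, M)
        coords[:, :per_leaflet, 2] += grid_h
        coords[:, per_leaflet:, 2] += grid_h
        s2 = mf.FrameSeries(series.times, coords, series.boxes,
                            series.particles, series.provenance)
        labels = mf.assign_leaflets_series(s2)
        hf = mf.height_field(s2, labels, grid_m=M)
        expect = np.tile(grid_h.reshape(M, M), (2, 1, 1))
        expect -= expect.mean(axis=(1, 2), keepdims=True)
        assert np.abs(hf.grids - expect).max() < 0.1

    def test_generator_grid_recovered_exactly(self):
        series, fields = mf.gen_helfrich_membrane(L=320.0, grid_m=16,
                                                  K_C=25.0, n_frames=12,
                                                  seed=5)
        labels = mf.assign_leaflets_series(series)
        hf = mf.height_field(series, labels, grid_m=16)
        np.testing.assert_allclose(hf.grids, fields.grids, atol=1e-9)

    def test_too_fine_grid_rejected(self, flat_bilayer):
        labels = mf.assign_leaflets_series(flat_bilayer)
        with pytest.raises(ValueError, match="coarser"):
            mf.height_field(flat_bilayer, labels, grid_m=64)


class TestSpectrum:
    def test_zero_field_zero_spectrum(self):
        fields = mb.HeightFieldSeries(grids=np.zeros((12, 16, 16)),
                                      cell_size=10.0, box_area=160.0 ** 2)
        spec = mf.fluctuation_spectrum(fields)
        np.testing.assert_allclose(spec.s_q, 0.0)

    def test_single_cosine_weight(self):
        L, M, A = 320.0, 32, 5.0
        x = (np.arange(M) + 0.5) * (L / M)
        g = np.tile(A * np.cos(2 * np.pi * x / L)[:, None], (1, M))
        grids = np.tile(g[None], (12, 1, 1))
        grids -= grids.mean(axis=(1, 2), keepdims=True)
        fields = mb.HeightFieldSeries(grids=grids, cell_size=L / M,
                                      box_area=L * L)
        spec = mf.fluctuation_spectrum(fields)
        i = int(np.argmin(np.abs(spec.q - 2 * np.pi / L)))
        # the ± cosine mode pair carries A²·box_area/4 each; all other modes 0
        total = spec.s_q * spec.n_q
        assert total[i] == pytest.approx(2 * A ** 2 * L * L / 4, rel=1e-6)
        assert np.all(total[np.arange(total.size) != i] <
                      1e-9 * total[i])

    def test_helfrich_equipartition(self, helfrich_fields):
        spec = mf.fluctuation_spectrum(helfrich_fields)
        A = helfrich_fields.box_area
        for b in range(5):
            expect = 1.0 / (A * 25.0 * spec.q[b] ** 4)
            n_eff = spec.n_q[b] * spec.n_frames / 2
            se = expect / np.sqrt(n_eff)
            assert abs(spec.s_q[b] - expect) <= 3 * se


class TestRigidityFit:
    def _spectrum(self, kc, sigma, A=400.0 ** 2):
        q = (np.arange(1, 9)) * 2 * np.pi / 400.0
        s = 1.0 / (A * (kc * q ** 4 + sigma * q ** 2))
        return mb.UndulationSpectrum(q=q, s_q=s, n_q=np.full(8, 4),
                                     n_frames=100, box_area=A)

    def test_noiseless_inversion(self):
        est = mf.fit_bending_rigidity(self._spectrum(20.0, 0.0), 400.0 ** 2,
                                      q_max=1.0, include_tension=False)
        assert est.K_C == pytest.approx(20.0)
        assert est.sigma == 0.0

    def test_noiseless_with_tension(self):
        est = mf.fit_bending_rigidity(self._spectrum(20.0, 1e-3), 400.0 ** 2,
                                      q_max=1.0, include_tension=True)
        assert est.K_C == pytest.approx(20.0, rel=1e-6)
        assert est.sigma == pytest.approx(1e-3, rel=1e-4)

    def test_inconsistent_spectrum_raises(self):
        spec = self._spectrum(20.0, 0.0)
        spec.s_q = spec.s_q[::-1]  # rising spectrum: not Helfrich-like
        with pytest.raises(ValueError, match="Helfrich"):
            mf.fit_bending_rigidity(spec, 400.0 ** 2, q_max=1.0)

    def test_recovery_from_fixture(self, helfrich_fields):
        spec = mf.fluctuation_spectrum(helfrich_fields)
        est = mf.fit_bending_rigidity(spec, helfrich_fields.box_area,
                                      mf.default_q_max(38.0))
        assert abs(est.K_C - 25.0) / 25.0 <= 0.10
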