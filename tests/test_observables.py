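"""Analysis estimators against constructed fixtures and synthetic oracles."""

import numpy as np
import pytest

from nanospin.forcefield import BeadKind
from nanospin.observables import (AnalysisError, ObservableSeries,
                                  bending_stiffness, diffusion_coefficient,
                                  fluctuation_spectrum, height_field,
                                  leaflet_planes, lipid_density_map, msd,
                                  penetrated_count, pore_area,
                                  stretching_modulus,
                                  synthetic_helfrich_frames)
from nanospin.system import Frame, Trajectory


def make_frame(positions, kinds, box=(20.0, 20.0, 60.0), unwrapped=None,
               time=0.0):
    positions = np.asarray(positions, dtype=float)
    return Frame(time=time, step=int(time), box=np.asarray(box, float),
                 positions=positions,
                 unwrapped=positions.copy() if unwrapped is None
                 else np.asarray(unwrapped, float),
                 kinds=np.asarray(kinds, dtype=np.int64),
                 molecule_id=np.zeros(len(positions), dtype=np.int64))


def slab_frame(n=400, box=20.0, z0=30.0, seed=0, kinds_value=BeadKind.HEAD):
    rng = np.random.default_rng(seed)
    pos = np.column_stack([rng.uniform(0, box, n), rng.uniform(0, box, n),
                           np.full(n, z0) + rng.normal(0, 0.3, n)])
    return make_frame(pos, np.full(n, int(kinds_value)), (box, box, 60.0))


class TestDensityMap:
    def test_conserves_bead_count(self):
        fr = slab_frame(500)
        grid, ca = lipid_density_map(fr, cell=2.0)
        assert grid.sum() * ca == pytest.approx(500)

    def test_uniform_membrane_moderate_variation(self):
        """An intact membrane has ~5 beads/sigma^2 projected (3 beads,
        two leaflets, ~1.2 sigma^2/lipid), i.e. ~20 per 2-sigma cell;
        Poisson counting then keeps the CV well below the pore regime."""
        fr = slab_frame(8000, box=40.0)
        grid, _ = lipid_density_map(fr, cell=2.0)
        cv = grid.std() / grid.mean()
        assert cv < 0.3

    def test_empty_box(self):
        fr = make_frame(np.zeros((0, 3)), np.zeros(0))
        grid, _ = lipid_density_map(fr, cell=2.0)
        assert np.all(grid == 0)

    def test_cell_size_bounds(self):
        with pytest.raises(AnalysisError):
            lipid_density_map(slab_frame(), cell=0.5)


class TestPoreArea:
    def test_constructed_hole(self):
        """A 5x5 empty block on a uniform grid at 2-sigma cells is a
        100-sigma^2 pore."""
        grid = np.full((10, 10), 5.0)
        grid[2:7, 2:7] = 0.0
        out = pore_area(grid, cell_area=4.0, threshold_fraction=0.25,
                        reference_density=5.0)
        assert out["total_area"] == pytest.approx(100.0)
        assert out["largest_area"] == pytest.approx(100.0)
        assert out["n_components"] == 1

    def test_intact_grid_scores_zero(self):
        grid = np.full((10, 10), 5.0)
        out = pore_area(grid, cell_area=4.0, threshold_fraction=0.25)
        assert out["total_area"] == 0.0

    def test_fully_empty_grid_is_whole_box(self):
        grid = np.zeros((10, 10))
        out = pore_area(grid, cell_area=4.0, threshold_fraction=0.25,
                        reference_density=5.0)
        assert out["total_area"] == pytest.approx(400.0)

    def test_two_holes_largest_vs_total(self):
        grid = np.full((12, 12), 5.0)
        grid[1:3, 1:3] = 0.0   # 4 cells
        grid[8:9, 8:10] = 0.0  # 2 cells
        out = pore_area(grid, cell_area=4.0, threshold_fraction=0.25,
                        reference_density=5.0)
        assert out["n_components"] == 2
        assert out["total_area"] == pytest.approx(24.0)
        assert out["largest_area"] == pytest.approx(16.0)

    def test_validation(self):
        with pytest.raises(AnalysisError):
            pore_area(np.zeros((0, 0)), 4.0)
        with pytest.raises(AnalysisError):
            pore_area(np.ones((4, 4)), 4.0, threshold_fraction=1.5)


class TestPenetration:
    def _bilayer_frame(self, cargo_z):
        rng = np.random.default_rng(1)
        n = 200
        pos_up = np.column_stack([rng.uniform(0, 20, n),
                                  rng.uniform(0, 20, n), np.full(n, 32.0)])
        pos_lo = pos_up.copy()
        pos_lo[:, 2] = 28.0
        cargo = np.column_stack([rng.uniform(0, 20, len(cargo_z)),
                                 rng.uniform(0, 20, len(cargo_z)),
                                 np.asarray(cargo_z, float)])
        pos = np.vstack([pos_up, pos_lo, cargo])
        kinds = np.concatenate([
            np.full(2 * n, int(BeadKind.HEAD)),
            np.full(len(cargo_z), int(BeadKind.CARGO))])
        return make_frame(pos, kinds)

    def test_all_cis_is_zero(self):
        fr = self._bilayer_frame([40.0, 45.0, 50.0])
        assert penetrated_count(fr, margin=1.0) == 0

    def test_three_translocated(self):
        fr = self._bilayer_frame([40.0, 20.0, 21.0, 25.0, 45.0])
        assert penetrated_count(fr, margin=1.0) == 3

    def test_unreachable_margin(self):
        fr = self._bilayer_frame([20.0])
        assert penetrated_count(fr, margin=100.0) == 0

    def test_no_lipids_raises(self):
        fr = make_frame([[1, 1, 1]], [int(BeadKind.CARGO)])
        with pytest.raises(AnalysisError):
            penetrated_count(fr)

    def test_leaflet_planes(self):
        fr = self._bilayer_frame([])
        up, lo = leaflet_planes(fr)
        assert up == pytest.approx(32.0)
        assert lo == pytest.approx(28.0)


def _walker_trajectory(X, box=100.0, kinds_value=BeadKind.CARGO):
    """Trajectory from an (T, n, 3) unwrapped position array."""
    traj = Trajectory()
    for t in range(X.shape[0]):
        pos = X[t] % box
        traj.frames.append(Frame(
            time=float(t), step=t, box=np.array([box, box, box]),
            positions=pos, unwrapped=X[t].copy(),
            kinds=np.full(X.shape[1], int(kinds_value), dtype=np.int64),
            molecule_id=np.zeros(X.shape[1], dtype=np.int64)))
    return traj


class TestMSD:
    def test_static_configuration_zero(self):
        X = np.tile(np.random.default_rng(0).uniform(0, 50, (1, 20, 3)),
                    (10, 1, 1))
        s = msd(_walker_trajectory(X), np.arange(20))
        assert np.allclose(s.values, 0.0)

    def test_ballistic_closed_form(self):
        v = np.array([0.3, -0.2, 0.5])
        t = np.arange(30)[:, None, None]
        X = np.zeros((30, 5, 3)) + v * t
        s = msd(_walker_trajectory(X), np.arange(5))
        expected = (v @ v) * s.times**2
        assert np.allclose(s.values, expected, rtol=1e-10)

    def test_axis_mask_selects_z(self):
        X = np.zeros((20, 4, 3))
        X[:, :, 0] = np.arange(20)[:, None]  # motion only along x
        s = msd(_walker_trajectory(X), np.arange(4), axis_mask=(0, 0, 1))
        assert np.allclose(s.values, 0.0)

    def test_brownian_recovery_within_ten_percent(self):
        """500 random walkers with D = 0.01 per axis: the z-axis MSD slope
        over the central window recovers D."""
        rng = np.random.default_rng(42)
        D, dt, T, n = 0.01, 1.0, 200, 500
        steps = rng.normal(0, np.sqrt(2 * D * dt), (T, n, 3))
        X = np.cumsum(steps, axis=0)
        s = msd(_walker_trajectory(X), np.arange(n), axis_mask=(0, 0, 1))
        out = diffusion_coefficient(s, dimensionality=1,
                                    fit_window=(5, 80))
        assert out["D"] == pytest.approx(D, rel=0.10)

    def test_empty_selection(self):
        X = np.zeros((5, 3, 3))
        with pytest.raises(AnalysisError):
            msd(_walker_trajectory(X), np.zeros(3, dtype=bool))


class TestDiffusionCoefficient:
    def test_exact_line(self):
        t = np.linspace(1, 50, 50)
        s = ObservableSeries("msd", t, 4 * 0.01 * t)
        assert diffusion_coefficient(s, 2)["D"] == pytest.approx(0.01)

    def test_single_point_window_rejected(self):
        t = np.linspace(1, 50, 50)
        s = ObservableSeries("msd", t, 4 * 0.01 * t)
        with pytest.raises(AnalysisError):
            diffusion_coefficient(s, 2, fit_window=(10.0, 10.5))

    def test_negative_slope_warns(self):
        t = np.linspace(1, 50, 50)
        s = ObservableSeries("msd", t, -t)
        assert diffusion_coefficient(s, 2)["warning"] is not None


class TestBendingStiffness:
    def test_helfrich_recovery(self):
        """Surfaces sampled from a kappa = 10 spectrum are recovered
        within 15%."""
        traj = synthetic_helfrich_frames(kappa=10.0, L=40.0, n_cells=16,
                                         n_frames=400, seed=3)
        out = bending_stiffness(traj, n_cells=16, temperature=1.1)
        assert out["kappa"] == pytest.approx(10.0, rel=0.15)
        assert out["q4_consistent"]

    def test_white_noise_flagged(self):
        rng = np.random.default_rng(0)
        traj = Trajectory()
        L, nc = 40.0, 16
        cell = L / nc
        xs = (np.arange(nc) + 0.5) * cell
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        for t in range(80):
            h = rng.normal(0, 1.0, (nc, nc))
            pos = np.column_stack([gx.ravel(), gy.ravel(), h.ravel()])
            traj.frames.append(Frame(
                time=float(t), step=t, box=np.array([L, L, 100.0]),
                positions=pos, unwrapped=pos.copy(),
                kinds=np.full(len(pos), int(BeadKind.HEAD), dtype=np.int64),
                molecule_id=np.zeros(len(pos), dtype=np.int64)))
        out = bending_stiffness(traj, n_cells=nc, temperature=1.1,
                                min_frames=50)
        assert not out["q4_consistent"]

    def test_area_scaling_leaves_kappa_unchanged(self):
        """Doubling the box area at fixed kappa halves per-mode amplitude
        but the estimate is unchanged (within statistics)."""
        a = bending_stiffness(synthetic_helfrich_frames(8.0, 30.0, 16, 300,
                                                        seed=5),
                              n_cells=16, temperature=1.1)
        b = bending_stiffness(synthetic_helfrich_frames(8.0, 30.0 * np.sqrt(2),
                                                        16, 300, seed=6),
                              n_cells=16, temperature=1.1)
        assert a["kappa"] == pytest.approx(b["kappa"], rel=0.2)

    def test_too_few_frames(self):
        traj = synthetic_helfrich_frames(10.0, 40.0, 8, 10, seed=0)
        with pytest.raises(AnalysisError, match="frames"):
            bending_stiffness(traj, min_frames=50)


class TestStretchingModulus:
    def test_closed_form_gaussian_series(self):
        """A Gaussian area series with <A> = 1000 and Var = 41.7 gives
        K_A = 1.1*1000/41.7 ~ 26.4 (the closed form, evaluated on the
        sample statistics)."""
        rng = np.random.default_rng(0)
        a = rng.normal(1000.0, np.sqrt(41.7), 20000)
        out = stretching_modulus(a, temperature=1.1)
        expected = 1.1 * a.mean() / a.var()
        # white noise: tau_int ~ 1/2 sample, so the finite-window
        # debiasing is a ~1e-4 relative effect here
        assert out["K_A"] == pytest.approx(expected, rel=1e-3)
        assert out["K_A"] == pytest.approx(26.4, rel=0.05)

    def test_constant_area_rejected(self):
        with pytest.raises(AnalysisError, match="barostat"):
            stretching_modulus(np.full(100, 900.0))

    def test_halved_variance_doubles_modulus(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0.0, 1.0, 5000)
        a1 = 1000.0 + base
        a2 = 1000.0 + base / np.sqrt(2)
        k1 = stretching_modulus(a1)["K_A"]
        k2 = stretching_modulus(a2)["K_A"]
        assert k2 == pytest.approx(2 * k1, rel=1e-2)


class TestEstimatorInvariances:
    def test_rigid_translation(self):
        fr = slab_frame(8000, box=40.0)
        grid1, ca = lipid_density_map(fr, 2.0)
        shifted = make_frame((fr.positions + np.array([3.0, 5.0, 2.0]))
                             % np.array([40.0, 40.0, 60.0]),
                             fr.kinds, (40.0, 40.0, 60.0))
        grid2, _ = lipid_density_map(shifted, 2.0)
        p1 = pore_area(grid1, ca)
        p2 = pore_area(grid2, ca)
        assert p1["total_area"] == pytest.approx(p2["total_area"], abs=16.0)

    def test_index_relabeling(self):
        fr = slab_frame(300, box=20.0)
        perm = np.random.default_rng(2).permutation(300)
        fr2 = make_frame(fr.positions[perm], fr.kinds[perm])
        g1, ca = lipid_density_map(fr, 2.0)
        g2, _ = lipid_density_map(fr2, 2.0)
        assert np.array_equal(g1, g2)


def test_height_field_interpolates_empty_cells():
    rng = np.random.default_rng(0)
    n = 60  # sparse: some of the 8x8 cells will be empty
    pos = np.column_stack([rng.uniform(0, 20, n), rng.uniform(0, 20, n),
                           30.0 + rng.normal(0, 0.2, n)])
    fr = make_frame(pos, np.full(n, int(BeadKind.HEAD)))
    hf = height_field(fr, n_cells=8)
    assert np.isfinite(hf.grid).all()
    assert hf.n_empty > 0


def test_observable_series_validation():
    with pytest.raises(AnalysisError):
        ObservableSeries("x", [0, 1, 1], [1, 2, 3])
    with pytest.raises(AnalysisError):
        ObservableSeries("x", [0, 1], [1, 2, 3])


def test_bending_fit_separates_tension_from_bending():
    """Surfaces drawn with an explicit tension component (sigma = 2,
    kappa = 8) still yield the bending modulus, not the mixture a pure
    q^-4 fit would report."""
    from nanospin.observables import synthetic_helfrich_frames
    traj = synthetic_helfrich_frames(kappa=8.0, L=40.0, n_cells=16,
                                     n_frames=500, seed=9, sigma=2.0)
    out = bending_stiffness(traj, n_cells=16, temperature=1.1)
    assert out["kappa"] == pytest.approx(8.0, rel=0.25)
    assert out["sigma_eff"] == pytest.approx(2.0, rel=0.35)


def test_stretching_modulus_debiases_correlated_windows():
    """Short windows of a slow Ornstein-Uhlenbeck area process
    underestimate the variance; the autocorrelation-corrected estimator
    recovers the true K_A where the naive per-window variance is biased
    high."""
    rng = np.random.default_rng(11)
    tau, var_true, mean = 150.0, 40.0, 1000.0
    a_coef = np.exp(-1.0 / tau)
    noise_sd = np.sqrt(var_true * (1 - a_coef**2))
    n_rep, n_per = 6, 1500
    windows = []
    for _ in range(n_rep):
        x = np.empty(n_per)
        x[0] = rng.normal(0, np.sqrt(var_true))
        for t in range(1, n_per):
            x[t] = a_coef * x[t - 1] + rng.normal(0, noise_sd)
        windows.append(mean + x)
    series = np.concatenate(windows)
    k_true = 1.1 * mean / var_true
    out = stretching_modulus(series, temperature=1.1, window_length=n_per)
    assert out["K_A"] == pytest.approx(k_true, rel=0.25)
    naive = 1.1 * mean / np.mean([w.var() for w in windows])
    assert naive > out["K_A"]  # the bias the correction removes
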