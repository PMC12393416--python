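"""Inverse solver: cost, adjoint gradients, TV prox, descent, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msbptomo import (
    Grid2D,
    Measurement,
    OpticalConfig,
    RIVolume,
    SolverConfig,
    artifact_energy,
    bead_phantom,
    calibrate_hyperparameters,
    data_term,
    forward,
    gradient_amplitude,
    gradient_field,
    illumination_ring,
    reconstruct,
    simulate_measurements,
    snap_frequency,
    sphere_mask,
    synthetic_field_measurement,
    total_variation,
    tv_prox,
)
from msbptomo.inverse import _gradient


def random_volume(rng, grid, n_layers=4, dz=0.3, n0=1.33, scale=0.01):
    return RIVolume(rng.uniform(0, scale, (n_layers,) + grid.shape), dz, n0, grid)


def finite_difference_gradient(volume, measurement, config, h=1e-6):
    fd = np.zeros_like(volume.delta_n)
    for idx in np.ndindex(volume.delta_n.shape):
        vp = volume.delta_n.copy()
        vm = volume.delta_n.copy()
        vp[idx] += h
        vm[idx] -= h
        cp = data_term(RIVolume(vp, volume.dz, volume.n0, volume.grid), measurement, config)
        cm = data_term(RIVolume(vm, volume.dz, volume.n0, volume.grid), measurement, config)
        fd[idx] = (cp - cm) / (2 * h)
    return fd


class TestDataTerm:
    def test_zero_for_self_consistent_data(self, grid16, optics, rng):
        vol = random_volume(rng, grid16)
        k = snap_frequency((0.4, 0.2), grid16)
        y = forward(vol, k, 1.0, "field", optics)
        assert data_term(vol, Measurement(y, "field", k, 1.0), optics) <= 1e-20

    def test_constant_offset_closed_form(self, grid16, optics, rng):
        vol = random_volume(rng, grid16)
        c = 0.3 - 0.4j
        y = forward(vol, (0, 0), 0.0, "field", optics) + c
        val = data_term(vol, Measurement(y, "field", (0, 0), 0.0), optics)
        assert val == pytest.approx(0.5 * y.size * abs(c) ** 2, rel=1e-10)

    def test_matches_brute_force_sum(self, grid16, optics, rng):
        vol = random_volume(rng, grid16)
        y = rng.uniform(0.5, 1.5, grid16.shape)
        m = Measurement(y, "amplitude", (0, 0), 0.0)
        G = np.abs(forward(vol, (0, 0), 0.0, "field", optics))
        brute = 0.5 * sum(
            abs(y[i, j] - G[i, j]) ** 2 for i in range(16) for j in range(16)
        )
        assert data_term(vol, m, optics) == pytest.approx(brute, rel=1e-12)


class TestGradients:
    @pytest.mark.parametrize("kind", ["field", "amplitude"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_finite_differences(self, kind, seed, optics):
        rng = np.random.default_rng(seed)
        grid = Grid2D(8, 8, 0.2)
        vol = random_volume(rng, grid, n_layers=4)
        other = random_volume(rng, grid, n_layers=4)
        k = snap_frequency((0.4, -0.2), grid)
        y = forward(other, k, 1.5, kind, optics)
        m = Measurement(y, kind, k, 1.5)
        grad = (gradient_field if kind == "field" else gradient_amplitude)(vol, m, optics)
        fd = finite_difference_gradient(vol, m, optics)
        scale = np.max(np.abs(fd))
        tol = 1e-5 if kind == "field" else 1e-4
        assert np.max(np.abs(grad - fd)) / scale < tol

    def test_zero_residual_zero_gradient(self, optics, rng):
        grid = Grid2D(8, 8, 0.2)
        vol = random_volume(rng, grid)
        k = (0.0, 0.0)
        y = forward(vol, k, 0.0, "field", optics)
        g = gradient_field(vol, Measurement(y, "field", k, 0.0), optics)
        assert np.max(np.abs(g)) < 1e-14

    def test_amplitude_zero_residual_zero_gradient(self, optics, rng):
        grid = Grid2D(8, 8, 0.2)
        vol = random_volume(rng, grid)
        y = np.abs(forward(vol, (0, 0), 0.0, "field", optics))
        g = gradient_amplitude(vol, Measurement(y, "amplitude", (0, 0), 0.0), optics)
        assert np.max(np.abs(g)) < 1e-14

    def test_translation_equivariance(self, optics, rng):
        # shifting the data laterally shifts the gradient identically
        grid = Grid2D(16, 16, 0.2)
        vol = random_volume(rng, grid, n_layers=3)
        y = forward(random_volume(rng, grid, n_layers=3), (0, 0), 0.0, "field", optics)
        g0 = gradient_field(vol, Measurement(y, "field", (0, 0), 0.0), optics)
        shift = (3, -5)
        y_s = np.roll(y, shift, axis=(0, 1))
        vol_s = RIVolume(
            np.roll(vol.delta_n, shift, axis=(1, 2)), vol.dz, vol.n0, grid
        )
        g_s = gradient_field(vol_s, Measurement(y_s, "field", (0, 0), 0.0), optics)
        np.testing.assert_allclose(
            g_s, np.roll(g0, shift, axis=(1, 2)), atol=1e-12 * np.max(np.abs(g0))
        )

    def test_structural_identity_bitwise(self, optics, rng):
        # pairing y_amp with the predicted phase reproduces the amplitude
        # gradient exactly, bit for bit
        grid = Grid2D(8, 8, 0.2)
        vol = random_volume(rng, grid)
        y = np.abs(forward(random_volume(rng, grid), (0, 0), 0.5, "field", optics))
        m_amp = Measurement(y, "amplitude", (0, 0), 0.5)
        g_amp = gradient_amplitude(vol, m_amp, optics)
        m_syn = synthetic_field_measurement(vol, m_amp, optics)
        g_field = gradient_field(vol, m_syn, optics)
        np.testing.assert_array_equal(g_amp, g_field)

    def test_kind_mismatch_rejected(self, optics, rng):
        grid = Grid2D(8, 8, 0.2)
        vol = random_volume(rng, grid)
        m = Measurement(np.ones(grid.shape), "amplitude", (0, 0), 0.0)
        with pytest.raises(ValueError):
            gradient_field(vol, m, optics)


def taut_string_tv1d(y, lam):
    """Exact 1D TV denoising (Condat's direct algorithm) — independent oracle."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = np.empty(n)
    k = k0 = km = kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:
            x[km : k + 1] = vmin if umin < 0 else (vmax if umax > 0 else vmin + umin)
            if umin < 0:
                x[k0 : km + 1] = vmin
                k = k0 = km = km + 1
                if k > n - 1:
                    return x
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
                continue
            if umax > 0:
                x[k0 : kp + 1] = vmax
                k = k0 = kp = kp + 1
                if k > n - 1:
                    return x
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
                continue
            x[k0 : n] = vmin + umin / (k - k0 + 1)
            return x
        umin += y[k + 1] - vmin
        if umin < -lam:
            x[k0 : km + 1] = vmin
            k = k0 = kp = km = km + 1
            vmin = y[k]
            vmax = y[k] + 2 * lam
            umin = lam
            umax = -lam
            continue
        umax += y[k + 1] - vmax
        if umax > lam:
            x[k0 : kp + 1] = vmax
            k = k0 = km = kp = kp + 1
            vmin = y[k] - 2 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
            continue
        k += 1
        if umin >= lam:
            km = k
            vmin += (umin - lam) / (k - k0 + 1)
            umin = lam
        if umax <= -lam:
            kp = k
            vmax += (umax + lam) / (k - k0 + 1)
            umax = -lam


class TestTVProx:
    def test_zero_weight_is_identity(self, grid16, rng):
        vol = random_volume(rng, grid16)
        out = tv_prox(vol, 0.0)
        np.testing.assert_array_equal(out.delta_n, vol.delta_n)

    def test_constant_volume_fixed_point(self, grid16):
        vol = RIVolume(np.full((3,) + grid16.shape, 0.01), 0.3, 1.33, grid16)
        out = tv_prox(vol, 0.05)
        np.testing.assert_allclose(out.delta_n, 0.01, atol=1e-12)

    def test_1d_step_matches_taut_string(self):
        # a 1D step profile along x, constant along y and z: the 3D prox
        # reduces to exact 1D TV denoising
        grid = Grid2D(32, 4, 0.2)
        prof = np.zeros(32)
        prof[12:20] = 0.01
        vol = RIVolume(np.tile(prof, (2, 4, 1)), 0.3, 1.33, grid)
        w = 2e-4
        out = tv_prox(vol, w, n_iters=400)
        expect = taut_string_tv1d(prof, w)
        assert np.max(np.abs(out.delta_n[1, 2] - expect)) < 1e-4

    @settings(deadline=None, max_examples=15)
    @given(w=st.floats(1e-5, 1e-2), seed=st.integers(0, 100))
    def test_tv_never_increases(self, w, seed):
        rng = np.random.default_rng(seed)
        grid = Grid2D(8, 8, 0.2)
        vol = random_volume(rng, grid, n_layers=3)
        out = tv_prox(vol, w, n_iters=60)
        tv_in = total_variation(vol.delta_n)
        assert total_variation(out.delta_n) <= tv_in * (1 + 1e-9) + 1e-12


class TestArtifactEnergy:
    def test_zero_volume(self, grid16):
        vol = RIVolume(np.zeros((2,) + grid16.shape), 0.3, 1.33, grid16)
        assert artifact_energy(vol, 0.2) == 0.0

    def test_center_energy_ignored(self, grid16):
        dn = np.zeros((2,) + grid16.shape)
        dn[:, 6:10, 6:10] = 0.05
        vol = RIVolume(dn, 0.3, 1.33, grid16)
        assert artifact_energy(vol, 0.2) == 0.0

    def test_uniform_volume_normalization(self, grid16):
        vol = RIVolume(np.full((2,) + grid16.shape, 0.04), 0.3, 1.33, grid16)
        assert artifact_energy(vol, 0.25) == pytest.approx(0.04**2, rel=1e-12)

    def test_border_fraction_validated(self, grid16):
        vol = RIVolume(np.zeros((1,) + grid16.shape), 0.3, 1.33, grid16)
        with pytest.raises(ValueError):
            artifact_energy(vol, 0.7)


class TestReconstruct:
    def _bead_set(self, optics, grid, M=8, dz=0.25, d=1.5, dn=0.01, n_angles=6):
        vol = bead_phantom(d, dn, grid, M, dz, n0=optics.n0)
        angles = illumination_ring(n_angles, optics, 0.9, grid=grid)
        return vol, simulate_measurements(vol, angles, [0.0], "amplitude", optics)

    def test_fixed_point_at_truth(self, optics):
        grid = Grid2D(32, 32, 0.15)
        vol, mset = self._bead_set(optics, grid)
        cfg = SolverConfig(step_size=0.01, tau=0.0, n_epochs=2, momentum=0.0,
                           batch_size=6, init="given")
        res = reconstruct(mset, cfg, 8, 0.25, init_volume=vol)
        assert res.cost_trace[0, 0] < 1e-12
        assert np.max(np.abs(res.volume.delta_n - vol.delta_n)) < 1e-6

    def test_full_batch_descent_is_monotone(self, optics):
        grid = Grid2D(32, 32, 0.15)
        _, mset = self._bead_set(optics, grid)
        cfg = SolverConfig(step_size=0.02, tau=0.0, n_epochs=8, momentum=0.0,
                           batch_size=6)
        res = reconstruct(mset, cfg, 8, 0.25)
        costs = res.cost_trace[:, 0]
        assert np.all(np.diff(costs) <= 1e-12)

    def test_deterministic_under_seed(self, optics):
        grid = Grid2D(16, 16, 0.2)
        _, mset = self._bead_set(optics, grid, M=4, dz=0.4, d=1.2, n_angles=4)
        cfg = SolverConfig(n_epochs=3, seed=9)
        a = reconstruct(mset, cfg, 4, 0.25)
        b = reconstruct(mset, cfg, 4, 0.25)
        np.testing.assert_array_equal(a.volume.delta_n, b.volume.delta_n)

    def test_global_phase_invariance_of_amplitude_cost(self, optics):
        # multiplying any field record by a unit-modulus constant before
        # amplitude extraction leaves the reconstruction unchanged
        grid = Grid2D(16, 16, 0.2)
        vol = bead_phantom(1.2, 0.01, grid, 4, 0.4, n0=optics.n0)
        angles = illumination_ring(4, optics, 0.9, grid=grid)
        fset = simulate_measurements(vol, angles, [0.0], "field", optics)
        from msbptomo import MeasurementSet

        recs_a = [Measurement(np.abs(m.data), "amplitude", m.k_lat, m.defocus, m.index)
                  for m in fset]
        phase = np.exp(1j * 1.234)
        recs_b = [Measurement(np.abs(phase * m.data), "amplitude", m.k_lat, m.defocus,
                              m.index) for m in fset]
        cfg = SolverConfig(n_epochs=3, seed=2)
        ra = reconstruct(MeasurementSet(recs_a, optics, grid), cfg, 4, 0.4)
        rb = reconstruct(MeasurementSet(recs_b, optics, grid), cfg, 4, 0.4)
        np.testing.assert_allclose(ra.volume.delta_n, rb.volume.delta_n, atol=1e-12)

    def test_non_finite_cost_reported_with_epoch(self, optics):
        grid = Grid2D(16, 16, 0.2)
        _, mset = self._bead_set(optics, grid, M=4, dz=0.4, d=1.2, dn=0.05, n_angles=4)
        mset[0].data[3, 3] = np.nan  # corrupted record poisons the cost
        cfg = SolverConfig(n_epochs=3)
        with pytest.raises(RuntimeError, match="epoch"):
            reconstruct(mset, cfg, 4, 0.4)

    def test_empty_set_rejected(self, optics, grid16):
        from msbptomo import MeasurementSet

        with pytest.raises(ValueError, match="empty"):
            reconstruct(MeasurementSet([], optics, grid16), SolverConfig(), 4, 0.25)

    def test_padded_gradient_matches_finite_differences(self, optics):
        # the crop/zero-embed adjoint used with volume padding is exact too
        rng = np.random.default_rng(3)
        fov = Grid2D(8, 8, 0.2)
        padded = Grid2D(12, 12, 0.2)
        vol = random_volume(rng, padded, n_layers=3)
        y = rng.uniform(0.6, 1.4, fov.shape)
        m = Measurement(y, "amplitude", (0, 0), 0.0)
        grad = _gradient(vol, m, optics)[0]

        def cost(dn):
            v = RIVolume(dn, vol.dz, vol.n0, padded)
            return _gradient(v, m, optics)[1]

        h = 1e-6
        fd = np.zeros_like(grad)
        for idx in np.ndindex(grad.shape):
            vp = vol.delta_n.copy()
            vm = vol.delta_n.copy()
            vp[idx] += h
            vm[idx] -= h
            fd[idx] = (cost(vp) - cost(vm)) / (2 * h)
        assert np.max(np.abs(grad - fd)) / np.max(np.abs(fd)) < 1e-4


class TestCalibration:
    def test_selection_rule_and_table(self, optics):
        grid = Grid2D(24, 24, 0.15)
        step, tau, table = calibrate_hyperparameters(
            [(1.2, 0.01), (1.2, 0.03)],
            step_grid=[0.05, 1e4],  # second entry absurd on purpose
            tau_grid=[1e-4],
            config=SolverConfig(n_epochs=8, nonneg=True, momentum=0.0, batch_size=4),
            grid=grid,
            n_layers=6,
            dz=0.3,
            n_angles=4,
        )
        assert not table["error"].isna().any()  # robust: never NaN, inf allowed
        worst = table.groupby(["step_size", "tau"])["error"].max()
        sel = worst.loc[(step, tau)]
        assert sel == worst.min()
        # the absurd step must not have won
        assert step == 0.05

    def test_empty_grids_rejected(self):
        with pytest.raises(ValueError):
            calibrate_hyperparameters([(2.0, 0.01)], [], [1e-4])
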