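"""QSM chain: masking, Laplacian unwrapping, field fitting, background
removal, dipole inversion."""

import numpy as np
import pytest

from nigra.core import FrequencyMap, VoxelGrid
from nigra.qsm import (
    compute_brain_mask,
    dipole_field_hz,
    estimate_frequency,
    invert_dipole,
    laplacian_unwrap,
    remove_background_field,
)

GRID = VoxelGrid(dims=(48, 48, 48), voxel_size=(1.0, 1.0, 1.0))


def _radius2(grid):
    centers = [(n - 1) / 2.0 for n in grid.dims]
    xx, yy, zz = np.meshgrid(*[np.arange(n) - c for n, c in zip(grid.dims, centers)],
                             indexing="ij")
    return xx**2 + yy**2 + zz**2


class TestBrainMask:
    def test_uniform_magnitude_gives_full_mask(self):
        mask = compute_brain_mask(np.ones((20, 20, 20)))
        assert mask.all()

    def test_head_ellipsoid_recovered(self):
        r2 = _radius2(GRID)
        head = r2 <= 18**2
        mag = np.where(head, 100.0, 0.0)
        mask = compute_brain_mask(mag)
        assert np.all(mask[r2 <= 15**2])  # interior covered
        assert not mask[0, 0, 0] and not mask[-1, -1, -1]

    def test_largest_component_wins(self):
        mag = np.zeros((40, 40, 40))
        mag[2:6, 2:6, 2:6] = 50.0  # small blob
        mag[15:35, 15:35, 15:35] = 50.0  # large blob
        mask = compute_brain_mask(mag, closing_radius_vox=0)
        assert mask[20, 20, 20] and not mask[3, 3, 3]

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="empty mask|no signal"):
            compute_brain_mask(np.zeros((8, 8, 8)))


class TestLaplacianUnwrap:
    def test_wrap_free_smooth_phase_identity(self):
        n = 48
        mode = np.cos(np.pi * (np.arange(n) + 0.5) / n)
        psi = 0.3 * mode[:, None, None] + 0.2 * np.cos(
            2 * np.pi * (np.arange(n) + 0.5) / n)[None, :, None] * np.ones((n, n, n))
        out = laplacian_unwrap(psi, GRID)
        diff = out - psi
        assert np.abs(diff - diff.mean()).max() < 1e-6

    def test_constant_phase_maps_to_constant(self):
        out = laplacian_unwrap(np.full(GRID.dims, 1.3), GRID)
        assert np.ptp(out) < 1e-9

    def test_wrapped_quadratic_ramp_recovered(self):
        n = 48
        ax = (np.arange(n) - (n - 1) / 2.0) / (n / 2.0)
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        ramp = 6 * np.pi * (1.0 - (xx**2 + yy**2 + zz**2) / 3.0)
        wrapped = np.angle(np.exp(1j * ramp))
        rec = laplacian_unwrap(wrapped, GRID)
        interior = (np.abs(xx) < 0.7) & (np.abs(yy) < 0.7) & (np.abs(zz) < 0.7)
        diff = rec - ramp
        assert np.abs(diff[interior] - diff[interior].mean()).max() < 0.05

    def test_unwrap_closure(self):
        n = 48
        ax = (np.arange(n) - (n - 1) / 2.0) / (n / 2.0)
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        ramp = 4 * np.pi * np.exp(-(xx**2 + yy**2 + zz**2))
        wrapped = np.angle(np.exp(1j * ramp))
        rec = laplacian_unwrap(wrapped, GRID)
        interior = (np.abs(xx) < 0.7) & (np.abs(yy) < 0.7) & (np.abs(zz) < 0.7)
        closure = np.angle(np.exp(1j * (rec - wrapped)))
        # wrap(unwrapped - wrapped) is a constant modulo small solver error
        assert np.ptp(closure[interior]) < 0.1

    def test_nonfinite_rejected(self):
        bad = np.zeros(GRID.dims)
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            laplacian_unwrap(bad, GRID)


class TestFrequencyFit:
    TES = (13.77, 26.39, 39.0)

    def test_exact_line_recovered(self):
        f = 10.0
        phases = [2 * np.pi * f * te / 1000.0 * np.ones((8, 8, 8)) for te in self.TES]
        grid = VoxelGrid((8, 8, 8))
        fm = estimate_frequency(phases, self.TES, grid)
        np.testing.assert_allclose(fm.values_hz, 10.0, atol=1e-10)

    def test_intercept_absorbed(self):
        f = 10.0
        phases = [0.3 + 2 * np.pi * f * te / 1000.0 * np.ones((8, 8, 8)) for te in self.TES]
        fm = estimate_frequency(phases, self.TES, VoxelGrid((8, 8, 8)))
        np.testing.assert_allclose(fm.values_hz, 10.0, atol=1e-10)

    def test_weighted_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        shape = (6, 6, 6)
        phases = np.stack([rng.normal(size=shape) for _ in self.TES])
        weights = np.stack([rng.uniform(0.5, 2.0, size=shape) for _ in self.TES])
        fm = estimate_frequency(phases, self.TES, VoxelGrid(shape), weights=weights)
        t = 2 * np.pi * np.array(self.TES) / 1000.0
        for idx in np.ndindex(shape):
            w = weights[(slice(None),) + idx]
            y = phases[(slice(None),) + idx]
            A = np.stack([t, np.ones_like(t)], axis=1)
            W = np.diag(w)
            slope, _ = np.linalg.solve(A.T @ W @ A, A.T @ W @ y)
            assert fm.values_hz[idx] == pytest.approx(slope, abs=1e-10)

    def test_single_echo_requires_flag(self):
        phases = [np.ones((4, 4, 4))]
        with pytest.raises(ValueError, match="single-echo"):
            estimate_frequency(phases, (20.0,), VoxelGrid((4, 4, 4)))
        fm = estimate_frequency(phases, (20.0,), VoxelGrid((4, 4, 4)), allow_single_echo=True)
        np.testing.assert_allclose(fm.values_hz, 1.0 / (2 * np.pi * 0.02))


class TestBackgroundRemoval:
    def setup_method(self):
        self.r2 = _radius2(GRID)
        self.mask = self.r2 <= 18**2

    def test_constant_field_annihilated(self):
        fm = FrequencyMap(values_hz=np.full(GRID.dims, 5.0), mask=self.mask, grid=GRID)
        local = remove_background_field(fm, radius_mm=3.0)
        assert np.sqrt((local.values_hz[local.mask] ** 2).mean()) < 1e-10

    def test_exterior_source_suppressed(self):
        chi = np.zeros(GRID.dims)
        centers = [(n - 1) / 2.0 for n in GRID.dims]
        xx, yy, zz = np.meshgrid(*[np.arange(n) - c for n, c in zip(GRID.dims, centers)],
                                 indexing="ij")
        chi[(xx**2 + yy**2 + (zz - 22) ** 2) <= 9] = 500.0  # outside the mask
        field = dipole_field_hz(chi, GRID, 3.0)
        fm = FrequencyMap(values_hz=field, mask=self.mask, grid=GRID)
        local = remove_background_field(fm, radius_mm=3.0)
        rms_in = np.sqrt((field[local.mask] ** 2).mean())
        rms_out = np.sqrt((local.values_hz[local.mask] ** 2).mean())
        assert rms_out < 0.05 * rms_in

    def test_interior_source_retained(self):
        chi = np.zeros(GRID.dims)
        chi[self.r2 <= 25] = 200.0
        field = dipole_field_hz(chi, GRID, 3.0)
        fm = FrequencyMap(values_hz=field, mask=self.mask, grid=GRID)
        local = remove_background_field(fm, radius_mm=3.0)
        kept = (local.values_hz[local.mask] ** 2).sum() / (field[local.mask] ** 2).sum()
        assert kept > 0.8

    def test_oversized_radius_rejected(self):
        fm = FrequencyMap(values_hz=np.zeros(GRID.dims), mask=self.mask, grid=GRID)
        with pytest.raises(ValueError, match="radius"):
            remove_background_field(fm, radius_mm=30.0)


class TestDipoleInversion:
    def test_zero_field_gives_zero_map(self):
        mask = np.ones((24, 24, 24), bool)
        grid = VoxelGrid((24, 24, 24))
        fm = FrequencyMap(values_hz=np.zeros(grid.dims), mask=mask, grid=grid)
        chi = invert_dipole(fm, 3.0, n_iter=5)
        np.testing.assert_allclose(chi.values_ppb, 0.0, atol=1e-12)

    @pytest.mark.parametrize("delta", [-0.1, 0.0, 0.34, 1.0])
    def test_delta_out_of_range_rejected(self, delta):
        grid = VoxelGrid((8, 8, 8))
        fm = FrequencyMap(values_hz=np.zeros(grid.dims), mask=np.ones(grid.dims, bool),
                          grid=grid)
        with pytest.raises(ValueError, match="delta"):
            invert_dipole(fm, 3.0, delta=delta)

    def test_linearity(self):
        grid = VoxelGrid((24, 24, 24))
        rng = np.random.default_rng(1)
        mask = _radius2(grid) <= 9**2
        field = rng.normal(size=grid.dims)
        a = 3.7
        fm1 = FrequencyMap(values_hz=field, mask=mask, grid=grid)
        fm2 = FrequencyMap(values_hz=a * field, mask=mask, grid=grid)
        chi1 = invert_dipole(fm1, 3.0, n_iter=10)
        chi2 = invert_dipole(fm2, 3.0, n_iter=10)
        np.testing.assert_allclose(chi2.values_ppb, a * chi1.values_ppb,
                                   rtol=1e-9, atol=1e-8)

    def test_iterations_do_not_degrade_sphere_recovery(self):
        grid = VoxelGrid((32, 32, 32))
        r2 = _radius2(grid)
        sphere = r2 <= 6**2
        chi_true = np.where(sphere, 100.0, 0.0)
        field = dipole_field_hz(chi_true, grid, 3.0)
        mask = np.ones(grid.dims, bool)
        fm = FrequencyMap(values_hz=field, mask=mask, grid=grid)
        ref = chi_true - chi_true.mean()

        def rmse(n_iter):
            rec = invert_dipole(fm, 3.0, delta=0.1, n_iter=n_iter)
            return np.sqrt(((rec.values_ppb - ref)[sphere] ** 2).mean())

        assert rmse(30) <= rmse(0) + 1e-9

    def test_mask_mean_referenced_to_zero(self):
        grid = VoxelGrid((24, 24, 24))
        mask = _radius2(grid) <= 8**2
        rng = np.random.default_rng(2)
        fm = FrequencyMap(values_hz=rng.normal(size=grid.dims), mask=mask, grid=grid)
        chi = invert_dipole(fm, 3.0, n_iter=3)
        assert abs(chi.values_ppb[mask].mean()) < 1e-9
        assert np.all(chi.values_ppb[~mask] == 0)
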