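"""QSM reconstruction chain: masking, unwrapping, field fitting, background
removal, dipole inversion.

Conventions: susceptibility in ppb, fields in Hz, B0 along the grid's slice
axis, dipole kernel D(k) = 1/3 - kz^2/|k|^2 with D(0) = 0.  All spectral
solves zero-pad each axis by a factor of 2 to suppress wrap-around.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.fft import dctn, idctn, fftn, ifftn, fftfreq

from .core import GAMMA_BAR_HZ_PER_T, FrequencyMap, SusceptibilityMap, VoxelGrid

PAD_FACTOR = 2


def _padded_shape(shape: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(PAD_FACTOR * n for n in shape)


def dipole_kernel(shape: tuple[int, int, int], voxel_size: tuple[float, float, float],
                  b0_axis: int = 2) -> np.ndarray:
    """Unit dipole response D(k) = 1/3 - k_z^2/|k|^2 on an FFT grid, D(0) = 0."""
    ks = np.meshgrid(
        *[fftfreq(n, d=s) for n, s in zip(shape, voxel_size)], indexing="ij"
    )
    k2 = sum(k**2 for k in ks)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - ks[b0_axis] ** 2 / k2
    d[k2 == 0] = 0.0
    return d


def _apply_kspace_kernel(vol: np.ndarray, kernel_padded: np.ndarray) -> np.ndarray:
    shape = vol.shape
    big = fftn(vol, s=kernel_padded.shape)
    out = ifftn(big * kernel_padded).real
    return out[tuple(slice(0, n) for n in shape)]


def dipole_field_hz(chi_ppb: np.ndarray, grid: VoxelGrid, b0_tesla: float) -> np.ndarray:
    """Field perturbation (Hz) of a susceptibility distribution, B0 on the slice axis."""
    d = dipole_kernel(_padded_shape(grid.dims), grid.voxel_size, b0_axis=grid.slice_axis)
    rel = np.asarray(chi_ppb, dtype=float) * 1e-9
    return GAMMA_BAR_HZ_PER_T * b0_tesla * _apply_kspace_kernel(rel, d)


def compute_brain_mask(magnitude: np.ndarray, threshold_frac: float = 0.2,
                       closing_radius_vox: int = 2) -> np.ndarray:
    """Threshold-and-morphology brain mask from a magnitude volume.

    Threshold at ``threshold_frac`` of the robust (99th-percentile) maximum,
    keep the largest connected component, and close small holes.
    """
    mag = np.asarray(magnitude, dtype=float)
    if mag.size == 0 or not np.any(mag > 0):
        raise ValueError("magnitude volume carries no signal: empty mask")
    robust_max = np.percentile(mag, 99.0)
    if robust_max <= 0:
        robust_max = mag.max()
    mask = mag > threshold_frac * robust_max
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no voxel exceeds the mask threshold")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    if closing_radius_vox > 0:
        ball = _ellipsoid_footprint((closing_radius_vox,) * 3)
        r = closing_radius_vox
        padded = np.pad(mask, r)  # keep the closing from eating the volume border
        mask = ndimage.binary_closing(padded, structure=ball)[r:-r, r:-r, r:-r]
    return mask


def _ellipsoid_footprint(radii_vox: tuple[int, int, int]) -> np.ndarray:
    rx, ry, rz = (max(int(r), 0) for r in radii_vox)
    x, y, z = np.mgrid[-rx : rx + 1, -ry : ry + 1, -rz : rz + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        return (
            (x / max(rx, 1e-9)) ** 2 + (y / max(ry, 1e-9)) ** 2 + (z / max(rz, 1e-9)) ** 2
        ) <= 1.0


def _dct_laplacian_eigs(shape: tuple[int, ...], voxel_size: tuple[float, ...]) -> np.ndarray:
    """Spectral (cosine-basis, Neumann) Laplacian eigenvalues -(pi m / (N d))^2."""
    axes = [
        -((np.pi * np.arange(n) / (n * s)) ** 2) for n, s in zip(shape, voxel_size)
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    return sum(grids)


def laplacian_unwrap(wrapped: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Laplacian phase unwrapping via a cosine-spectral Poisson solve.

    Solves lap(phi) = cos(psi) lap(sin psi) - sin(psi) lap(cos psi); the
    right-hand side is wrap-invariant because it touches psi only through
    sin/cos.  The k = 0 coefficient is zeroed, so the output is mean-free:
    callers compare modulo an additive constant.
    """
    psi = np.asarray(wrapped, dtype=float)
    if not np.all(np.isfinite(psi)):
        raise ValueError("non-finite phase input")
    lam = _dct_laplacian_eigs(psi.shape, grid.voxel_size)

    def lap(f: np.ndarray) -> np.ndarray:
        return idctn(lam * dctn(f, norm="ortho"), norm="ortho")

    rhs = np.cos(psi) * lap(np.sin(psi)) - np.sin(psi) * lap(np.cos(psi))
    coef = dctn(rhs, norm="ortho")
    lam_safe = np.where(lam == 0, 1.0, lam)
    coef = coef / lam_safe
    coef.flat[0] = 0.0
    return idctn(coef, norm="ortho")


def estimate_frequency(
    unwrapped_echo_phases: list[np.ndarray] | np.ndarray,
    te_list_ms: tuple[float, ...],
    grid: VoxelGrid,
    mask: np.ndarray | None = None,
    weights: list[np.ndarray] | np.ndarray | None = None,
    allow_single_echo: bool = False,
) -> FrequencyMap:
    """Per-voxel weighted least-squares frequency (Hz) from unwrapped phases.

    Fits phase = 2*pi*f*TE + c per voxel; the intercept absorbs receiver and
    channel offsets.  Weights default to uniform; pass per-echo magnitude^2
    volumes for SNR-optimal fits.  A single echo requires
    ``allow_single_echo`` (intercept-free phase/(2 pi TE)).
    """
    phases = np.asarray(unwrapped_echo_phases, dtype=float)
    if phases.ndim == 3:
        phases = phases[None]
    n_echo = phases.shape[0]
    if n_echo != len(te_list_ms):
        raise ValueError("echo count does not match te_list")
    if mask is None:
        mask = np.ones(grid.dims, dtype=bool)
    t = 2.0 * np.pi * np.asarray(te_list_ms, dtype=float) / 1000.0  # s * 2pi
    if n_echo == 1:
        if not allow_single_echo:
            raise ValueError("single-echo frequency fit requires allow_single_echo=True")
        return FrequencyMap(values_hz=phases[0] / t[0], mask=mask, grid=grid)
    if weights is None:
        w = np.ones((n_echo,) + grid.dims)
    else:
        w = np.asarray(weights, dtype=float)
        if w.ndim == 1:
            w = np.broadcast_to(w[:, None, None, None], (n_echo,) + grid.dims).copy()
    tw = t[:, None, None, None]
    sw = w.sum(axis=0)
    sw = np.where(sw <= 0, 1.0, sw)
    t_bar = (w * tw).sum(axis=0) / sw
    p_bar = (w * phases).sum(axis=0) / sw
    cov = (w * (tw - t_bar) * (phases - p_bar)).sum(axis=0)
    var = (w * (tw - t_bar) ** 2).sum(axis=0)
    var = np.where(var <= 0, 1.0, var)
    return FrequencyMap(values_hz=cov / var, mask=mask, grid=grid)


def _smv_kernel_k(shape: tuple[int, ...], voxel_size: tuple[float, ...],
                  radius_mm: float) -> np.ndarray:
    """K-space transfer function of the spherical-mean-value filter."""
    offsets = [
        np.minimum(np.arange(n), n - np.arange(n)) * s for n, s in zip(shape, voxel_size)
    ]
    ox, oy, oz = np.meshgrid(*offsets, indexing="ij")
    ball = (ox**2 + oy**2 + oz**2) <= radius_mm**2
    kern = ball.astype(float)
    kern /= kern.sum()
    return fftn(kern)  # kernel centered at origin: transfer function is its FFT


def remove_background_field(
    freq: FrequencyMap,
    radius_mm: float = 2.0,
    deconv_threshold: float = 0.05,
) -> FrequencyMap:
    """SHARP-style background removal by spherical-mean-value filtering.

    Applies (delta - S_r) to the field, deconvolves by (1 - S_r(k)) where it
    is well conditioned, and restricts to the mask eroded by the sphere
    radius.  Any field harmonic inside the mask (i.e. generated by sources
    outside it) is annihilated up to a boundary layer.
    """
    grid = freq.grid
    mask = freq.mask
    if not np.any(mask):
        raise ValueError("empty mask")
    radii_vox = tuple(int(np.floor(radius_mm / s)) for s in grid.voxel_size)
    if any(2 * r + 1 > n for r, n in zip(radii_vox, grid.dims)):
        raise ValueError(f"SMV radius {radius_mm} mm too large for the grid")
    eroded = ndimage.binary_erosion(mask, structure=_ellipsoid_footprint(radii_vox))
    if not np.any(eroded):
        raise ValueError(f"SMV radius {radius_mm} mm too large for the mask")

    shape_p = _padded_shape(grid.dims)
    sk = _smv_kernel_k(shape_p, grid.voxel_size, radius_mm)
    hk = 1.0 - sk
    f = np.where(mask, freq.values_hz, 0.0)
    high = _apply_kspace_kernel(f, hk)
    high = np.where(eroded, high, 0.0)
    inv = np.zeros_like(hk)
    good = np.abs(hk) > deconv_threshold
    inv[good] = 1.0 / hk[good]
    local = _apply_kspace_kernel(high, inv)
    local = np.where(eroded, local, 0.0)
    return FrequencyMap(values_hz=local, mask=eroded, grid=grid)


def invert_dipole(
    local: FrequencyMap,
    b0_tesla: float,
    delta: float = 0.1,
    n_iter: int = 30,
) -> SusceptibilityMap:
    """Truncated k-space dipole inversion with iterative refinement.

    The initial estimate divides the normalized field by the dipole kernel
    thresholded at ``delta`` (sign-preserving).  Each refinement enforces the
    measured data on the well-conditioned region {|D| > delta} while applying
    the brain-mask support constraint in image space.  The output is in ppb,
    referenced to zero mean over the mask.
    """
    if not (0.0 < delta < 1.0 / 3.0):
        raise ValueError(f"delta must lie in (0, 1/3), got {delta}")
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    grid = local.grid
    mask = local.mask
    phi_rel = np.where(mask, local.values_hz, 0.0) / (GAMMA_BAR_HZ_PER_T * b0_tesla)

    shape_p = _padded_shape(grid.dims)
    d = dipole_kernel(shape_p, grid.voxel_size, b0_axis=grid.slice_axis)
    f_phi = fftn(phi_rel, s=shape_p)
    sign = np.where(d >= 0, 1.0, -1.0)
    inv_trunc = sign / np.maximum(np.abs(d), delta)
    x_k = f_phi * inv_trunc

    well = np.abs(d) > delta
    data_k = np.zeros_like(f_phi)
    data_k[well] = f_phi[well] / d[well]
    mask_p = np.zeros(shape_p, dtype=bool)
    mask_p[tuple(slice(0, n) for n in grid.dims)] = mask
    crop = tuple(slice(0, n) for n in grid.dims)
    for _ in range(n_iter):
        x = ifftn(x_k).real
        x = np.where(mask_p, x, 0.0)
        x_k = fftn(x)
        x_k[well] = data_k[well]
    chi = ifftn(x_k).real[crop] * 1e9
    chi = np.where(mask, chi - chi[mask].mean(), 0.0)
    return SusceptibilityMap(
        values_ppb=chi, mask=mask, grid=grid,
        meta={"delta": delta, "n_iter": n_iter, "b0_tesla": b0_tesla},
    )


def reconstruct_qsm(
    echo_phases_wrapped: np.ndarray,
    echo_magnitudes: np.ndarray,
    te_list_ms: tuple[float, ...],
    grid: VoxelGrid,
    b0_tesla: float,
    mask: np.ndarray | None = None,
    smv_radius_mm: float = 2.0,
    delta: float = 0.1,
    n_iter: int = 30,
) -> SusceptibilityMap:
    """Full chain: unwrap each echo, fit frequency, remove background, invert."""
    if mask is None:
        mask = compute_brain_mask(np.sqrt((echo_magnitudes**2).sum(axis=0)))
    unwrapped = np.stack([laplacian_unwrap(p, grid) for p in echo_phases_wrapped])
    weights = echo_magnitudes**2
    freq = estimate_frequency(unwrapped, te_list_ms, grid, mask=mask, weights=weights)
    local = remove_background_field(freq, radius_mm=smv_radius_mm)
    return invert_dipole(local, b0_tesla=b0_tesla, delta=delta, n_iter=n_iter)
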