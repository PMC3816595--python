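"""Morphons registration driven by quadrature-filter phase differences.

Complex log-normal quadrature filters along six icosahedral directions
measure local phase in both images; per-direction phase differences yield
directional displacement constraints that are combined per voxel by
certainty-weighted least squares.  Updates accumulate into the total field
with certainty-weighted averaging, and both field and certainty are
Gaussian-smoothed with a sigma of 1.25x the level's voxel size.  Because
local phase is independent of signal amplitude, the method is invariant to
global intensity rescaling of either image.

Eight dyadic resolution steps are used (finest = native grid) with caps of
20 iterations per step and 4 on the final step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_model import (
    DisplacementField,
    ImageGrid,
    ScalarImage,
    resample_field_to_grid,
    trilinear_sample,
)
from .preprocessing import pyramid_grid

__all__ = [
    "QuadratureFilterBank",
    "MorphonsConfig",
    "phase_difference_update",
    "morphons_register",
    "icosahedral_directions",
]


def icosahedral_directions() -> np.ndarray:
    """Six pairwise non-antiparallel unit vectors (icosahedron half-axes)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    dirs = np.array(
        [
            [1.0, phi, 0.0],
            [-1.0, phi, 0.0],
            [phi, 0.0, 1.0],
            [phi, 0.0, -1.0],
            [0.0, 1.0, phi],
            [0.0, -1.0, phi],
        ]
    )
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass(frozen=True)
class QuadratureFilterBank:
    """Log-normal quadrature filters along a set of directions.

    ``center_frequency`` is in rad/voxel; ``bandwidth_octaves`` is the
    relative bandwidth of the log-normal radial profile.  Filtering is done
    in the frequency domain on the full grid; ``spatial_kernels`` exposes
    the equivalent truncated spatial kernels (real part even, imaginary
    part odd along the filter direction).
    """

    directions: tuple = tuple(map(tuple, icosahedral_directions()))
    center_frequency: float = np.pi / 4.0
    bandwidth_octaves: float = 2.0
    kernel_size: int = 9

    def __post_init__(self):
        dirs = np.asarray(self.directions, dtype=float)
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("directions must be unit vectors")
        dots = dirs @ dirs.T
        if np.any(dots + 1.0 < 1e-9):
            raise ValueError("directions must be pairwise non-antiparallel")
        if self.center_frequency <= 0 or self.center_frequency > np.pi:
            raise ValueError("center_frequency must lie in (0, pi] rad/voxel")

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    def frequency_responses(self, shape: tuple[int, int, int]) -> list[np.ndarray]:
        """Filter transfer functions sampled on the FFT grid of ``shape``."""
        freqs = [2.0 * np.pi * np.fft.fftfreq(n) for n in shape]
        wx, wy, wz = np.meshgrid(*freqs, indexing="ij")
        wmag = np.sqrt(wx**2 + wy**2 + wz**2)
        with np.errstate(divide="ignore"):
            lnr = np.log(np.where(wmag > 0, wmag, 1.0) / self.center_frequency)
        radial = np.exp(-4.0 / (np.log(2.0) * self.bandwidth_octaves**2) * lnr**2)
        radial[wmag == 0] = 0.0
        responses = []
        for n in np.asarray(self.directions):
            proj = wx * n[0] + wy * n[1] + wz * n[2]
            with np.errstate(invalid="ignore"):
                cos = np.where(wmag > 0, proj / np.maximum(wmag, 1e-30), 0.0)
            directional = np.where(proj > 0, cos**2, 0.0)
            responses.append(radial * directional)
        return responses

    def spatial_kernels(self) -> list[np.ndarray]:
        """Complex spatial kernels truncated to ``kernel_size``^3."""
        n = 4 * self.kernel_size  # oversampled grid keeps truncation mild
        responses = self.frequency_responses((n, n, n))
        half = self.kernel_size // 2
        kernels = []
        for resp in responses:
            k = np.fft.ifftn(resp)
            k = np.fft.fftshift(k)
            c = n // 2
            kernels.append(k[c - half : c + half + 1, c - half : c + half + 1, c - half : c + half + 1])
        return kernels

    def responses(
        self, values: np.ndarray, transfer: list[np.ndarray] | None = None
    ) -> list[np.ndarray]:
        """Complex quadrature responses of an image (frequency-domain filtering).

        ``transfer`` may carry precomputed :meth:`frequency_responses` for
        the image shape (hot loop of the registrar).
        """
        if transfer is None:
            transfer = self.frequency_responses(values.shape)
        spectrum = np.fft.fftn(values)
        return [np.fft.ifftn(spectrum * h) for h in transfer]


@dataclass(frozen=True)
class MorphonsConfig:
    levels: int = 8
    max_iterations_per_level: int = 20
    max_iterations_final: int = 4
    smoothing_sigma_factor: float = 1.25  # x voxel size of the resolution grid
    filter_bank: QuadratureFilterBank = QuadratureFilterBank()
    min_level_dim: int = 16  # coarsest grids stay large enough for the filters
    max_step_voxels: float = 1.5  # per-iteration update clamp (phase-wrap guard)
    update_tol_voxels: float = 1e-3  # early stop when updates become negligible

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.smoothing_sigma_factor < 0:
            raise ValueError("smoothing_sigma_factor must be >= 0")


def phase_difference_update(
    fixed: ScalarImage,
    warped: ScalarImage,
    bank: QuadratureFilterBank | None = None,
    fixed_responses: list[np.ndarray] | None = None,
    transfer: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One phase-difference update (mm) plus its certainty field.

    For each direction k the local phase difference between the images is
    ``dphi_k = arg(q_f conj(q_m))``; the directional displacement is
    ``dphi_k / rho`` voxels along the filter direction with certainty
    ``|q_f conj(q_m)| cos^2(dphi_k / 2)``.  The per-voxel update solves the
    certainty-weighted least-squares combination of the directional
    constraints; voxels with no certainty get a zero update.
    """
    if fixed.grid != warped.grid:
        raise ValueError("images must share a grid")
    bank = bank or QuadratureFilterBank()
    if fixed_responses is None:
        fixed_responses = bank.responses(fixed.values, transfer)
    moving_responses = bank.responses(warped.values, transfer)
    dirs = np.asarray(bank.directions)
    rho = bank.center_frequency
    shape = fixed.grid.dims
    a_mat = np.zeros(shape + (3, 3))
    b_vec = np.zeros(shape + (3,))
    total_certainty = np.zeros(shape)
    for k in range(bank.n_directions):
        prod = fixed_responses[k] * np.conj(moving_responses[k])
        dphi = np.angle(prod)
        certainty = np.abs(prod) * np.cos(dphi / 2.0) ** 2
        d_k = dphi / rho  # voxels along dirs[k] (index space)
        n = dirs[k]
        outer = np.outer(n, n)
        a_mat += certainty[..., None, None] * outer
        b_vec += (certainty * d_k)[..., None] * n
        total_certainty += certainty
    # solve the 3x3 systems; Tikhonov floor keeps near-singular voxels stable
    eps = 1e-6 * max(float(total_certainty.max()), 1e-30)
    a_mat += eps * np.eye(3)
    update_vox = np.linalg.solve(a_mat, b_vec[..., None])[..., 0]
    update_vox[total_certainty <= 0] = 0.0
    update_mm = update_vox * np.asarray(fixed.grid.spacing)
    return update_mm, total_certainty


def _smooth(arr: np.ndarray, sigma_vox: float) -> np.ndarray:
    if sigma_vox <= 0:
        return arr
    return ndimage.gaussian_filter(arr, sigma_vox, mode="nearest")


def _resample_certainty(cert: np.ndarray, src_grid: ImageGrid, dst_grid: ImageGrid) -> np.ndarray:
    src = ScalarImage(src_grid, cert)
    pts = dst_grid.voxel_centers()
    return np.maximum(trilinear_sample(src, pts, fill_value=0.0), 0.0)


def morphons_register(
    fixed: ScalarImage,
    moving: ScalarImage,
    config: MorphonsConfig | None = None,
) -> DisplacementField:
    """Multi-resolution Morphons registration (pull-back field, mm).

    Dyadic levels coarse to fine; per-axis factors are clamped so every
    level keeps at least ``min_level_dim`` voxels per axis, and duplicate
    grids produced by clamping are merged (with a warning via the pyramid
    helper).  Accumulation uses the certainty-weighted running average

    ``u <- (c_a u + c (u + du)) / (c_a + c)``,  ``c_a <- (c_a^2 + c^2) / (c_a + c)``.
    """
    import warnings as _warnings

    cfg = config or MorphonsConfig()
    if fixed.grid != moving.grid:
        raise ValueError("fixed and moving must share a grid (pre-align first)")

    factors = [2 ** (cfg.levels - 1 - k) for k in range(cfg.levels)]
    grids: list[ImageGrid] = []
    for f in factors:
        g = pyramid_grid(fixed.grid, f, cfg.min_level_dim)
        if grids and g == grids[-1]:
            continue
        grids.append(g)
    if len(grids) < cfg.levels:
        _warnings.warn(
            f"image too small for {cfg.levels} dyadic levels; using {len(grids)}",
            stacklevel=2,
        )

    bank = cfg.filter_bank
    fld: DisplacementField | None = None
    cert_acc: np.ndarray | None = None
    for li, grid in enumerate(grids):
        final = li == len(grids) - 1
        # anti-aliased level images
        f_img = _level_image(fixed, grid)
        m_img = _level_image(moving, grid)
        if fld is None:
            fld = DisplacementField.zeros(grid)
            cert_acc = np.zeros(grid.dims)
        else:
            cert_acc = _resample_certainty(cert_acc, fld.grid, grid)
            fld = resample_field_to_grid(fld, grid)
        centers = grid.voxel_centers()
        sigma_vox = cfg.smoothing_sigma_factor
        fill = float(m_img.values.min())
        transfer = bank.frequency_responses(grid.dims)
        fixed_resp = bank.responses(f_img.values, transfer)
        cap = cfg.max_iterations_final if final else cfg.max_iterations_per_level
        mean_spacing = float(np.mean(grid.spacing))
        max_step_mm = cfg.max_step_voxels * mean_spacing
        for _ in range(cap):
            warped = trilinear_sample(m_img, centers + fld.vectors, fill)
            du, cert = phase_difference_update(
                f_img, ScalarImage(grid, warped), bank, fixed_resp, transfer
            )
            mag = np.linalg.norm(du, axis=-1)
            over = mag > max_step_mm
            if np.any(over):
                du[over] *= (max_step_mm / mag[over])[..., None]
            if float(np.abs(du).mean()) < cfg.update_tol_voxels * mean_spacing:
                break  # negligible update: leave the field untouched
            denom = cert_acc + cert
            safe = np.maximum(denom, 1e-30)
            new_u = (
                cert_acc[..., None] * fld.vectors
                + cert[..., None] * (fld.vectors + du)
            ) / safe[..., None]
            new_u[denom <= 0] = 0.0
            cert_acc = np.where(denom > 0, (cert_acc**2 + cert**2) / safe, 0.0)
            vectors = np.empty_like(new_u)
            for a in range(3):
                vectors[..., a] = _smooth(new_u[..., a], sigma_vox)
            cert_acc = _smooth(cert_acc, sigma_vox)
            fld = DisplacementField(grid, vectors)

    if fld.grid != fixed.grid:
        fld = resample_field_to_grid(fld, fixed.grid)
    return fld


def _level_image(image: ScalarImage, grid: ImageGrid) -> ScalarImage:
    if grid == image.grid:
        return image
    # per-axis anti-aliasing for per-axis (clamped) downsampling factors
    sigma_vox = [0.5 * d0 / d for d0, d in zip(image.grid.dims, grid.dims)]
    smoothed = ndimage.gaussian_filter(image.values, sigma_vox, mode="nearest")
    src = ScalarImage(image.grid, smoothed)
    return ScalarImage(grid, trilinear_sample(src, grid.voxel_centers()))
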