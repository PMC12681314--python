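"""Calibration-less preprocessing: coil compression and sensitivity estimation.

The pipeline mirrors how a calibration-less SMS acquisition is prepared for
reconstruction: (1) PCA compression of the physical channels to a small set
of virtual channels, computed from the entire spoke time series; (2)
conjugate-phase demodulation of the CAIPIRINHA cycling, which turns the
multiband data into a motion-averaged single-slice k-space per slice;
(3) density-compensated adjoint NUFFT to per-slice coil images; (4) FFT to
Cartesian k-space, extraction of the central 24x24 calibration region, and
ESPIRiT eigen-analysis to recover one sensitivity map set per slice.

Compression precedes demodulation and map estimation, so maps live in the
virtual-channel basis used by the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nufft import NufftPlan, radial_density_weights
from .simulator import CoilMaps, MultiCoilKSpace
from .trajectory import PhaseSchedule, RadialTrajectory

CALIB_SIZE = 24


@dataclass
class CompressionMatrix:
    """PCA coil-compression operator: rows are orthonormal virtual channels."""

    matrix: np.ndarray = field(repr=False)  # (C_virtual, C_physical)
    singular_values: np.ndarray = field(repr=False)  # all C_physical values

    @property
    def n_virtual(self) -> int:
        return self.matrix.shape[0]

    def retained_energy(self) -> float:
        """Fraction of total signal energy carried by the virtual channels."""
        s2 = self.singular_values**2
        return float(s2[: self.n_virtual].sum() / s2.sum())


def compress_coils(kspace: MultiCoilKSpace, n_virtual: int) -> tuple[MultiCoilKSpace, CompressionMatrix]:
    """Project physical channels onto the leading PCA virtual channels.

    The compression matrix holds the leading left singular vectors of the
    coil-by-samples data matrix (no mean-centring: MR k-space is
    DC-dominated and centring would distort it).
    """
    c = kspace.n_coils
    if not 1 <= n_virtual <= c:
        raise ValueError(f"n_virtual must be in [1, {c}], got {n_virtual}")
    x = kspace.data.reshape(c, -1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    mat = u[:, :n_virtual].conj().T
    out = MultiCoilKSpace(
        data=(mat @ x).reshape(n_virtual, kspace.n_spokes, kspace.points_per_spoke),
        trajectory=kspace.trajectory,
        schedule=kspace.schedule,
        fov_mm=kspace.fov_mm,
        noise_sigma=kspace.noise_sigma,
    )
    return out, CompressionMatrix(matrix=mat, singular_values=s)


def motion_averaged_slice_kspace(kspace: MultiCoilKSpace, schedule: PhaseSchedule | None = None) -> np.ndarray:
    """Demodulate the CAIPIRINHA cycling: conj-phase multiply per slice.

    Returns (n_slices, n_coils, n_spokes, points): spoke n of slice i is the
    acquired spoke multiplied by exp(-j*phase[n, i]).  All spokes keep their
    angles; a single time-collapsed adjoint per slice then averages motion
    while the other slices' contributions destructively interfere.
    """
    schedule = schedule or kspace.schedule
    if schedule.n_excitations < kspace.n_spokes:
        raise ValueError("schedule shorter than the spoke count")
    conj_phi = np.exp(-1j * schedule.phases_rad[: kspace.n_spokes])  # (n, NSli)
    return conj_phi.T[:, None, :, None] * kspace.data[None]


def slice_coil_images(
    slice_kspace: np.ndarray, trajectory: RadialTrajectory, grid_size: int
) -> np.ndarray:
    """Adjoint NUFFT (ramp density compensation) of per-slice k-space.

    ``slice_kspace``: (n_slices, n_coils, n_spokes, points) ->
    (n_slices, n_coils, N, N).
    """
    n_sli, n_coils = slice_kspace.shape[:2]
    coords = trajectory.coords.reshape(-1, 2)
    plan = NufftPlan(coords, grid_size)
    w = radial_density_weights(coords)
    flat = slice_kspace.reshape(n_sli, n_coils, -1)
    imgs = plan.adjoint(flat * w / flat.shape[-1])
    return imgs


def extract_calibration(coil_images: np.ndarray, calib_size: int = CALIB_SIZE) -> np.ndarray:
    """Central Cartesian k-space block of each coil image.

    ``coil_images``: (..., N, N) -> (..., calib_size, calib_size), centred on
    the DC bin of the fftshifted spectrum.
    """
    n = coil_images.shape[-1]
    if n < calib_size:
        raise ValueError(f"grid size {n} smaller than calibration size {calib_size}")
    spec = np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(coil_images, axes=(-2, -1)), axes=(-2, -1)),
        axes=(-2, -1),
    )
    lo = n // 2 - calib_size // 2
    return spec[..., lo : lo + calib_size, lo : lo + calib_size]


def espirit_maps(
    calibration: np.ndarray,
    kernel_size: int = 6,
    sv_threshold: float = 0.01,
    eig_threshold: float = 0.85,
    grid_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """ESPIRiT sensitivity estimation from a calibration block.

    Builds the block-Hankel matrix of sliding ``kernel_size`` windows over
    the (n_coils, calib, calib) calibration data, keeps the right singular
    vectors with sigma >= sv_threshold * sigma_max, forms the image-domain
    pixelwise operator (scaled so its top eigenvalue is <= 1), and returns
    the leading eigenvector per pixel as the single sensitivity map set.

    Returns ``(maps, eigenvalues)``: maps (n_coils, N, N) with per-pixel unit
    norm, zeroed where the leading eigenvalue falls below ``eig_threshold``;
    phase fixed so coil 0 is real non-negative.
    """
    calibration = np.asarray(calibration)
    n_coils, nc = calibration.shape[0], calibration.shape[-1]
    k = kernel_size
    if not 1 <= k <= nc:
        raise ValueError(f"kernel_size must be in [1, {nc}], got {k}")
    if not np.any(calibration):
        raise ValueError("calibration region is identically zero")
    n = grid_size or nc

    # block-Hankel matrix: rows are flattened k x k x C windows
    nwin = nc - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(calibration, (k, k), axis=(-2, -1))
    # windows: (C, nwin, nwin, k, k) -> (nwin*nwin, k*k*C)
    a = windows.transpose(1, 2, 3, 4, 0).reshape(nwin * nwin, k * k * n_coils)
    _, s, vh = np.linalg.svd(a, full_matrices=True)
    n_keep = max(1, int(np.sum(s >= sv_threshold * s[0])))
    # conjugated null-space kernels: the per-pixel eigenvector then comes out
    # in the same orientation as the sensitivities themselves
    kernels = vh[:n_keep].reshape(n_keep, k, k, n_coils)

    # image-domain kernels: g_q,c(x) = (1/k) sum_kappa v_q[kappa, c] e^{+2pi i kappa.x/N}
    pad = np.zeros((n_keep, n_coils, n, n), dtype=complex)
    lo = n // 2 - k // 2
    pad[:, :, lo : lo + k, lo : lo + k] = kernels.transpose(0, 3, 1, 2)
    g = np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(pad, axes=(-2, -1)), axes=(-2, -1)),
        axes=(-2, -1),
    ) * (n * n / k)

    gram = np.einsum("qcxy,qdxy->xycd", g, g.conj())
    eigvals, eigvecs = np.linalg.eigh(gram)
    lead = eigvals[..., -1].real
    maps = eigvecs[..., -1].transpose(2, 0, 1)  # (C, N, N)
    # per-pixel phase reference: coil 0 real non-negative
    ref = np.exp(-1j * np.angle(maps[0]))
    maps = maps * ref
    maps[:, lead < eig_threshold] = 0.0
    return maps, lead


def estimate_sensitivities(
    kspace: MultiCoilKSpace,
    grid_size: int,
    n_virtual: int | None = None,
    kernel_size: int = 6,
    sv_threshold: float = 0.01,
    eig_threshold: float = 0.85,
) -> tuple[CoilMaps, MultiCoilKSpace, CompressionMatrix | None]:
    """Full calibration-less pipeline: compress, demodulate, grid, ESPIRiT.

    Returns per-slice maps in the virtual-channel basis, the compressed
    k-space the solver should consume, and the compression matrix (None when
    no compression was requested).
    """
    comp_mat = None
    if n_virtual is not None and n_virtual < kspace.n_coils:
        kspace, comp_mat = compress_coils(kspace, n_virtual)
    traj = kspace.trajectory
    demod = motion_averaged_slice_kspace(kspace)
    imgs = slice_coil_images(demod, traj, grid_size)
    maps = np.empty_like(imgs)
    for i in range(traj.n_slices):
        calib = extract_calibration(imgs[i])
        maps[i], _ = espirit_maps(
            calib,
            kernel_size=kernel_size,
            sv_threshold=sv_threshold,
            eig_threshold=eig_threshold,
            grid_size=grid_size,
        )
    return CoilMaps(maps=maps), kspace, comp_mat
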