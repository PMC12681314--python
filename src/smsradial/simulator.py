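"""Synthetic-data generator: dynamic digital phantom and SMS radial acquisition.

This module is the digital analogue of a moving oral-cavity phantom imaged
with a multiband radial FLASH sequence.  It produces per-slice ground-truth
complex image series, smooth complex coil sensitivities, and noisy
multi-coil radial k-space generated through the same encoding model the
reconstruction inverts:

    y[c, n] = sum_i exp(j*phase[n, i]) * F( S[i, c] * x_i(f(n)) ) + noise

with F the NUFFT evaluated on spoke n's coordinates, phase the CAIPIRINHA
schedule, and f(n) the ground-truth frame active at excitation n.  The
signal model is steady-state complex magnetization per pixel: no relaxation
or flip-angle simulation, no off-resonance, and all spokes within a frame
see the same phantom state (intra-frame motion blur is not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .nufft import NufftPlan
from .trajectory import PhaseSchedule, RadialTrajectory


@dataclass
class MotionParams:
    """Sinusoidal translation of the moving structure.

    amplitude_px: peak displacement from rest (peak-to-peak = 2x amplitude).
    period_frames: frames per full protrusion/retraction cycle.
    direction: unit-ish (row, col) direction of motion.
    """

    amplitude_px: float = 6.0
    period_frames: float = 20.0
    direction: tuple[float, float] = (0.0, 1.0)


@dataclass
class DynamicPhantom:
    """Per-slice ground-truth complex image series.

    slices: (n_slices, n_frames, N, N) complex, magnitudes in [0, 1].
    centroids: (n_slices, n_frames, 2) ground-truth centre of each slice's
    moving ellipse, in pixel coordinates.
    """

    slices: np.ndarray = field(repr=False)
    motion_params: MotionParams = field(default_factory=MotionParams)
    seed: int = 0
    centroids: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def n_frames(self) -> int:
        return self.slices.shape[1]

    @property
    def grid_size(self) -> int:
        return self.slices.shape[-1]


@dataclass
class CoilMaps:
    """Per-slice, per-coil complex sensitivities: (n_slices, n_coils, N, N)."""

    maps: np.ndarray = field(repr=False)

    @property
    def n_slices(self) -> int:
        return self.maps.shape[0]

    @property
    def n_coils(self) -> int:
        return self.maps.shape[1]

    @property
    def grid_size(self) -> int:
        return self.maps.shape[-1]

    def rss(self) -> np.ndarray:
        """Root-sum-of-squares magnitude per slice: (n_slices, N, N)."""
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=1))


@dataclass
class MultiCoilKSpace:
    """Acquired complex samples [coil x spoke x point] with sequence metadata."""

    data: np.ndarray = field(repr=False)
    trajectory: RadialTrajectory
    schedule: PhaseSchedule
    fov_mm: float = 280.0
    noise_sigma: float = 0.0

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_spokes(self) -> int:
        return self.data.shape[1]

    @property
    def points_per_spoke(self) -> int:
        return self.data.shape[2]


def _ellipse(n: int, center: tuple[float, float], semi: tuple[float, float], angle_deg: float = 0.0) -> np.ndarray:
    """Soft-edged ellipse mask on an n x n grid (rows, cols)."""
    r, c = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
    a = np.deg2rad(angle_deg)
    dr, dc = r - center[0], c - center[1]
    u = np.cos(a) * dr + np.sin(a) * dc
    v = -np.sin(a) * dr + np.cos(a) * dc
    mask = ((u / semi[0]) ** 2 + (v / semi[1]) ** 2 <= 1.0).astype(float)
    return gaussian_filter(mask, sigma=1.0)


def make_phantom(
    grid_size: int,
    n_slices: int,
    n_frames: int,
    motion_params: MotionParams | None = None,
    seed: int = 0,
) -> DynamicPhantom:
    """Dynamic oral-cavity-like phantom.

    Every slice holds a static "head" ellipse whose orientation, size, and
    intensity differ per slice, a slice-specific constellation of static
    marker discs plus a smooth random tissue texture (so that leakage from
    one slice into another is detectable), and a brighter "tongue" ellipse
    whose centroid translates sinusoidally — the protrusion/retraction
    analogue.  A smooth low-order phase makes the images properly complex.
    """
    if grid_size < 32:
        raise ValueError(f"grid_size must be >= 32, got {grid_size}")
    if n_frames < 2:
        raise ValueError(f"n_frames must be >= 2, got {n_frames}")
    mp = motion_params or MotionParams()
    rng = np.random.default_rng(seed)
    n = grid_size
    center = (n / 2.0, n / 2.0)

    t = np.arange(n_frames, dtype=float)
    disp = mp.amplitude_px * np.sin(2.0 * np.pi * t / mp.period_frames)
    d = np.asarray(mp.direction, dtype=float)
    d = d / (np.linalg.norm(d) or 1.0)

    slices = np.empty((n_slices, n_frames, n, n), dtype=complex)
    centroids = np.empty((n_slices, n_frames, 2))
    rr, cc = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
    for i in range(n_slices):
        head_angle = 55.0 * i
        head_mask = _ellipse(
            n, center, (n * (0.36 + 0.025 * i), n * (0.31 - 0.015 * i)), head_angle
        )
        head = (0.40 + 0.06 * (i % 3)) * head_mask
        # smooth slice-specific texture over the head tissue
        texture = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 16)
        texture = 0.35 * texture / (np.abs(texture).max() or 1.0)
        # slice-specific static markers at distinct angular positions
        markers = np.zeros((n, n))
        for m in range(2 + i):
            ang = 2.0 * np.pi * (m + 0.5) / (2 + i) + 1.3 * i + 0.1 * rng.uniform()
            pos = (center[0] + 0.2 * n * np.sin(ang), center[1] + 0.2 * n * np.cos(ang))
            markers += 0.5 * _ellipse(n, pos, (n * 0.05, n * 0.05))
        # smooth per-slice phase: gentle linear + quadratic surface
        ph = (
            0.8 * (i - (n_slices - 1) / 2) * (cc - n / 2) / n
            + 0.5 * ((rr - n / 2) ** 2 + (cc - n / 2) ** 2) / n**2
        )
        phase = np.exp(1j * 2.0 * np.pi * 0.15 * ph)
        # slice-specific rest position of the moving structure
        rest_ang = 2.0 * np.pi * i / max(n_slices, 1) + 0.6
        rest = (
            n / 2 + 0.1 * n * np.sin(rest_ang),
            n / 2 + 0.1 * n * np.cos(rest_ang),
        )
        centroids[i] = np.stack([rest[0] + disp * d[0], rest[1] + disp * d[1]], axis=1)
        static = np.clip(head * (1.0 + texture * head_mask) + markers, 0.0, 1.0)
        for f in range(n_frames):
            tongue = 0.9 * _ellipse(
                n,
                (centroids[i, f, 0], centroids[i, f, 1]),
                (n * 0.09, n * 0.16),
                angle_deg=head_angle + 25.0,
            )
            mag = np.clip(static + tongue, 0.0, 1.0)
            slices[i, f] = mag * phase
    return DynamicPhantom(slices=slices, motion_params=mp, seed=seed, centroids=centroids)


def make_coil_maps(grid_size: int, n_slices: int, n_coils: int, seed: int = 0) -> CoilMaps:
    """Smooth complex sensitivities: Gaussian lobes on a ring around the FOV.

    A generic surrogate for a multi-channel head/neck array: coil c's
    magnitude is a broad Gaussian centred on the FOV ring at angle 2*pi*c/C,
    with a mild per-slice rotation of the ring and a small per-coil linear
    phase.  Each map is then hard low-passed to the central 1/8 of the grid
    bandwidth, so the maps are strictly bandlimited (as physical coil
    sensitivities effectively are).
    """
    if n_coils < 2:
        raise ValueError(f"n_coils must be >= 2, got {n_coils}")
    rng = np.random.default_rng(seed)
    n = grid_size
    rr, cc = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
    maps = np.empty((n_slices, n_coils, n, n), dtype=complex)
    sigma = 0.55 * n
    ring = 0.52 * n
    # hard low-pass window: central block of half-width n//16 bins
    half = max(n // 16, 2)
    band = np.zeros((n, n))
    lo = n // 2 - half
    band[lo : lo + 2 * half, lo : lo + 2 * half] = 1.0
    for i in range(n_slices):
        for c in range(n_coils):
            ang = 2.0 * np.pi * c / n_coils + 0.07 * i + 0.02 * rng.standard_normal()
            pr = n / 2 + ring * np.sin(ang)
            pc = n / 2 + ring * np.cos(ang)
            mag = np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2) / (2.0 * sigma**2)) + 0.05
            # small linear phase, <= ~1.5 cycles across the FOV
            slope = 1.5 * rng.uniform(-1.0, 1.0, size=2)
            phase = 2.0 * np.pi * (slope[0] * rr + slope[1] * cc) / n + 2.0 * np.pi * c / n_coils
            raw = mag * np.exp(1j * phase)
            spec = np.fft.fftshift(np.fft.fft2(raw)) * band
            maps[i, c] = np.fft.ifft2(np.fft.ifftshift(spec))
    return CoilMaps(maps=maps)


def acquire(
    phantom: DynamicPhantom,
    maps: CoilMaps,
    trajectory: RadialTrajectory,
    schedule: PhaseSchedule,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> MultiCoilKSpace:
    """Simulate the SMS radial acquisition of a dynamic phantom.

    Spokes are grouped by the ground-truth frame active at their excitation
    time (trajectory.spokes_per_frame excitations per frame); each group is
    encoded with one NUFFT plan.  Noise is i.i.d. circular complex Gaussian,
    ``noise_sigma`` per real/imaginary component, independent across coils.
    """
    n_sli, n_coils = maps.n_slices, maps.n_coils
    if phantom.n_slices != n_sli:
        raise ValueError("phantom and coil maps disagree on the number of slices")
    if phantom.grid_size != maps.grid_size:
        raise ValueError("phantom and coil maps disagree on grid size")
    if schedule.n_excitations < trajectory.n_spokes:
        raise ValueError("phase schedule shorter than the number of spokes")
    if schedule.n_slices != n_sli:
        raise ValueError("schedule and maps disagree on the number of slices")
    spf = trajectory.spokes_per_frame
    needed_frames = int(np.ceil(trajectory.n_spokes / spf))
    if phantom.n_frames < min(needed_frames, max(trajectory.n_spokes // spf, 1)):
        raise ValueError("phantom has too few frames for this trajectory")

    ppe = trajectory.points_per_spoke
    data = np.empty((n_coils, trajectory.n_spokes, ppe), dtype=complex)
    factors = schedule.factors()  # (n_excitations, n_slices)
    for start in range(0, trajectory.n_spokes, spf):
        stop = min(start + spf, trajectory.n_spokes)
        f = min(start // spf, phantom.n_frames - 1)
        coords = trajectory.coords[start:stop].reshape(-1, 2)
        plan = NufftPlan(coords, phantom.grid_size)
        # batch over (slice, coil): weighted images -> k-space samples
        imgs = maps.maps * phantom.slices[:, f][:, None]  # (NSli, C, N, N)
        ks = plan.forward(imgs).reshape(n_sli, n_coils, stop - start, ppe)
        phi = factors[start:stop].T[:, None, :, None]  # (NSli, 1, spokes, 1)
        data[:, start:stop] = np.sum(phi * ks, axis=0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data += noise_sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    return MultiCoilKSpace(
        data=data, trajectory=trajectory, schedule=schedule, noise_sigma=noise_sigma
    )
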