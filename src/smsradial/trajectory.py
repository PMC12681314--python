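"""Radial trajectories and CAIPIRINHA phase schedules.

Golden-angle (GA) radial sampling advances the spoke angle by 180°/GR per
excitation, GR = (1+√5)/2, which gives near-uniform k-space coverage for any
retrospectively chosen window length.  The SMS-GA variant divides that
increment by the number of simultaneously excited slices so that, within a
frame, the spokes belonging to the different CAIPIRINHA phase states
interleave evenly and the inter-slice interference is more destructive.

Slice separation relies on CAIPIRINHA phase cycling: at excitation n the
multiband pulse imposes on slice i the phase i·φ_n with
φ_n = mod(2π n / NSli, 2π), so that over a full period of NSli excitations
the slice phases form a discrete Fourier basis across slices.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0


class SamplingScheme(str, enum.Enum):
    """Radial angle-increment scheme."""

    GA = "GA"
    SMS_GA = "SMS_GA"


def angular_increment(scheme: SamplingScheme | str, n_slices: int) -> float:
    """Angular gap in degrees between successive radial spokes.

    GA uses 180°/GR regardless of the multiband factor; SMS-GA divides by
    ``n_slices`` so consecutive phase-cycle states fan out across the frame.
    """
    scheme = SamplingScheme(scheme)
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    base = 180.0 / GOLDEN_RATIO
    if scheme is SamplingScheme.GA:
        return base
    return base / n_slices


def spoke_angles(n_spokes: int, increment_deg: float) -> np.ndarray:
    """Angles (degrees, in [0, 360)) of ``n_spokes`` spokes, first at 0°."""
    if n_spokes < 1:
        raise ValueError(f"n_spokes must be >= 1, got {n_spokes}")
    return np.mod(np.arange(n_spokes) * float(increment_deg), 360.0)


def sample_coordinates(angles_deg: np.ndarray, points_per_spoke: int) -> np.ndarray:
    """Per-sample k-space coordinates in cycles/pixel.

    Each spoke is a full diameter through k = 0.  Readout radii span
    [-0.5, +0.5) endpoint-exclusive with spacing 1/points_per_spoke, so an
    even number of points places one sample exactly at DC.

    Returns array of shape (n_spokes, points_per_spoke, 2) — (kx, ky).
    """
    if points_per_spoke < 2:
        raise ValueError(f"points_per_spoke must be >= 2, got {points_per_spoke}")
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    kr = -0.5 + np.arange(points_per_spoke) / points_per_spoke
    rad = np.deg2rad(angles)
    direction = np.stack([np.cos(rad), np.sin(rad)], axis=-1)  # (S, 2)
    return kr[None, :, None] * direction[:, None, :]


def bin_spokes(n_spokes: int, spokes_per_frame: int) -> tuple[np.ndarray, int]:
    """Map each spoke to a frame index; trailing incomplete frames are dropped.

    Returns ``(frame_index, n_frames)`` where ``frame_index[m]`` is the frame
    of spoke m (−1 for discarded trailing spokes).  Zero frames is legal here;
    reconstruction entry points treat it as an error.
    """
    if n_spokes < 1:
        raise ValueError(f"n_spokes must be >= 1, got {n_spokes}")
    if spokes_per_frame < 1:
        raise ValueError(f"spokes_per_frame must be >= 1, got {spokes_per_frame}")
    n_frames = n_spokes // spokes_per_frame
    idx = np.arange(n_spokes) // spokes_per_frame
    idx[idx >= n_frames] = -1
    return idx, int(n_frames)


def frame_duration(spokes_per_frame: int, tr_ms: float) -> float:
    """Temporal resolution in milliseconds: spokes/frame × TR."""
    if spokes_per_frame < 1 or tr_ms <= 0:
        raise ValueError("spokes_per_frame and tr_ms must be positive")
    return spokes_per_frame * tr_ms


@dataclass
class PhaseSchedule:
    """Per-excitation, per-slice CAIPIRINHA phases (radians, in [0, 2π)).

    ``phases_rad[n, i]`` is the phase imposed on slice i at excitation n;
    slice 0 is the zero-phase reference.  The schedule is periodic in n with
    period ``n_slices``.
    """

    n_slices: int
    n_excitations: int
    phases_rad: np.ndarray = field(repr=False)

    def factors(self) -> np.ndarray:
        """Unit-modulus complex factors exp(j·phase), shape (n, n_slices)."""
        return np.exp(1j * self.phases_rad)


def caipirinha_schedule(n_slices: int, n_excitations: int) -> PhaseSchedule:
    """CAIPIRINHA phase schedule: phase[n, i] = mod(2π·i·n / NSli, 2π)."""
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    if n_excitations < 1:
        raise ValueError(f"n_excitations must be >= 1, got {n_excitations}")
    n = np.arange(n_excitations)[:, None]
    i = np.arange(n_slices)[None, :]
    phases = np.mod(2.0 * np.pi * i * n / n_slices, 2.0 * np.pi)
    return PhaseSchedule(n_slices=n_slices, n_excitations=n_excitations, phases_rad=phases)


@dataclass
class RadialTrajectory:
    """A full radial acquisition: angles, sample coordinates, frame binning."""

    scheme: SamplingScheme
    n_slices: int
    n_spokes: int
    points_per_spoke: int
    angles_deg: np.ndarray = field(repr=False)
    coords: np.ndarray = field(repr=False)  # (n_spokes, points_per_spoke, 2)
    spokes_per_frame: int = 25
    tr_ms: float = 2.5

    @property
    def n_frames(self) -> int:
        return self.n_spokes // self.spokes_per_frame

    @property
    def frame_duration_ms(self) -> float:
        return frame_duration(self.spokes_per_frame, self.tr_ms)

    def frame_slice(self, frame: int) -> slice:
        """Spoke index range belonging to ``frame``."""
        if not 0 <= frame < self.n_frames:
            raise IndexError(f"frame {frame} out of range [0, {self.n_frames})")
        start = frame * self.spokes_per_frame
        return slice(start, start + self.spokes_per_frame)

    def frame_coords(self, frame: int) -> np.ndarray:
        """Sample coordinates of one frame, flattened to (K, 2)."""
        return self.coords[self.frame_slice(frame)].reshape(-1, 2)


def make_trajectory(
    scheme: SamplingScheme | str,
    n_slices: int,
    n_spokes: int,
    points_per_spoke: int = 128,
    spokes_per_frame: int = 25,
    tr_ms: float = 2.5,
) -> RadialTrajectory:
    """Build a GA or SMS-GA trajectory with its sample coordinates."""
    scheme = SamplingScheme(scheme)
    inc = angular_increment(scheme, n_slices)
    angles = spoke_angles(n_spokes, inc)
    coords = sample_coordinates(angles, points_per_spoke)
    return RadialTrajectory(
        scheme=scheme,
        n_slices=n_slices,
        n_spokes=n_spokes,
        points_per_spoke=points_per_spoke,
        angles_deg=angles,
        coords=coords,
        spokes_per_frame=spokes_per_frame,
        tr_ms=tr_ms,
    )
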