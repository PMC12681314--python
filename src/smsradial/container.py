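"""HDF5 container for acquisitions, ground truth, maps, and reconstructions.

Layout (one file per run):

    attrs:  schema_version, scheme, n_slices, tr_ms, points_per_spoke,
            spokes_per_frame, fov_mm, noise_sigma
    kspace/data_re, data_im          (C, spokes, points)
    trajectory/angles_deg, coords    coords in cycles/pixel
    schedule/phases_rad              (excitations, n_slices)
    truth/slice{i}_re/_im            ground-truth videos (simulated runs)
    truth/centroids, truth/maps_re/_im
    maps/slice{i}_re/_im             estimated sensitivities
    compression/matrix_re/_im, compression/singular_values
    recon/slice{i}_re/_im, recon/objective, recon/primal_residual, ...
    metrics/...                      free-form numeric results

Complex arrays are stored as paired real/imaginary float datasets so the
files stay portable across HDF5 readers.  Readers reject files whose major
schema version they do not understand.
"""

from __future__ import annotations

import numpy as np
import h5py

from .recon import ReconResult
from .simulator import CoilMaps, DynamicPhantom, MotionParams, MultiCoilKSpace
from .trajectory import (
    PhaseSchedule,
    RadialTrajectory,
    SamplingScheme,
)

SCHEMA_VERSION = "1.0"


class ContainerError(RuntimeError):
    """Raised for missing datasets or incompatible schema versions."""


def _write_complex(group: h5py.Group, name: str, arr: np.ndarray) -> None:
    arr = np.asarray(arr)
    group.create_dataset(f"{name}_re", data=arr.real)
    group.create_dataset(f"{name}_im", data=arr.imag)


def _read_complex(group: h5py.Group, name: str) -> np.ndarray:
    try:
        return group[f"{name}_re"][()] + 1j * group[f"{name}_im"][()]
    except KeyError as exc:
        raise ContainerError(f"missing complex dataset '{group.name}/{name}'") from exc


def _check_version(f: h5py.File) -> None:
    ver = f.attrs.get("schema_version")
    if ver is None:
        raise ContainerError("not an smsradial container: no schema_version attribute")
    major = str(ver).split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise ContainerError(
            f"container schema version {ver} not supported (reader understands "
            f"major version {SCHEMA_VERSION.split('.')[0]})"
        )


def write_simulation(
    path,
    kspace: MultiCoilKSpace,
    phantom: DynamicPhantom | None = None,
    true_maps: CoilMaps | None = None,
) -> None:
    """Write an acquisition (and, for simulated runs, its ground truth)."""
    traj, sched = kspace.trajectory, kspace.schedule
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["scheme"] = traj.scheme.value
        f.attrs["n_slices"] = traj.n_slices
        f.attrs["tr_ms"] = traj.tr_ms
        f.attrs["points_per_spoke"] = traj.points_per_spoke
        f.attrs["spokes_per_frame"] = traj.spokes_per_frame
        f.attrs["fov_mm"] = kspace.fov_mm
        f.attrs["noise_sigma"] = kspace.noise_sigma
        _write_complex(f.create_group("kspace"), "data", kspace.data)
        g = f.create_group("trajectory")
        g.create_dataset("angles_deg", data=traj.angles_deg)
        g.create_dataset("coords", data=traj.coords)
        f.create_group("schedule").create_dataset("phases_rad", data=sched.phases_rad)
        if phantom is not None:
            g = f.create_group("truth")
            for i in range(phantom.n_slices):
                _write_complex(g, f"slice{i}", phantom.slices[i])
            if phantom.centroids is not None:
                g.create_dataset("centroids", data=phantom.centroids)
            g.attrs["motion_amplitude_px"] = phantom.motion_params.amplitude_px
            g.attrs["motion_period_frames"] = phantom.motion_params.period_frames
            g.attrs["seed"] = phantom.seed
            if true_maps is not None:
                _write_complex(g, "maps", true_maps.maps)


def read_acquisition(path) -> MultiCoilKSpace:
    """Read k-space + trajectory + schedule back into memory."""
    with h5py.File(path, "r") as f:
        _check_version(f)
        if "kspace" not in f or "trajectory" not in f:
            raise ContainerError("container lacks kspace/trajectory groups")
        traj = RadialTrajectory(
            scheme=SamplingScheme(f.attrs["scheme"]),
            n_slices=int(f.attrs["n_slices"]),
            n_spokes=f["trajectory/angles_deg"].shape[0],
            points_per_spoke=int(f.attrs["points_per_spoke"]),
            angles_deg=f["trajectory/angles_deg"][()],
            coords=f["trajectory/coords"][()],
            spokes_per_frame=int(f.attrs["spokes_per_frame"]),
            tr_ms=float(f.attrs["tr_ms"]),
        )
        phases = f["schedule/phases_rad"][()]
        sched = PhaseSchedule(
            n_slices=traj.n_slices, n_excitations=phases.shape[0], phases_rad=phases
        )
        return MultiCoilKSpace(
            data=_read_complex(f["kspace"], "data"),
            trajectory=traj,
            schedule=sched,
            fov_mm=float(f.attrs["fov_mm"]),
            noise_sigma=float(f.attrs["noise_sigma"]),
        )


def read_truth(path) -> DynamicPhantom:
    """Read the ground-truth phantom (simulated containers only)."""
    with h5py.File(path, "r") as f:
        _check_version(f)
        if "truth" not in f:
            raise ContainerError("container holds no ground truth")
        g = f["truth"]
        n_slices = int(f.attrs["n_slices"])
        slices = np.stack([_read_complex(g, f"slice{i}") for i in range(n_slices)])
        return DynamicPhantom(
            slices=slices,
            motion_params=MotionParams(
                amplitude_px=float(g.attrs["motion_amplitude_px"]),
                period_frames=float(g.attrs["motion_period_frames"]),
            ),
            seed=int(g.attrs["seed"]),
            centroids=g["centroids"][()] if "centroids" in g else None,
        )


def read_true_maps(path) -> CoilMaps:
    with h5py.File(path, "r") as f:
        _check_version(f)
        if "truth" not in f or "truth/maps_re" not in f:
            raise ContainerError("container holds no ground-truth coil maps")
        return CoilMaps(maps=_read_complex(f["truth"], "maps"))


def write_maps(path, maps: CoilMaps, compression=None) -> None:
    """Append estimated sensitivities (and the compression matrix) to a container."""
    with h5py.File(path, "a") as f:
        _check_version(f)
        if "maps" in f:
            del f["maps"]
        g = f.create_group("maps")
        for i in range(maps.n_slices):
            _write_complex(g, f"slice{i}", maps.maps[i])
        if compression is not None:
            if "compression" in f:
                del f["compression"]
            g = f.create_group("compression")
            _write_complex(g, "matrix", compression.matrix)
            g.create_dataset("singular_values", data=compression.singular_values)


def read_maps(path) -> CoilMaps:
    with h5py.File(path, "r") as f:
        _check_version(f)
        if "maps" not in f:
            raise ContainerError("container holds no estimated maps")
        n_slices = int(f.attrs["n_slices"])
        return CoilMaps(
            maps=np.stack([_read_complex(f["maps"], f"slice{i}") for i in range(n_slices)])
        )


def write_recon(path, result: ReconResult, name: str = "recon") -> None:
    with h5py.File(path, "a") as f:
        _check_version(f)
        if name in f:
            del f[name]
        g = f.create_group(name)
        for i in range(result.videos.shape[0]):
            _write_complex(g, f"slice{i}", result.videos[i])
        for key in ("objective", "primal_residual", "dual_residual", "rho"):
            val = getattr(result, key)
            if val is not None:
                g.create_dataset(key, data=np.asarray(val))
        g.attrs["converged"] = bool(result.converged)


def read_recon(path, name: str = "recon") -> np.ndarray:
    with h5py.File(path, "r") as f:
        _check_version(f)
        if name not in f:
            raise ContainerError(f"container holds no '{name}' group")
        n_slices = int(f.attrs["n_slices"])
        return np.stack([_read_complex(f[name], f"slice{i}") for i in range(n_slices)])


def write_metrics(path, table: dict) -> None:
    """Store a flat dict of numeric arrays/scalars under metrics/."""
    with h5py.File(path, "a") as f:
        _check_version(f)
        if "metrics" in f:
            del f["metrics"]
        g = f.create_group("metrics")
        for key, val in table.items():
            g.create_dataset(key, data=np.asarray(val))
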