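"""Core in-memory containers for volume stacks and label volumes.

Axis convention throughout the package: arrays are indexed ``(z, y, x)``
where ``z`` is the serial-section (milling) direction, ``y`` the image row
and ``x`` the image column.  Voxel sizes are physical, in nanometres, in the
same ``(z, y, x)`` order.  The fiber axis of a thread specimen is recorded
in metadata as a unit 3-vector in this coordinate frame.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = [
    "VolumeStack",
    "PhaseLabelVolume",
    "PhantomTruth",
    "array_checksum",
    "axis_vector",
]

_AXIS_VECTORS = {
    "z": (1.0, 0.0, 0.0),
    "y": (0.0, 1.0, 0.0),
    "x": (0.0, 0.0, 1.0),
}


def axis_vector(axis: str | np.ndarray) -> np.ndarray:
    """Return a unit 3-vector in (z, y, x) order for an axis name or vector."""
    if isinstance(axis, str):
        try:
            return np.asarray(_AXIS_VECTORS[axis.lower()], dtype=float)
        except KeyError:
            raise ValueError(f"unknown axis name {axis!r}; expected one of z, y, x")
    v = np.asarray(axis, dtype=float)
    if v.shape != (3,):
        raise ValueError("axis vector must have exactly 3 components (z, y, x)")
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("axis vector must be nonzero")
    return v / n


def array_checksum(arr: np.ndarray) -> str:
    """sha256 of an array's contiguous bytes (dtype and shape included)."""
    a = np.ascontiguousarray(arr)
    h = hashlib.sha256()
    h.update(str(a.dtype).encode())
    h.update(str(a.shape).encode())
    h.update(a.tobytes())
    return h.hexdigest()


@dataclass
class VolumeStack:
    """A 3D scalar intensity volume with physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensity values.
    voxel_size_nm : tuple of 3 floats
        Physical voxel edge lengths in nm, (z, y, x) order.
    fiber_axis : str or 3-vector
        Direction of the fiber axis in the (z, y, x) frame.  Defaults to
        the milling direction ``z`` (transverse serial sections).
    meta : dict
        Free-form provenance / acquisition metadata.
    """

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float]
    fiber_axis: Any = "z"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        vs = tuple(float(v) for v in self.voxel_size_nm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size_nm must be 3 positive reals (z, y, x)")
        self.voxel_size_nm = vs
        self.fiber_axis = axis_vector(self.fiber_axis)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def checksum(self) -> str:
        return array_checksum(self.data)

    def copy_with(self, data: np.ndarray, **meta: Any) -> "VolumeStack":
        m = dict(self.meta)
        m.update(meta)
        return VolumeStack(data, self.voxel_size_nm, self.fiber_axis, m)


@dataclass
class PhaseLabelVolume:
    """Integer-labelled volume mapping voxels to named phases and instances.

    ``phases`` holds per-voxel phase codes (0 = background) named through
    ``phase_names``; ``instances`` optionally holds per-voxel object IDs
    (vesicle / granule numbers, 0 = background).
    """

    phases: np.ndarray
    phase_names: Mapping[int, str]
    voxel_size_nm: tuple[float, float, float]
    instances: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases)
        if self.phases.ndim not in (2, 3):
            raise ValueError("phases must be a 2D or 3D integer array")
        if not np.issubdtype(self.phases.dtype, np.integer):
            raise ValueError("phase labels must be integers")
        if self.phases.min() < 0:
            raise ValueError("phase labels must be non-negative (0 = background)")
        if self.instances is not None:
            self.instances = np.asarray(self.instances)
            if self.instances.shape != self.phases.shape:
                raise ValueError("instances must be congruent with phases")
        self.voxel_size_nm = tuple(float(v) for v in self.voxel_size_nm)
        self.phase_names = dict(self.phase_names)

    def phase_mask(self, name: str) -> np.ndarray:
        codes = [c for c, n in self.phase_names.items() if n == name]
        if not codes:
            raise KeyError(f"phase {name!r} not present; have {sorted(self.phase_names.values())}")
        return np.isin(self.phases, codes)

    def instance_ids(self) -> np.ndarray:
        if self.instances is None:
            return np.array([], dtype=int)
        ids = np.unique(self.instances)
        return ids[ids > 0]


@dataclass
class PhantomTruth:
    """Generator-side ground truth bundled with a synthetic phantom."""

    clean: VolumeStack
    config: Any
    labels: PhaseLabelVolume | None = None
    ls_mask: np.ndarray | None = None
    support_mask: np.ndarray | None = None
    realized: dict = field(default_factory=dict)
    shifts_px: np.ndarray | None = None
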