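"""Core domain containers for multi-echo placental MRI.

The in-memory model is deliberately small: an :class:`EchoTrain` describes
the acquisition timing, a :class:`MultiEchoVolume` holds the 4D magnitude
stack (x, y, z, echo) with voxel dimensions in mm, and a
:class:`PlacentaMask` is a binary region of interest on the same 3D grid.
Arrays keep the on-disk orientation; no resampling is ever applied because
every derived metric is orientation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Recognised scanner field-strength labels.
FIELD_LABELS = ("0.55T", "1.5T", "3T", "custom")

#: Printed four-echo trains (ms) of the multi-echo gradient-echo EPI
#: protocol at each field strength.
FIELD_ECHO_TIMES_MS = {
    "0.55T": (46.0, 120.0, 194.0, 268.0),
    "1.5T": (7.84, 60.574, 113.308, 116.041),
    "3T": (13.8, 70.4, 127.0, 183.6),
}

#: Nominal isotropic voxel size (mm) of the protocol at each field strength.
FIELD_VOXEL_MM = {"0.55T": 3.1, "1.5T": 2.5, "3T": 3.0}


def _check_field_label(field_label: str) -> str:
    if field_label not in FIELD_LABELS:
        raise ValueError(
            f"unknown field label {field_label!r}; expected one of {FIELD_LABELS}"
        )
    return field_label


@dataclass(frozen=True)
class EchoTrain:
    """Ordered echo times (ms) tagged with a field-strength label.

    Parameters
    ----------
    field_label:
        One of ``"0.55T"``, ``"1.5T"``, ``"3T"`` or ``"custom"``.
    echo_times_ms:
        At least two strictly increasing, strictly positive echo times.
    """

    field_label: str
    echo_times_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        _check_field_label(self.field_label)
        tes = tuple(float(t) for t in self.echo_times_ms)
        if len(tes) < 2:
            raise ValueError("echo train needs at least 2 echoes")
        if any(t <= 0 for t in tes):
            raise ValueError("echo times must be positive")
        if any(b <= a for a, b in zip(tes, tes[1:])):
            raise ValueError("echo times must be strictly increasing")
        object.__setattr__(self, "echo_times_ms", tes)

    @classmethod
    def for_field(cls, field_label: str) -> "EchoTrain":
        """The printed protocol echo train for a named field strength."""
        if field_label not in FIELD_ECHO_TIMES_MS:
            raise ValueError(
                f"no built-in echo train for {field_label!r}; "
                f"known fields: {sorted(FIELD_ECHO_TIMES_MS)}"
            )
        return cls(field_label, FIELD_ECHO_TIMES_MS[field_label])

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.echo_times_ms, dtype=float)


def _check_voxel_dims(voxel_dims_mm: Sequence[float]) -> tuple[float, float, float]:
    dims = tuple(float(d) for d in voxel_dims_mm)
    if len(dims) != 3:
        raise ValueError("voxel_dims_mm must have 3 entries")
    if any(d <= 0 for d in dims):
        raise ValueError("voxel dimensions must be positive")
    return dims


@dataclass
class MultiEchoVolume:
    """4D magnitude image stack indexed (x, y, z, echo)."""

    data: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    echo_train: EchoTrain

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] != self.echo_train.n_echoes:
            raise ValueError(
                f"echo count mismatch: data has {self.data.shape[3]} volumes "
                f"but echo train has {self.echo_train.n_echoes} echo times"
            )
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")
        self.voxel_dims_mm = _check_voxel_dims(self.voxel_dims_mm)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims_mm))


@dataclass
class PlacentaMask:
    """Binary placental region of interest on a 3D grid."""

    data: np.ndarray
    voxel_dims_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got {arr.ndim}D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1 (binarize first)")
        self.data = arr.astype(bool)
        self.voxel_dims_mm = _check_voxel_dims(self.voxel_dims_mm)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims_mm))

    def require_nonempty(self) -> None:
        if self.n_voxels == 0:
            raise ValueError("placental mask is empty")


@dataclass
class CohortRecord:
    """One subject's scan: field, gestational age and mean placental T2*."""

    subject_id: str
    field_label: str
    ga_weeks: float
    mean_t2star_ms: float
    bmi: float | None = None
    maternal_age: float | None = None
    placental_location: str | None = None

    def __post_init__(self) -> None:
        _check_field_label(self.field_label)
        if not (10.0 < self.ga_weeks < 45.0):
            raise ValueError(
                f"ga_weeks must lie in (10, 45); got {self.ga_weeks}"
            )
        if self.mean_t2star_ms <= 0:
            raise ValueError("mean_t2star_ms must be positive")
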