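"""NIfTI and table I/O.

Volumes, masks and derived maps travel as ``.nii``/``.nii.gz``; echo
timing and field-strength metadata, which NIfTI headers cannot carry in a
standard field, live in a JSON sidecar written next to each output
(``<stem>.json`` with keys ``echo_times_ms``, ``field_label``,
``voxel_dims_mm``). Cohort tables are CSV with columns ``subject_id``,
``field_label``, ``ga_weeks``, ``mean_t2star_ms`` and optional ``bmi``,
``maternal_age``, ``placental_location``.

Arrays are used in the on-disk orientation; voxel dimensions come from the
header zooms. No resampling or reorientation is performed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CohortRecord, EchoTrain, MultiEchoVolume, PlacentaMask
from .metrics import MorphMap, PlacentalMetrics
from .relaxometry import T2StarMap

__all__ = [
    "read_multiecho",
    "read_mask",
    "write_map",
    "read_map",
    "write_volume",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_metrics_csv",
    "sidecar_path",
    "write_sidecar",
    "read_sidecar",
]

REQUIRED_COHORT_COLUMNS = ("subject_id", "field_label", "ga_weeks", "mean_t2star_ms")
OPTIONAL_COHORT_COLUMNS = ("bmi", "maternal_age", "placental_location")


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, ...], nib.Nifti1Image]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    # NIfTI zooms are float32; the JSON sidecar, when present, carries the
    # exact voxel dimensions and takes precedence.
    sp = sidecar_path(path)
    if sp.exists():
        try:
            dims = json.loads(sp.read_text()).get("voxel_dims_mm")
        except (json.JSONDecodeError, OSError):
            dims = None
        if dims is not None and len(dims) == 3:
            zooms = tuple(float(d) for d in dims)
    return data, zooms, img


def sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_sidecar(path, echo_train: EchoTrain | None, voxel_dims_mm: Sequence[float]) -> Path:
    payload = {"voxel_dims_mm": [float(d) for d in voxel_dims_mm]}
    if echo_train is not None:
        payload["echo_times_ms"] = list(echo_train.echo_times_ms)
        payload["field_label"] = echo_train.field_label
    sp = sidecar_path(path)
    sp.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return sp


def read_sidecar(path) -> dict:
    return json.loads(sidecar_path(path).read_text())


def read_multiecho(
    paths: str | Path | Sequence[str | Path],
    echo_times_ms: Sequence[float],
    field_label: str = "custom",
) -> MultiEchoVolume:
    """Load a multi-echo stack from one 4D NIfTI or N 3D NIfTIs.

    ``echo_times_ms`` must match the number of echo volumes; the echo axis
    order follows the echo-time order given.
    """
    train = EchoTrain(field_label, tuple(echo_times_ms))
    if isinstance(paths, (str, Path)):
        data, zooms, _ = _load_nifti(paths)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise ValueError(f"{paths}: expected a 4D volume, got {data.ndim}D")
        if data.shape[3] != train.n_echoes:
            raise ValueError(
                f"echo count mismatch: {paths} holds {data.shape[3]} volumes "
                f"but {train.n_echoes} echo times were given"
            )
    else:
        paths = list(paths)
        if len(paths) != train.n_echoes:
            raise ValueError(
                f"echo count mismatch: {len(paths)} files "
                f"but {train.n_echoes} echo times were given"
            )
        volumes, zooms = [], None
        for p in paths:
            vol, z, _ = _load_nifti(p)
            if vol.ndim != 3:
                raise ValueError(f"{p}: expected a 3D volume, got {vol.ndim}D")
            if zooms is None:
                zooms = z
                shape = vol.shape
            elif vol.shape != shape:
                raise ValueError(f"{p}: grid shape {vol.shape} differs from {shape}")
            volumes.append(vol)
        data = np.stack(volumes, axis=-1)
    return MultiEchoVolume(data=data, voxel_dims_mm=zooms, echo_train=train)


def read_mask(path, reference: MultiEchoVolume) -> PlacentaMask:
    """Load a mask on the reference grid; soft values are thresholded at 0.5."""
    data, _, _ = _load_nifti(path)
    if data.shape != reference.grid_shape:
        raise ValueError(
            f"mask grid {data.shape} does not match volume grid {reference.grid_shape}"
        )
    return PlacentaMask(
        data=(data > 0.5).astype(np.uint8), voxel_dims_mm=reference.voxel_dims_mm
    )


def _affine(voxel_dims_mm: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_dims_mm
    return aff


def write_volume(volume: MultiEchoVolume, path) -> Path:
    """Write a multi-echo stack as 4D NIfTI plus its metadata sidecar."""
    img = nib.Nifti1Image(volume.data, _affine(volume.voxel_dims_mm))
    img.header.set_zooms(tuple(volume.voxel_dims_mm) + (1.0,))
    nib.save(img, str(path))
    write_sidecar(path, volume.echo_train, volume.voxel_dims_mm)
    return Path(path)


def write_map(map3d: T2StarMap | MorphMap | PlacentaMask, path) -> Path:
    """Write a 3D map (T2*, morphology or mask) as NIfTI with a sidecar."""
    if isinstance(map3d, T2StarMap):
        data, dims, train = map3d.t2star_ms, map3d.voxel_dims_mm, map3d.echo_train
    elif isinstance(map3d, MorphMap):
        data, dims, train = map3d.distance_mm, map3d.voxel_dims_mm, None
    elif isinstance(map3d, PlacentaMask):
        data, dims, train = map3d.data.astype(np.uint8), map3d.voxel_dims_mm, None
    else:
        raise TypeError(f"cannot write object of type {type(map3d).__name__}")
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(dims))
    img.header.set_zooms(tuple(dims))
    nib.save(img, str(path))
    write_sidecar(path, train, dims)
    return Path(path)


def read_map(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3D map back as (values, voxel_dims_mm)."""
    data, zooms, _ = _load_nifti(path)
    return data, zooms


def read_cohort_csv(path) -> list[CohortRecord]:
    """Read a cohort table, validating the required columns."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} is missing column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for opt in OPTIONAL_COHORT_COLUMNS:
            if opt in df.columns:
                val = getattr(row, opt)
                if pd.notna(val):
                    kwargs[opt] = val
        records.append(
            CohortRecord(
                subject_id=str(row.subject_id),
                field_label=str(row.field_label),
                ga_weeks=float(row.ga_weeks),
                mean_t2star_ms=float(row.mean_t2star_ms),
                **kwargs,
            )
        )
    return records


def write_cohort_csv(records: Iterable[CohortRecord], path) -> Path:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "field_label": r.field_label,
                "ga_weeks": r.ga_weeks,
                "mean_t2star_ms": r.mean_t2star_ms,
                "bmi": r.bmi,
                "maternal_age": r.maternal_age,
                "placental_location": r.placental_location,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def write_metrics_csv(metrics: PlacentalMetrics, path, subject_id: str = "subject") -> Path:
    row = {"subject_id": subject_id, **metrics.as_dict()}
    pd.DataFrame([row]).to_csv(path, index=False)
    return Path(path)
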