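"""Synthetic multi-echo phantoms and simulated cohorts with known truth.

The generator emulates the geometry and contrast of a coronal multi-echo
gradient-echo EPI stack of the gravid uterus at desk scale: a
placenta-shaped compartment (a slab or a half-ellipsoid cap) whose T2*
equals the built-in normative mean for the requested field strength and
gestational age plus a spatially correlated heterogeneity field, a thin
uterine-wall rind with shorter T2*, and surrounding amniotic fluid with
long T2*. Per echo, the signal is S0 * exp(-TE/T2*) with the field's
printed echo train; optional Gaussian or Rician magnitude noise is scaled
so that SNR is defined at the first echo inside the placenta.

Everything is deterministic for a given seed: a single
:class:`numpy.random.SeedSequence` is split into independent child streams
for the heterogeneity field and the noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .core import (
    FIELD_VOXEL_MM,
    CohortRecord,
    EchoTrain,
    MultiEchoVolume,
    PlacentaMask,
)
from .metrics import PlacentalMetrics, compute_all
from .normative import builtin_reference
from .relaxometry import T2StarMap

__all__ = ["PhantomSpec", "PhantomOutput", "make_phantom", "simulate_cohort"]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic scan.

    Defaults give a 0.55T, 30-week slab placenta of 20 mm constructed
    thickness on a 40x40x24 grid at the field's nominal voxel size.
    Heterogeneity is a Gaussian-blurred white-noise field with correlation
    length ``hetero_corr_mm`` and amplitude ``hetero_amplitude_ms``; when
    the amplitude is None it defaults to 10% of the normative mean scaled
    by GA/30, mimicking the increase of parenchymal heterogeneity with
    gestation. Compartment T2* defaults: amniotic fluid 300 ms scaled by
    the field's normative level relative to 3T; uterine wall at half the
    placental mean. These defaults are illustrative contrast choices, not
    literature-calibrated tissue values.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 24)
    voxel_dims_mm: tuple[float, float, float] | None = None
    field_label: str = "0.55T"
    ga_weeks: float = 30.0
    geometry: str = "slab"  # "slab" | "ellipsoid_cap"
    slab_thickness_mm: float = 20.0
    slab_margin_voxels: int = 3
    cap_semiaxes_mm: tuple[float, float, float] = (42.0, 42.0, 16.0)
    hetero_amplitude_ms: float | None = None
    hetero_corr_mm: float = 12.0
    fluid_t2star_ms: float | None = None
    wall_t2star_ms: float | None = None
    wall_thickness_voxels: int = 2
    s0_placenta: float = 1000.0
    s0_wall: float = 800.0
    s0_fluid: float = 1400.0
    noise: str = "none"  # "none" | "gaussian" | "rician"
    snr: float = 50.0
    seed: int = 0

    def resolved_voxel_dims(self) -> tuple[float, float, float]:
        if self.voxel_dims_mm is not None:
            return tuple(float(d) for d in self.voxel_dims_mm)
        iso = FIELD_VOXEL_MM.get(self.field_label, 2.5)
        return (iso, iso, iso)

    def validate(self) -> None:
        if self.geometry not in ("slab", "ellipsoid_cap"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.noise not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise != "none" and self.snr <= 0:
            raise ValueError("SNR must be positive when noise is enabled")


@dataclass
class PhantomOutput:
    volume: MultiEchoVolume
    mask: PlacentaMask
    true_t2star: np.ndarray
    true_metrics: PlacentalMetrics
    noise_sigma: float


def _placenta_geometry(spec: PhantomSpec, dims: tuple[float, float, float]) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = dims
    mask = np.zeros(spec.grid_shape, dtype=bool)
    if spec.geometry == "slab":
        n_thick = int(round(spec.slab_thickness_mm / dz))
        if n_thick < 1 or n_thick > nz - 2:
            raise ValueError(
                f"slab of {spec.slab_thickness_mm} mm ({n_thick} voxels) "
                f"does not fit the {nz}-voxel z extent"
            )
        m = spec.slab_margin_voxels
        if 2 * m >= min(nx, ny):
            raise ValueError("slab margin leaves no lateral extent")
        z0 = (nz - n_thick) // 2
        mask[m : nx - m, m : ny - m, z0 : z0 + n_thick] = True
    else:  # ellipsoid_cap: half-ellipsoid, flat face down
        a, b, c = spec.cap_semiaxes_mm
        cx, cy = (nx - 1) / 2.0 * dx, (ny - 1) / 2.0 * dy
        z_base = nz // 3 * dz
        x = np.arange(nx)[:, None, None] * dx
        y = np.arange(ny)[None, :, None] * dy
        z = np.arange(nz)[None, None, :] * dz
        inside = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + (
            (z - z_base) / c
        ) ** 2 <= 1.0
        mask = inside & (z >= z_base)
        # keep a border of background so distances stay bounded by anatomy
        mask[0], mask[-1] = False, False
        mask[:, 0], mask[:, -1] = False, False
        mask[:, :, 0], mask[:, :, -1] = False, False
        if not mask.any():
            raise ValueError("ellipsoid cap does not intersect the grid")
    return mask


def _heterogeneity(
    shape: tuple[int, int, int],
    dims: tuple[float, float, float],
    amplitude_ms: float,
    corr_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean smoothed white-noise field, rescaled to the requested
    amplitude (SD in ms)."""
    if amplitude_ms == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    sigma_vox = [corr_mm / d for d in dims]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd * amplitude_ms


def make_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate one multi-echo phantom with its ground-truth mask, T2*
    field and metrics."""
    spec.validate()
    dims = spec.resolved_voxel_dims()
    echo_train = EchoTrain.for_field(spec.field_label) if spec.field_label in (
        "0.55T",
        "1.5T",
        "3T",
    ) else None
    if echo_train is None:
        raise ValueError("phantom requires a named field label with a protocol echo train")

    curve = builtin_reference(spec.field_label)
    mu = float(curve.mean(spec.ga_weeks))

    placenta = _placenta_geometry(spec, dims)
    wall = (
        ndimage.binary_dilation(placenta, iterations=spec.wall_thickness_voxels)
        & ~placenta
    )
    fluid = ~placenta & ~wall

    # field-scaled default compartment values
    level = mu / float(builtin_reference("3T").mean(spec.ga_weeks))
    fluid_t2 = spec.fluid_t2star_ms if spec.fluid_t2star_ms is not None else 300.0 * level
    wall_t2 = spec.wall_t2star_ms if spec.wall_t2star_ms is not None else 0.5 * mu
    amp = (
        spec.hetero_amplitude_ms
        if spec.hetero_amplitude_ms is not None
        else 0.10 * mu * spec.ga_weeks / 30.0
    )

    ss = np.random.SeedSequence(spec.seed)
    rng_hetero, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    t2 = np.empty(spec.grid_shape)
    t2[fluid] = fluid_t2
    t2[wall] = wall_t2
    hetero = _heterogeneity(spec.grid_shape, dims, amp, spec.hetero_corr_mm, rng_hetero)
    t2[placenta] = np.clip(mu + hetero[placenta], 5.0, None)

    s0 = np.empty(spec.grid_shape)
    s0[fluid] = spec.s0_fluid
    s0[wall] = spec.s0_wall
    s0[placenta] = spec.s0_placenta

    te = echo_train.as_array()
    signal = s0[..., None] * np.exp(-te[None, None, None, :] / t2[..., None])

    sigma = 0.0
    if spec.noise != "none":
        sigma = float(signal[placenta, 0].mean() / spec.snr)
        if spec.noise == "gaussian":
            signal = np.clip(signal + rng_noise.normal(0.0, sigma, signal.shape), 0.0, None)
        else:  # rician: magnitude of complex signal with Gaussian channel noise
            re = signal + rng_noise.normal(0.0, sigma, signal.shape)
            im = rng_noise.normal(0.0, sigma, signal.shape)
            signal = np.hypot(re, im)

    volume = MultiEchoVolume(data=signal, voxel_dims_mm=dims, echo_train=echo_train)
    mask = PlacentaMask(data=placenta.astype(np.uint8), voxel_dims_mm=dims)

    truth_map = T2StarMap(
        t2star_ms=np.where(placenta, t2, np.nan),
        s0=np.where(placenta, s0, np.nan),
        fit_quality=np.where(placenta, 1.0, np.nan),
        valid=placenta.copy(),
        non_decaying=np.zeros_like(placenta),
        voxel_dims_mm=dims,
        echo_train=echo_train,
    )
    true_metrics = compute_all(truth_map, mask)

    return PhantomOutput(
        volume=volume,
        mask=mask,
        true_t2star=np.where(placenta, t2, np.nan),
        true_metrics=true_metrics,
        noise_sigma=sigma,
    )


def simulate_cohort(
    n: int,
    field_label: str,
    ga_interval: tuple[float, float] = (17.0, 40.0),
    residual_sd_ms: float = 15.0,
    seed: int = 0,
) -> list[CohortRecord]:
    """Draw a healthy cohort from the built-in normative curve.

    GA is uniform on ``ga_interval``; mean T2* is the curve mean plus
    Gaussian noise of SD ``residual_sd_ms``. Non-positive draws (possible
    only at implausibly large SD) are rejected and redrawn, keeping the
    stream deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    lo, hi = ga_interval
    if not (lo < hi):
        raise ValueError(f"invalid GA interval {ga_interval}")
    curve = builtin_reference(field_label)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    for i in range(n):
        ga = float(rng.uniform(lo, hi))
        value = float(curve.mean(ga) + rng.normal(0.0, residual_sd_ms))
        while value <= 0:
            value = float(curve.mean(ga) + rng.normal(0.0, residual_sd_ms))
        records.append(
            CohortRecord(
                subject_id=f"sim-{field_label}-{i:04d}",
                field_label=field_label,
                ga_weeks=ga,
                mean_t2star_ms=value,
            )
        )
    return records
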