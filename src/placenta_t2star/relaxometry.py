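"""Voxelwise mono-exponential T2* estimation.

The signal model for a multi-echo gradient-echo magnitude acquisition is

    S(TE) = S0 * exp(-TE / T2*)

with S0 the extrapolated magnitude at TE = 0 and T2* the effective
transverse relaxation time (ms). Estimation is least-squares over all
echoes. Two strategies are provided:

``"nonlinear"`` (default)
    Nonlinear least squares on the exponential model, initialized from the
    closed-form log-linear regression. Deterministic: fixed initialization,
    no random restarts.
``"loglin"``
    The log-linear estimate alone (ordinary least squares on log S vs TE).
    Faster, biased under noise at late echoes, kept for comparison.

A voxel is *invalid* when any echo magnitude is non-positive (the model is
fit over all echoes or not at all) or when the fitted decay rate is
non-positive (non-decaying signal); such voxels carry NaN in the output
maps and, for non-decaying fits, T2* pinned at the configured cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import EchoTrain, MultiEchoVolume, PlacentaMask

__all__ = ["FitOptions", "T2StarMap", "fit_voxel", "fit_map"]


@dataclass(frozen=True)
class FitOptions:
    """Tuning knobs of the voxelwise fit.

    cap_ms:
        Upper bound on reported T2* (ms). Fluid and noise-only voxels can
        otherwise produce arbitrarily long estimates.
    method:
        ``"nonlinear"`` or ``"loglin"``.
    """

    cap_ms: float = 1000.0
    method: str = "nonlinear"

    def __post_init__(self) -> None:
        if self.cap_ms <= 0:
            raise ValueError("cap_ms must be positive")
        if self.method not in ("nonlinear", "loglin"):
            raise ValueError(f"unknown fit method {self.method!r}")


@dataclass
class T2StarMap:
    """Per-voxel fit results on a 3D grid.

    ``t2star_ms`` and ``s0`` are NaN where no valid fit exists; ``valid``
    marks successful fits and ``non_decaying`` flags voxels whose signal
    did not decay (T2* pinned at the cap, excluded from ``valid``).
    ``fit_quality`` is the coefficient of determination R^2 of the
    exponential model in signal space.
    """

    t2star_ms: np.ndarray
    s0: np.ndarray
    fit_quality: np.ndarray
    valid: np.ndarray
    non_decaying: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    echo_train: EchoTrain

    def valid_values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Valid T2* values, optionally restricted to a boolean mask."""
        sel = self.valid if mask is None else (self.valid & np.asarray(mask, bool))
        return self.t2star_ms[sel]


def _loglin(te: np.ndarray, signal: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS of log(signal) on TE; returns (log_s0, rate)."""
    y = np.log(signal)
    te_c = te - te.mean()
    slope = float(np.dot(te_c, y - y.mean()) / np.dot(te_c, te_c))
    intercept = float(y.mean() - slope * te.mean())
    return intercept, -slope  # rate = 1/T2*


def _r_squared(signal: np.ndarray, model: np.ndarray) -> float:
    ss_res = float(np.sum((signal - model) ** 2))
    ss_tot = float(np.sum((signal - signal.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def _refine(te: np.ndarray, sig: np.ndarray, s0: float, t2: float):
    """Nonlinear least-squares refinement from the log-linear start."""

    def resid(p):
        return p[0] * np.exp(-te / p[1]) - sig

    def jac(p):
        e = np.exp(-te / p[1])
        return np.column_stack([e, p[0] * e * te / p[1] ** 2])

    return least_squares(
        resid, x0=[s0, t2], jac=jac,
        bounds=([0.0, 1e-6], [np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )


def fit_voxel(
    signal: np.ndarray,
    echo_train: EchoTrain,
    options: FitOptions | None = None,
) -> tuple[float, float, float, bool]:
    """Fit S(TE) = S0*exp(-TE/T2*) to one voxel's echo magnitudes.

    Returns ``(s0, t2star_ms, fit_quality, valid)``. Degenerate inputs do
    not raise: any non-positive echo yields an all-NaN invalid voxel, and a
    non-decaying signal yields T2* at the cap with ``valid=False``.
    """
    options = options or FitOptions()
    te = echo_train.as_array()
    sig = np.asarray(signal, dtype=float)
    if sig.shape != te.shape:
        raise ValueError(
            f"signal has {sig.size} echoes but echo train has {te.size}"
        )
    if np.any(sig <= 0) or not np.all(np.isfinite(sig)):
        return float("nan"), float("nan"), float("nan"), False

    log_s0, rate = _loglin(te, sig)
    if rate <= 0:
        # Non-decaying: report the cap, flagged invalid.
        return float(np.exp(log_s0)), float(options.cap_ms), 0.0, False

    t2 = 1.0 / rate
    s0 = float(np.exp(log_s0))
    if options.method == "nonlinear":
        res = _refine(te, sig, s0, min(t2, options.cap_ms))
        s0, t2 = float(res.x[0]), float(res.x[1])
    t2 = min(t2, options.cap_ms)
    model = s0 * np.exp(-te / t2)
    return s0, t2, _r_squared(sig, model), True


def fit_map(
    volume: MultiEchoVolume,
    mask: PlacentaMask | None = None,
    options: FitOptions | None = None,
) -> T2StarMap:
    """Apply :func:`fit_voxel` over a volume, optionally inside a mask.

    Voxels outside the mask (when given) carry NaN and are neither valid
    nor flagged. The result is deterministic for identical inputs.
    """
    options = options or FitOptions()
    shape = volume.grid_shape
    if mask is not None and mask.data.shape != shape:
        raise ValueError(
            f"mask shape {mask.data.shape} does not match volume grid {shape}"
        )
    sel = np.ones(shape, dtype=bool) if mask is None else mask.data

    t2star = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    quality = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    flagged = np.zeros(shape, dtype=bool)

    te = volume.echo_train.as_array()
    signals = volume.data[sel]  # (n_voxels, n_echoes)

    # Vectorized log-linear pass gives every starting point at once; the
    # nonlinear refinement then runs only on fittable voxels.
    fittable = np.all(signals > 0, axis=1) & np.all(np.isfinite(signals), axis=1)
    idx = np.flatnonzero(sel.ravel())
    out_t2 = np.full(signals.shape[0], np.nan)
    out_s0 = np.full(signals.shape[0], np.nan)
    out_q = np.full(signals.shape[0], np.nan)
    out_valid = np.zeros(signals.shape[0], dtype=bool)
    out_flag = np.zeros(signals.shape[0], dtype=bool)

    if np.any(fittable):
        logs = np.log(signals[fittable])
        te_c = te - te.mean()
        slopes = (logs - logs.mean(axis=1, keepdims=True)) @ te_c / np.dot(te_c, te_c)
        rates = -slopes
        log_s0s = logs.mean(axis=1) - slopes * te.mean()

        sub_t2 = np.empty(rates.size)
        sub_s0 = np.exp(log_s0s)
        sub_q = np.zeros(rates.size)
        sub_valid = rates > 0
        sub_flag = ~sub_valid

        decaying = np.flatnonzero(sub_valid)
        sub_t2[sub_flag] = options.cap_ms
        sigs_f = signals[fittable]
        for j in decaying:
            t2_j = 1.0 / rates[j]
            s0_j = sub_s0[j]
            if options.method == "nonlinear":
                res = _refine(te, sigs_f[j], s0_j, min(t2_j, options.cap_ms))
                s0_j, t2_j = float(res.x[0]), float(res.x[1])
            t2_j = min(t2_j, options.cap_ms)
            sub_t2[j] = t2_j
            sub_s0[j] = s0_j
            sub_q[j] = _r_squared(sigs_f[j], s0_j * np.exp(-te / t2_j))

        out_t2[fittable] = sub_t2
        out_s0[fittable] = sub_s0
        out_q[fittable] = sub_q
        out_valid[fittable] = sub_valid
        out_flag[fittable] = sub_flag

    t2star.ravel()[idx] = out_t2
    s0.ravel()[idx] = out_s0
    quality.ravel()[idx] = out_q
    valid.ravel()[idx] = out_valid
    flagged.ravel()[idx] = out_flag

    return T2StarMap(
        t2star_ms=t2star,
        s0=s0,
        fit_quality=quality,
        valid=valid,
        non_decaying=flagged,
        voxel_dims_mm=volume.voxel_dims_mm,
        echo_train=volume.echo_train,
    )
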