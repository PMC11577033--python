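"""Gestational-age normative curves for mean placental T2* and z-scores.

Mean placental T2* declines with gestational age (GA) at every field
strength, and its absolute value is strongly field dependent. A normative
curve per field strength, mu(GA) with spread sigma(GA), turns an observed
mean T2* into a field-independent z-score

    z = (observed - mu(GA)) / sigma(GA)

so that cohorts scanned at 0.55T, 1.5T and 3T become directly comparable.

Two routes produce a :class:`NormativeCurve`:

:func:`fit_normative`
    Least-squares polynomial fit (default quadratic) to a cohort table,
    with either a constant residual-SD spread or a GA-linear spread.
:func:`builtin_reference`
    The built-in reference: the exact quadratic through the three
    published anchor means at 20, 30 and 40 weeks per field, with sigma
    taken from the published 95%-interval half-widths (divided by 1.96)
    and linearly interpolated in GA between the anchors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CohortRecord

__all__ = [
    "TABLE_ANCHORS",
    "NormativeCurve",
    "ZScoreResult",
    "fit_normative",
    "builtin_reference",
    "zscore",
    "ga_correlation",
]

#: Published normative anchors per field: GA (weeks) -> (mean, lo, hi) in
#: ms, where [lo, hi] is the printed 95% interval of the predicted mean.
TABLE_ANCHORS: dict[str, dict[float, tuple[float, float, float]]] = {
    "0.55T": {20.0: (245.0, 238.0, 252.0), 30.0: (200.0, 196.0, 204.0), 40.0: (152.0, 146.0, 159.0)},
    "1.5T": {20.0: (160.0, 148.0, 171.0), 30.0: (110.0, 105.0, 116.0), 40.0: (70.0, 57.0, 82.0)},
    "3T": {20.0: (98.0, 92.0, 101.0), 30.0: (60.0, 58.0, 62.0), 40.0: (25.0, 21.0, 29.0)},
}


@dataclass
class SigmaModel:
    """Spread model sigma(GA).

    kind:
        ``"const"`` — params = [sigma];
        ``"linear"`` — params = [intercept, slope] (ms vs weeks);
        ``"interp"`` — piecewise-linear through (knots_ga, knots_sigma).
    """

    kind: str
    params: list[float] = field(default_factory=list)
    knots_ga: list[float] = field(default_factory=list)
    knots_sigma: list[float] = field(default_factory=list)

    def __call__(self, ga_weeks: float | np.ndarray) -> np.ndarray:
        ga = np.asarray(ga_weeks, dtype=float)
        if self.kind == "const":
            out = np.full_like(ga, self.params[0])
        elif self.kind == "linear":
            out = self.params[0] + self.params[1] * ga
        elif self.kind == "interp":
            out = np.interp(ga, self.knots_ga, self.knots_sigma)
        else:
            raise ValueError(f"unknown sigma model {self.kind!r}")
        return out


@dataclass
class NormativeCurve:
    """mu(GA) polynomial plus sigma(GA) spread for one field strength.

    ``mean_coeffs`` are ascending-power polynomial coefficients of GA in
    weeks (numpy.polynomial convention).
    """

    field_label: str
    mean_coeffs: list[float]
    sigma_model: SigmaModel
    ga_range_weeks: tuple[float, float]
    n_fitted: int
    provenance: str = ""

    def mean(self, ga_weeks: float | np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(
            np.asarray(ga_weeks, dtype=float), self.mean_coeffs
        )

    def sigma(self, ga_weeks: float | np.ndarray) -> np.ndarray:
        return self.sigma_model(ga_weeks)

    def in_range(self, ga_weeks: float) -> bool:
        lo, hi = self.ga_range_weeks
        return lo <= ga_weeks <= hi

    def to_json(self, path=None) -> str:
        payload = {
            "field_label": self.field_label,
            "mean_coeffs": list(map(float, self.mean_coeffs)),
            "sigma_model": {
                "kind": self.sigma_model.kind,
                "params": list(map(float, self.sigma_model.params)),
                "knots_ga": list(map(float, self.sigma_model.knots_ga)),
                "knots_sigma": list(map(float, self.sigma_model.knots_sigma)),
            },
            "ga_range_weeks": list(self.ga_range_weeks),
            "n_fitted": self.n_fitted,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "NormativeCurve":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        sm = payload["sigma_model"]
        return cls(
            field_label=payload["field_label"],
            mean_coeffs=payload["mean_coeffs"],
            sigma_model=SigmaModel(
                kind=sm["kind"],
                params=sm["params"],
                knots_ga=sm["knots_ga"],
                knots_sigma=sm["knots_sigma"],
            ),
            ga_range_weeks=tuple(payload["ga_range_weeks"]),
            n_fitted=payload["n_fitted"],
            provenance=payload.get("provenance", ""),
        )


@dataclass
class ZScoreResult:
    z: float
    predicted_mean_ms: float
    predicted_sd_ms: float
    within_range: bool


def fit_normative(
    cohort: list[CohortRecord],
    field_label: str,
    degree: int = 2,
    sigma_mode: str = "const",
) -> NormativeCurve:
    """Fit mu(GA) by least-squares polynomial and sigma from residuals.

    ``sigma_mode="const"`` uses the residual SD (ddof = number of mean
    parameters); ``"linear"`` regresses |residual| on GA and rescales by
    sqrt(pi/2), the Gaussian mean-absolute-deviation factor.
    """
    recs = [r for r in cohort if r.field_label == field_label]
    if len(recs) != len(cohort):
        raise ValueError("cohort contains records from a different field")
    n_params = degree + 1
    if len(recs) < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} records for degree {degree}; got {len(recs)}"
        )
    ga = np.array([r.ga_weeks for r in recs])
    y = np.array([r.mean_t2star_ms for r in recs])
    if ga.max() - ga.min() <= 5.0:
        raise ValueError("GA spread must exceed 5 weeks for a stable fit")

    coeffs = np.polynomial.polynomial.polyfit(ga, y, degree)
    resid = y - np.polynomial.polynomial.polyval(ga, coeffs)

    if sigma_mode == "const":
        sd = float(np.sqrt(np.sum(resid**2) / max(1, len(recs) - n_params)))
        sigma = SigmaModel(kind="const", params=[sd])
    elif sigma_mode == "linear":
        b, a = np.polyfit(ga, np.abs(resid), 1)  # slope, intercept
        scale = float(np.sqrt(np.pi / 2.0))
        sigma = SigmaModel(kind="linear", params=[a * scale, b * scale])
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")

    return NormativeCurve(
        field_label=field_label,
        mean_coeffs=[float(c) for c in coeffs],
        sigma_model=sigma,
        ga_range_weeks=(float(ga.min()), float(ga.max())),
        n_fitted=len(recs),
        provenance=f"fit_normative(degree={degree}, sigma_mode={sigma_mode})",
    )


def builtin_reference(field_label: str) -> NormativeCurve:
    """The built-in reference curve for ``0.55T``, ``1.5T`` or ``3T``.

    mu is the unique quadratic through the field's three anchor means at
    20/30/40 weeks (an interpolant, so the anchors are reproduced
    exactly); sigma interpolates the anchor 95%-half-widths / 1.96.
    """
    if field_label not in TABLE_ANCHORS:
        raise ValueError(
            f"no built-in reference for {field_label!r}; "
            f"known fields: {sorted(TABLE_ANCHORS)}"
        )
    anchors = TABLE_ANCHORS[field_label]
    ga = np.array(sorted(anchors))
    means = np.array([anchors[g][0] for g in ga])
    halfwidths = np.array([(anchors[g][2] - anchors[g][1]) / 2.0 for g in ga])
    coeffs = np.polynomial.polynomial.polyfit(ga, means, 2)
    sigma = SigmaModel(
        kind="interp",
        knots_ga=list(map(float, ga)),
        knots_sigma=list(map(float, halfwidths / 1.96)),
    )
    return NormativeCurve(
        field_label=field_label,
        mean_coeffs=[float(c) for c in coeffs],
        sigma_model=sigma,
        ga_range_weeks=(float(ga.min()), float(ga.max())),
        n_fitted=3,
        provenance="builtin_reference: quadratic through published anchors",
    )


def zscore(
    curve: NormativeCurve, ga_weeks: float, observed_mean_t2star_ms: float
) -> ZScoreResult:
    """z = (observed - mu(GA)) / sigma(GA).

    Outside the curve's GA range the score is still computed but flagged
    as extrapolation via ``within_range=False``.
    """
    if observed_mean_t2star_ms <= 0:
        raise ValueError("observed mean T2* must be positive")
    mu = float(curve.mean(ga_weeks))
    sd = float(curve.sigma(ga_weeks))
    return ZScoreResult(
        z=(observed_mean_t2star_ms - mu) / sd,
        predicted_mean_ms=mu,
        predicted_sd_ms=sd,
        within_range=curve.in_range(ga_weeks),
    )


def ga_correlation(
    cohort: list[CohortRecord], metric_name: str = "mean_t2star_ms"
) -> tuple[float, float]:
    """Spearman rank correlation of a cohort metric against GA at scan."""
    if len(cohort) < 10:
        raise ValueError(f"need at least 10 records; got {len(cohort)}")
    ga = [r.ga_weeks for r in cohort]
    vals = [getattr(r, metric_name) for r in cohort]
    rho, p = stats.spearmanr(ga, vals)
    return float(rho), float(p)
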