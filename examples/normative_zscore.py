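"""Normative curves and field-independent z-scores.

Evaluates the built-in per-field normative curves of mean placental T2*
against gestational age, then z-scores one observation against its
field's curve.
"""

from placenta_t2star import builtin_reference, zscore

print("predicted normal mean T2* (ms):")
print(f"{'GA (wk)':<8}" + "".join(f"{f:>10}" for f in ("0.55T", "1.5T", "3T")))
for ga in (20, 25, 30, 35, 40):
    row = [float(builtin_reference(f).mean(ga)) for f in ("0.55T", "1.5T", "3T")]
    print(f"{ga:<8}" + "".join(f"{v:>10.1f}" for v in row))

curve = builtin_reference("0.55T")
result = zscore(curve, ga_weeks=32.0, observed_mean_t2star_ms=170.0)
print(f"\nobserved 170.0 ms at 32 wk on 0.55T:")
print(f"  predicted mean {result.predicted_mean_ms:.1f} ms, "
      f"SD {result.predicted_sd_ms:.2f} ms -> z = {result.z:+.2f}")
# A strongly negative z flags a mean T2* far below the healthy curve — the
# kind of deviation reported in placental dysfunction. Note the built-in
# SD interprets the published brackets as 95% intervals of the predicted
# mean, so it is tight; curves refit to a cohort use the residual SD.
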