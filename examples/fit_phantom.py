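"""Fit a voxelwise T2* map on a synthetic placental phantom.

Builds a noiseless 0.55T slab phantom at 30 weeks, fits the
mono-exponential model in every placental voxel, and compares the fitted
map with the known ground truth.
"""

import numpy as np

from placenta_t2star import PhantomSpec, builtin_reference, fit_map, make_phantom

spec = PhantomSpec(field_label="0.55T", ga_weeks=30.0, noise="none",
                   hetero_amplitude_ms=0.0, seed=1)
out = make_phantom(spec)
t2map = fit_map(out.volume, out.mask)

expected = float(builtin_reference("0.55T").mean(30.0))
fitted = t2map.valid_values(out.mask.data)
print(f"placental voxels fitted : {fitted.size}")
print(f"generating T2*          : {expected:.3f} ms (0.55T normative mean at 30 wk)")
print(f"fitted T2* (mean +- SD) : {fitted.mean():.3f} +- {fitted.std():.2e} ms")
print(f"max relative error      : {np.abs(fitted - expected).max() / expected:.2e}")
# A noiseless phantom is recovered to numerical precision: the fit is exact
# whenever the data truly follow S(TE) = S0*exp(-TE/T2*).
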