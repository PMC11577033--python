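# placenta-t2star

Quantitative placental T2* analysis from multi-echo gradient-echo MRI:
voxelwise mono-exponential relaxometry, a morphometric metric suite, and
gestational-age normative curves that turn a mean placental T2* into a
field-strength-independent z-score. A synthetic phantom and cohort
generator with known ground truth stands in for clinical scans, so every
step of the pipeline is testable end to end.

## Who this is for

Placental T2* shortens across gestation and in placental dysfunction, but
its absolute value depends strongly on scanner field strength (0.55T,
1.5T, 3T), which has blocked pooling of results across sites. This package
is for researchers in fetal/placental MRI who need (a) reproducible T2*
maps and derived placental measures from multi-echo data, and (b) a way to
express a subject's mean T2* on a common scale across field strengths.

## The model

For each voxel, the multi-echo magnitude signal is modelled as a
mono-exponential decay over echo time TE:

    S(TE) = S0 · exp(−TE / T2*)

(S0, T2*) are estimated by least squares over all echoes — nonlinear
refinement from a closed-form log-linear start by default. From the T2*
map and a binary placental mask the suite derives:

- **mean T2*** and histogram **skewness** / excess **kurtosis** of the
  masked voxel values;
- **volume** = voxel count × voxel volume (ml);
- a **morphological map**: per placental voxel, the Euclidean distance
  (mm) to the nearest non-placental voxel;
- **non-uniformity** = mean + SD of the morphological map;
- **maximal thickness** = 2 × max of the morphological map.

Per field strength, a normative curve μ(GA) (quadratic in gestational age,
weeks) with spread σ(GA) gives the z-score of an observation:

    z = (observed − μ(GA)) / σ(GA)

Built-in reference curves interpolate the published normal means at 20,
30 and 40 weeks for 0.55T, 1.5T and 3T exactly, with σ derived from the
published interval half-widths.

## Worked example

```sh
python examples/normative_zscore.py
```

prints the built-in normative table and one z-score:

```
predicted normal mean T2* (ms):
GA (wk)      0.55T      1.5T        3T
20           245.0     160.0      98.0
25           222.9     133.8      78.6
30           200.0     110.0      60.0
35           176.4      88.8      42.1
40           152.0      70.0      25.0

observed 170.0 ms at 32 wk on 0.55T:
  predicted mean 190.6 ms, SD 2.30 ms -> z = -8.99
```

The columns show the field dependence of T2* (longer at low field) and its
decline with gestation; the strongly negative z flags an observation far
below the healthy 0.55T curve at that age. `examples/fit_phantom.py`
(noiseless phantom recovered to machine precision),
`examples/metrics_demo.py` (metric suite vs ground truth at SNR 50) and
`examples/cohort_simulation.py` (cohort simulation, curve refitting,
Spearman trend) walk through the other capabilities.

The same operations are available from the shell:

```sh
placenta-t2star simulate phantom --out-dir ph/
placenta-t2star pipeline --in ph/phantom.nii.gz --mask ph/mask.nii.gz \
    --field 0.55T --ga 30 --out-dir run/
placenta-t2star zscore --builtin 1.5T --ga 40 --value 70
```

Each run writes its outputs (NIfTI map + JSON sidecar, metrics CSV,
z-score JSON) plus a `provenance.json` recording inputs and parameters.

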