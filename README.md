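# smartegg

Geometry of avian egg shapes built on Smart's contour model: contour
generation for the whole model family, Main-Axiom compliance analysis,
closed-form volumes of the resulting solids of revolution, parameter
measurement from digitized egg profiles, and a mean-percentage-error
model comparison workflow — as a Python library with a small CLI.

## The model

Smart's model (SM) describes the half-breadth of an egg as an ellipse
whose minor semi-axis grows linearly along the long axis, driven by a
single shape parameter tan θ (the slope of the tangential line at the
egg's mid-surface). In the measured frame — length *L*, maximum breadth
*B*, and *w*, the axial offset of the maximum-breadth section from
mid-length — every family member shares the canonical form

    y(x) = ( B / (2·√(L² − 4w²)) + tanθ·(x − w)/L ) · √(L² − 4x²),
    −L/2 ≤ x ≤ L/2

with the pointed end at x < 0. Variants differ only in how tan θ is
resolved from measurements:

| variant | measurements | tan θ |
|---------|--------------|-------|
| SM      | L, B, w, tan θ | given directly |
| SM^r    | L, B, w, r, R  | 4(R − r)/(√3·L) |
| SM^B0   | L, B, w, B0    | (BL − B0·√(L²−4w²)) / (2w·√(L²−4w²)) |
| SM^B02  | L, B, w        | SM^B0 with B0 from the Hügelschäffer mid-breadth ratio |
| SM^r2   | L, B, w        | SM^r with r, R from the Hügelschäffer quarter-radii |
| SM^MA   | L, B, w        | 2BLw / (L² − 4w²)^{3/2} (Main-Axiom constraint) |
| SM^U    | L, B, w, r     | B/√(L² − 2wL + 4w²) − 4r/(√3·L) |

Here B0 is the full breadth at mid-length, and r, R are the contour
radii (half-breadths) a quarter length from the pointed and blunt ends.

The **Main Axiom** requires the contour's interior extremum to fall at
the measured breadth section: y(w) = B/2 *and* y′(w) = 0, so the drawn
outline preserves the overall dimensions measured on the egg. Only
SM^MA satisfies it for every parameter set; for SM^r compliance forces

    r = R − √3·L²·B·w / (2·(L² − 4w²)^{3/2})

which, with the Hügelschäffer blunt-end ratio for R/B, confines the
Axiom-compatible pointed quarter-radius to r/B ∈ [0.27, 0.43] over the
empirical band w/L ∈ [0, 0.2].

Rotating the contour about the long axis gives closed-form volumes in
the (L, B0, tan θ) frame, e.g. V = (πL/6)(B0² + L²tan²θ/5), and shows
an ovoid always holds more volume than the equal-length ellipsoid — the
ellipsoid of equal volume is longer by the factor 1 + (L/B0)²tan²θ/5.

## Worked example

Fit every variant to a synthetic pyriform (pear-shaped) egg profile —
215 pixel-quantized points, scaled so L = 215 px = 57 mm:

```python
from smartegg import SmartEggModel, standard_fixtures

profile = standard_fixtures()["pyriform"]
res = SmartEggModel(profile).fit()
print(res.summary())
```

```
Smart egg-shape model comparison
======================================================================
profile: 215 points [px], scale 0.265116 mm/px
measured: L = 215 px, B = 138.6 px, w = 34.51 px (w/L = 0.1605)
          B0 = 126 px, r = 45 px, R = 68 px
free LS slope: tan(theta) = 0.233876
----------------------------------------------------------------------
variant  n_params  epsilon_pct  tan_theta  axiom_value_residual  axiom_slope_residual  axiom_compliant  k_used  excluded
  SM_MA         3      3.31619   0.243525                     0          -5.55112e-17             True     213         2
   SM_U         4      3.35767   0.245409                     0            0.00178427            False     213         2
   SM_r         5       3.3947   0.247052                     0            0.00334069            False     213         2
 SM_B02         3      3.84728   0.208258                     0            -0.0334009            False     213         2
  SM_r2         3      5.54954   0.188706                     0            -0.0519182            False     213         2
  SM_B0         4      5.97459   0.294212                     0             0.0480045            False     213         2
```

`epsilon_pct` is the mean percentage error between profile and model
half-breadths at the profile's own axial positions (tips excluded:
`excluded`); the Axiom residuals report y(w) − B/2 and y′(w). Every
variant passes through (w, B/2) by construction, so the value residual
is always zero and compliance is decided by the slope residual — here
only the Axiom-constrained SM^MA is compliant, while the slope rules of
the other variants put the drawn maximum off the measured section.

Volumes, from the CLI:

```sh
$ smartegg volume --L 57 --B0 40 --tan-theta 0.12 --json
{"V_p": 20953.6..., "V_b": 27077.8..., "V": 48031.5..., "V_el": 48031.5...,
 "L_el": 57.333..., "length_conserved": false, ...}
```

Other subcommands: `generate` (model contours), `measure`, `evaluate`,
`axiom` (residuals or the required-r/B curve), `atlas` (normalized
theoretical profiles and boundary-ratio tables), `synth` (fixtures).
Contour files are two-column `x,y` text with `# key=value` headers (see
`smartegg.io`).

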