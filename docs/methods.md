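# Methods

## Model family and conventions

All variants are evaluated through one canonical contour,
y(x) = (P + Q(x − w))·√(L² − 4x²) with P = B/(2√(L² − 4w²)) and
Q = tanθ/L, in the orientation with the pointed end at x < 0 and w ≥ 0.
The intercept P is fixed by the requirement that the contour pass
through the measured breadth section (w, B/2); every variant therefore
has a zero *value* residual against the Main Axiom by construction, and
compliance is carried entirely by the slope residual
y′(w) = tanθ·√(L² − 4w²)/L − 2Bw/(L² − 4w²).

The classical parabola and Hügelschäffer boundary contours are printed
in the opposite orientation (pointed end at x > 0); they are kept in
that native frame, and conversion is an explicit x → −x flip with the
roles of r and R swapped. Profiles carry an orientation flag for the
same reason.

r and R are *radii* — half-breadths of the contour at x = ∓L/4 — not
diameters. This is the only reading under which the r/R slope rule
tanθ = 4(R − r)/(√3 L) is consistent with the boundary-ratio curves
(which all express y/B directly) and with the substitution chain that
eliminates r and R from the five-parameter variant. B0, by contrast, is
a full breadth (B0 = 2y(0)).

A useful identity used throughout: for any canonical contour,
y(L/4) − y(−L/4) = √3·tanθ·L/4 exactly, so a contour's own quarter
radii always resolve back to its own slope parameter.

## Limits and guards

* w/L < 0.5 is enforced strictly (the shared denominator √(L² − 4w²)
  must stay real and nonzero); values above the empirical band
  w/L ≤ 0.2 warn rather than fail, to admit super-elongated eggs.
* The mid-breadth slope rule has w in a denominator. At w = 0 the
  geometry forces B0 = B and the slope limit is 0; B0 ≠ B at w = 0 is
  rejected as an inconsistent configuration rather than divided through.
  The Axiom-required r/B curve's second term is likewise evaluated as
  its limit (0) at w/L = 0, giving the endpoint value √3/4.
* For extreme parameters the linear factor P + Q(x − w) can go negative
  near a tip; the signed value is returned un-clamped, with a separate
  physicality predicate, so diagnostics can surface Axiom-violating
  fits instead of silently masking them.

## Axiom analysis

Compliance tolerances are |y(w) − B/2| ≤ 1e−12·B and |y′(w)| ≤ 1e−9;
no published tolerances exist, so these are engineering choices sitting
well above double-precision noise and well below any physically
meaningful violation. The slope residual uses the analytic derivative;
central finite differences (step 1e−6·L) serve as a cross-check in the
tests only. Contour maxima (for the atlas drift claims) are located by
a 10⁴-point scan refined by bounded scalar minimization — the contour
is smooth with a single interior extremum of interest.

The normalized atlases reproduce the theoretical profile constructions:
dimensionless contours (L = B = 1, w = t) over t ∈ {0, 0.05, …, 0.20},
with the auxiliary measurement supplied by a boundary-shape ratio rule
(parabola bound, Hügelschäffer bound, or their mean). Two facts the
test suite asserts as strict inequalities: under the Hügelschäffer
rules the drawn maximum breadth exceeds B for every t > 0, and its
location drifts from x = w. One nuance: at t = 0 the B0 atlas is the
ellipse under every rule, but the r/R atlas is the ellipse only under
the Hügelschäffer rule — the parabola rule keeps r ≠ R at t = 0 and
hence a nonzero slope. That asymmetry is inherent to the construction,
not an implementation artifact.

## Volumes

Volumes are computed in the (L, B0, tanθ) frame, where the
solid-of-revolution integrals have clean closed forms; callers holding
(L, B, w) convert through B0 = BL/√(L² − 4w²) − 2w·tanθ first. The
length-conservation discrepancy V − V_el = πL³tan²θ/30 is evaluated
from that algebraic form rather than by subtracting the two closed
forms, so tanθ = 0 yields exactly zero. The adaptive-quadrature oracle
(target 1e−12 absolute) lives in the test suite only.

## Measurement

L is the tip-to-tip x span; the mid-length reference is the midpoint of
the two tips. B0, r and R are piecewise-linear interpolations of the
sampled half-breadths — adequate for pixel-grid data, where the
interpolation error is far below the quantization floor.

Locating the maximum-breadth section (B, w) to sub-pixel accuracy is
the delicate step: around its maximum an egg contour is flat to within
one pixel over tens of pixels (curvature ~4·10⁻³ px⁻¹ at chicken-egg
scale), so any local polynomial fit through quantized samples is
noise-dominated. The default refinement instead exploits the family
structure: y/√(L² − 4x²) is *exactly* linear in x for every Smart
variant and nearly linear for any smooth egg-like outline. A linear
least-squares fit of y against (√(L² − 4x²), x·√(L² − 4x²)) — done in y
space, where pixel quantization is homoscedastic — followed by the
closed-form extremum of the fitted contour gives w to a few tenths of a
pixel at 398 points. A windowed quadratic fit and the raw discrete
maximum remain available (`refinement="quadratic"` / `"discrete"`) for
data that defeat the transform, and measurement falls back to the
quadratic automatically if the transform fit degenerates.

Measured w < 0 means the declared orientation was reversed (or the egg
is symmetric to within noise); the measurement is folded (w → |w|,
r ↔ R) with a provenance note rather than failing.

Closed outlines are folded to a half-profile by averaging |y| of the
two branches at the upper branch's x positions, averaging only where
the lower branch actually covers x.

A consequence worth knowing when interpreting fits: the measured w is
the *stationary point* of the observed contour, which is exactly the
quantity the Main-Axiom constraint encodes. On any profile that the
family represents exactly, the Axiom slope rule evaluated at the
measured (L, B, w) therefore recovers the generating tanθ exactly, and
the three-parameter Axiom variant ties the five-parameter variant at
ε ≈ 0. Parsimony rankings between variants are consequently meaningful
only on contours *outside* the family (such as real eggs, or the blend
fixtures below); on family-generated data only the chain-wise facts
hold (dropping a measurement within one derivation chain never improves
the fit).

## Fit metric

ε = (100/k)·Σ|v1 − v2|/|v1| over the profile's own axial positions,
where k counts the included points: samples with |v1| below 1e−9·B
(the tips) are excluded and reported separately, since the relative
error is undefined there. The metric is scale-invariant and zero iff
the model matches the profile at every included point. Comparison is
always on the folded half-profile.

## Synthetic data

The generator emulates pixel-wise digitization of egg photographs:
uniform axial sampling across [−L/2, L/2] including the tips, integer
rounding of the half-breadth (`quantize=True`), and optional additive
Gaussian noise truncated at zero. Noise defaults to σ = 0: digitized
pixel data carry no separate noise source, so quantization stands in
for measurement error. Generation is exactly reproducible per seed.

Out-of-family eggs are built from the pointed-end shape continuum: the
pointed side mixes the parabola and Hügelschäffer bounds linearly
(weight λ), the blunt side is always Hügelschäffer; both bounds pass
through (−w, B/2), so the junction is continuous for every λ. A linear
mix was chosen over other monotone blends because it makes the junction
condition exactly testable.

Standard fixtures (sampling regimes of characteristic egg shapes):

| fixture  | n   | L (px) | B/L  | w/L   | λ    | scale      |
|----------|-----|--------|------|-------|------|------------|
| ovoid    | 398 | 398    | 0.74 | 0.050 | 0.90 | —          |
| conical  | 215 | 215    | 0.70 | 0.088 | 0.50 | 57/215 mm/px |
| pyriform | 215 | 215    | 0.65 | 0.140 | 0.15 | 57/215 mm/px |

The point counts and the 57 mm = 215 px scaling mirror the digitization
regimes of real chicken / common sandpiper / razorbill profiles; the
shape ratios are realistic package choices for each class (chicken eggs
are wide, barely offset and nearly Hügelschäffer-shaped; pyriform eggs
slimmer, strongly offset, near the parabolic bound). They are stand-ins
and are not claimed to match any particular egg. What passing tests on
these fixtures show is that the pipeline measures and ranks contours of
the right sampling structure and shape class correctly; they say
nothing about biological variation, imaging artifacts, or asymmetries
about the long axis, none of which the generator emulates.

Round-trip recovery tests use Axiom-compliant family eggs (r set by the
compliance condition), because only there does the generating w
coincide with the measurable stationary point; recovery is then
quantization-limited (all five parameters within 1% at 398 points, and
regeneration from measured parameters stays under 0.5% ε). The test
suite fixes the seeds; problem sizes throughout (398/215-point
profiles, 100–1000-draw parameter grids, 200 noise replicates) match
the digitization regimes above while keeping the full suite in a few
seconds.

## Known limitations

* Image processing (edge detection, outline tracing) is out of scope;
  inputs begin at digitized points.
* Published per-egg ε values for real eggs cannot be reproduced here —
  the underlying digitized contours are not public; the fixtures test
  the workflow, not those numbers.
* No surface-area formulas and no shell-thickness corrections; measured
  lengths refer to whatever solid the contour describes.
* The structural (B, w) refinement is exact only within the Smart
  family; on strongly out-of-family contours (small blend λ) it carries
  a bias of order a pixel, which the quadratic fallback does not
  improve on.
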