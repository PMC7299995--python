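# Methods

This note documents the models behind `coccomap`, the defaults that
matter, and what the synthetic benchmark does and does not demonstrate.

## Synthetic specimen model

**Geometry.** A placolith is modelled as an elliptical annulus on a
square pixel grid (default 50 nm pixels, background border ≥ 10 % of the
coccolith length). Normalised elliptical radius *e* partitions the
platelet into a central opening (*e* < 0.40), a tube ring
(0.40 ≤ *e* ≤ 0.62, thickness `tube_thickness`, default 3 units), and
shields (0.62 < *e* ≤ 1, `shield_thickness`, default 1 unit). The
central structure — a bar along the major axis for the large 9 µm
template, an oblique bridge for the 5 µm template — spans the opening at
shield thickness when present. Outline irregularity (stressed
morphotypes) multiplies the radius by 1 + a·P(θ), where P is a smooth
random combination of angular modes 2–5 normalised to unit amplitude and
a ∈ [0, 1]; the stressed templates use a = 0.15 (M) and 0.25 (H, which
also loses the central structure and thins both tube and shields).

**Thickness → Ca.** Ca ppm is proportional to thickness with
k_Ca = 9.0 × 10⁴ ppm per unit. This puts the control template's masked
mean near 1.4 × 10⁵ ppm (the control-culture magnitude) while keeping
shields inside the 0.2–1 × 10⁵ ppm "low" Ca band and the tube above
1 × 10⁵ ppm, so transects reproduce the observed band zoning.

**Radial coordinate.** ρ is the Euclidean distance to the *exterior*
background (the zero region connected to the image border — the enclosed
central opening does not count), normalised to 0 at the outline and 1 at
the innermost rim pixel. "Towards the rim" is formalised as decreasing ρ.

**Lattice elements.** ppmᵢ = Ca_ppm · (Aᵢ/A_Ca) · r(ρ)/1000 with
r(ρ) = base · (g + (1 − g)ρ): the i/Ca molar ratio interpolates linearly
from `base` at the innermost pixel to `base · g` at the margin. g = 1
gives a spatially constant ratio (exact to machine precision with noise
off); g > 1 reproduces the rimward Sr/Ca increase.

**Surface elements.** All surface-deposited elements of a specimen share
one organic-coat pattern: Gaussian-smoothed white noise (correlation
length 6 px), standardised, shifted positive, and clipped at zero. The
shared pattern is deliberate — the observation that Fe/Ni/Zn profiles
mimic Cl describes a single coating layer, and the classifier's
r(element, Cl) test would be uninformative against mutually independent
fields. Each element applies its own scale and independent multiplicative
noise. A smooth on-coccolith envelope (0.3 off the specimen, saturating
to 1.0 on its interior) concentrates the coat on the platelet while
leaving it nonzero on the membrane; the envelope saturates quickly so it
does not correlate the coat with thickness.

**Hotspots.** A faint coat baseline plus `n_hotspots` Gaussian blobs
(default radius 1.5–2 px — point-like, as needle-debris contamination
is) centred on random coccolith pixels.

**Absent elements.** A flat field everywhere (possibly zero): present in
the hutch but showing no preference for the coccolith.

**Noise and determinism.** Multiplicative noise is mean-one lognormal
with the stated CV, applied last. All stages draw from
`numpy.random.default_rng([stage_offset, seed])` streams, so identical
configuration + seed is bit-identical at every stage. Each specimen
carries its ground truth (per-element mode, noise-free mean molar ratio
over the default mask, implied D) for recovery tests.

**Spectra.** Expected counts per bin are a flat continuum
(0.01 counts/bin/pixel) plus unit-integral element templates — Gaussians
at library line energies with FWHM(E) = √(60² + 2.47·E_eV) eV and fixed
within-element branching ratios — scaled by k*·sᵢ·ppmᵢ·t_dwell
(k* = 7.5, t_dwell = 0.2 s). Hutch/detector/grid lines (Ar, Kr, Si, Cu)
are added uniformly over all pixels. Lines at or above the 17.1 keV
incident energy are not excitable and are dropped. Observed counts are
Poisson draws; the noiseless expectation is stored alongside. Sensitivities
grow monotonically with Z across the Mg–Sr K-line range ((Z/20)² × 10⁻³
counts per ppm·s per unit k); Kr is modelled with Kα only to avoid an
artificial Kr-Kβ/Sr-Kα degeneracy.

## Fitting and quantification

Per-spectrum fits solve a bounded linear least-squares problem:
element amplitudes ≥ 0, polynomial continuum coefficients free (Legendre
basis, degree 2). Inclusion is decided once per specimen on the
Poisson-weighted (1/√max(y,1)) summed-spectrum fit at amplitude > 3σ,
then applied uniformly — per-pixel inclusion would make maps
incomparable. Per-pixel fits are unweighted; because the design matrix is
shared, the whole cube is solved in one unconstrained pass and only
pixels with a negative element amplitude are re-solved under the bound.
Candidate templates with cosine similarity > 0.9995 raise a collinearity
error naming the pair. As and Pb-L cannot be separated at 17.1 keV; the
As channel is reported as `As*` and flagged.

Calibration refines a single flux-area scale k by log-space least
squares against certified concentrations, weighting elements that span
orders of magnitude evenly; quantified ppm is invariant to the arbitrary
scale of the sensitivity table as long as calibration and quantification
share it.

*Estimator property:* nonnegative per-pixel fitting overestimates
specimen means for trace elements once per-pixel amplitudes fall to
~1 count (clipping bias, ≈ +3 % for a 500 ppm coat element at default
dwell). Specimen-level trace ratios should therefore be read from the
summed-spectrum fit, which is unbiased; the per-pixel trace maps remain
semiquantitative.

## Map analysis defaults

* Calcite mask: Ca ≥ 0.2 × 10⁵ ppm; every statistic is mask-restricted,
  and sub-threshold pixels are excluded from specimen means.
* Specimen mean ratios are means of per-pixel ratios, not ratios of mean
  concentrations; the two differ whenever the ratio varies spatially,
  and published per-specimen mean ppm and mean ratio columns are only
  mutually consistent under the former convention.
* Transects: nearest-pixel sampling at ~1 px steps (no interpolation,
  preserving the per-pixel data model); bands background / low
  (0.2–1 × 10⁵) / high (≥ 1 × 10⁵ ppm); background samples are excluded
  from band statistics. Coordinates are 0-based row-major pixel indices
  with centres at integers.
* Regions: margin = masked pixels within d_margin = 4 px of the outline
  (exterior distance transform); tube = remaining masked pixels with Ca
  at or above the q_tube = 0.80 quantile of the masked Ca distribution
  (quantile ties fall into the tube); external rim = the rest. The
  morphological zones are defined in the source imagery only by
  annotation, so this distance/quantile construction is one admissible
  formalisation; both parameters are configuration. Partitions with any
  region under 30 pixels are rejected, and specimens flagged as tilted
  are refused outright rather than corrected.
* Correlations are Pearson over masked pixels; zero variance yields a
  missing-value sentinel (never 0).

## Partition coefficients

D_x = (x/Ca)_calcite / (x/Ca)_solution, a ratio of molar ratios —
invariant to units and to absolute calcite density, and the only reading
consistent with the published (Sr/Ca, D_Sr) pairs. The shipped default
solution table is reconstructed from those pairs (Sr/Ca 8.81, Se/Ca
0.98 mmol/mol), is clearly marked as such, and should be replaced by the
measured medium composition for real experiments.

## Classification

Decision order for a detected element: no on/off-coccolith enrichment
(on-mask mean ≤ 1.5 × off-mask mean) → absent; top-1 %-pixel mass share
≥ 0.25 → hotspot; r(element, Ca) ≥ 0.6 → lattice; r(element, Ca) < 0.3
with r(element, Cl) ≥ 0.3 (or no Cl map, flagged) → surface; otherwise
the larger correlation decides with a low-confidence flag. θ_lattice =
0.6 sits below the ≈0.7 Se–Ca correlation treated as lattice evidence
and far above coat-field correlations; configuration validation enforces
θ_surface < θ_lattice. Verdicts are invariant to positive rescaling of
the element map.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: the full 50 nm
templates (~40k grid pixels, ~17k on the calcite) for map-level
statistics, 100 nm pixels for the 15-specimen classification benchmark,
and a 3 µm specimen with 20 eV energy bins for spectrum round trips
(Monte-Carlo suites use 20–100 seeds). Larger cubes scale linearly and
hold no new behaviour. Tolerances asserted by the tests were fixed from
simulation before freezing (bounds at 3 Monte-Carlo standard errors;
the coat-independence bound |r| < 0.3 holds at the 50 nm default, where
the ~17k-pixel mask spans enough independent coat patches — sd(r) ≈ 0.1).

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis assumes:
thickness-proportional Ca, ratio-preserving lattice incorporation, a
shared coat, point hotspots, Poisson counting. It does not emulate
secondary fluorescence or matrix absorption, escape/sum peaks or pile-up,
detector tilt, partially tilted specimens, porosity (thinning is the only
stress response knob), or spatially structured membrane background.
Recovery and 100 %-accuracy results on the benchmark therefore validate
the pipeline's machinery, not the difficulty of real beamline data; on
real maps the configurable thresholds are starting points, not findings.
Pb is never quantified separately (L-lines only at this incident energy),
and the `As*` channel is intrinsically ambiguous.
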