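# Methods

## Decomposition model

The package performs image-domain three-material decomposition in the
dual-energy Hounsfield plane. Each voxel is a point (HU₈₀, HU₁₃₅); each
basis material is a direction through the origin with gradient
g = HU₁₃₅/HU₈₀. With gradients sorted g₁ < g₂ < g₃ and voxel quotient
q = HU₁₃₅/HU₈₀, the rule is piecewise:

* q ≤ g₁ — all signal to material 1 (c₁ = HU₈₀);
* g₁ < q < g₂ — exact 2×2 solve c₁ + c₂ = HU₈₀, c₁g₁ + c₂g₂ = HU₁₃₅
  (material 3 zero); analogous for g₂ ≤ q < g₃;
* q ≥ g₃ — all signal to material 3;
* HU₈₀ ≤ τ (background threshold, default 100 HU) — all components zero.

Inside a bracket the solved magnitudes are automatically non-negative and
conserve the voxel's 80-kVp HU; outside, assignment is winner-take-all.
Map values are cᵢ·gᵢ, i.e. the material's contribution at the 135-kVp
scale, clamped at zero — map statistics are conventionally read next to
the 135-kVp conventional images, and the clamp matches the observed
"0, 0–14 HU" fluorine range of fresh bone.

Assumptions: the two volumes are co-registered; exactly three materials
dominate X-ray attenuation in the object; HU mixes linearly in volume
fractions. The decomposition order is purely quotient-bracketing; no
material is pre-subtracted.

### Parameters

| parameter | default | units | note |
|---|---|---|---|
| calcium anchor | (4248, 3000) | HU | calcite crystal measurement |
| iron anchor (fluorine basis) | (10000, 7365) | HU | algorithm parameter; differs from the measured rod (24422, 18311) by an unexplained rescaling — both are kept in their respective roles |
| fluorine gradient | 0.69 | – | fluorite quotient 3753/5432 rounded to 2 decimals |
| soft-tissue gradient (calcium basis) | 1.00 | – | water has 0 HU at both energies; water-like tissue attenuates nearly equally |
| background threshold τ | 100 | HU | below this at 80 kVp a voxel is background |

The calcium basis is this package's stand-in for the clinical
calcium-specific algorithm, whose parameters are proprietary; it uses the
measured calcite/iron anchors plus the soft-tissue direction and
reproduces the qualitative behavior (high calcium signal in
apatite-dominated voxels, zero in water-like ones).

Quotients are computed as HU(135)/HU(80) and rounded half-even only for
display; full precision is kept internally. Two known irregularities of
the reference table are handled explicitly: calcite's printed quotient
(0.707) differs by one ulp from the computed 0.706, and the graphite row
fits only the inverted ratio; graphite is excluded from basis
construction.

`effective_z` implements the Mayneord power-law electron-fraction mean
(default exponent 2.94). It is informational only: the reference table's
Z_eff values are not reproduced by this (or any common) power law.

## Phantom generator

The generator inverts the decomposition's own forward model: each region
has a composition (material → volume fraction, summing to 1), a voxel's
noiseless HU pair is the fraction-weighted sum of the material signatures,
and independent Gaussian noise is added per energy (the two spirals of a
rotate/rotate scanner are acquired separately). Geometries are boxes,
spheres/ellipsoids, axis-aligned cylinders and differences thereof;
regions must be disjoint; uncovered voxels are background. Values are
clipped to the scanner range [−32768, 32767] HU. Beam hardening is
emulated as a surface band: object voxels within a given Euclidean
distance of background are shifted by a fixed HU offset at both energies
and recorded in an artifact mask.

Bone mineral is modelled with the fluorite direction in place of
fluorapatite and calcite in place of hydroxyapatite/carbonate, plus pore
space. Default recipes pin the printed study values at the noiseless
level: fossil theropod bone (fluorite 0.511 / calcite 0.374 / pore 0.115)
gives 3040 HU at 135 kVp and a 1809-HU fluorine map; fresh bovine bone
(calcite 0.553) gives 1658 HU and exactly zero fluorine; the oldest
terrestrial cohort specimen gives ≈3500 HU fluorine. Printed standard
deviations (542 HU fossil, 90 HU fresh) are applied as voxel-level noise
at both energies — a modelling choice, since the study reports ROI-level
variability; specimens without printed SDs use 300 HU. The six-specimen
cohort orders extant → Pleistocene → Late Cretaceous → Late Jurassic
terrestrial plus two fluorine-poor marine specimens, with a calcite-rich
fluorine-free sediment throughout.

What the generator does **not** emulate: reconstruction-kernel texture and
spatially correlated noise, scatter and photon starvation, metal streaks,
partial-volume gradients at interfaces, registration error between the two
energy volumes, and heterogeneous within-region composition. Passing
tests therefore demonstrate correctness of the decomposition and
statistics under the stated noise model, not scanner-grade realism.

## Noise amplification and clamp bias

The fluorine/calcium bracket is narrow: g_Ca − g_F = 3000/4248 − 0.69 ≈
0.0162. The pairwise solve therefore amplifies HU noise by roughly
1/Δg ≈ 62: with SD-90 HU voxel noise per energy the per-voxel fluorine map
has an SD of several thousand HU, and the voxel quotient's SD (≈0.025)
exceeds the bracket width, so most voxels land on the clamps (zero below,
winner-take-all above). Clamping a wide, roughly symmetric distribution at
asymmetric bounds biases the voxelwise map mean: for the default fossil
bone mixture the ROI-mean fluorine under SD-90 noise sits ≈12 % below the
noiseless value (and lower still at the default 542 HU noise). This is an
inherent property of image-domain decomposition with closely spaced
gradients, not an implementation artifact; ROI means of the map remain
usable as *contrasts* (bone vs sediment, across ages) but understate the
noiseless fluorine signal in absolute terms. The corresponding
parameter-recovery acceptance test documents this by failing its 2 %
tolerance at the stated noise level.

## Statistics

* Descriptives: sample (n−1) SD; medians use the midpoint of the central
  pair; the report string mirrors "mean ± SD HU; median, min–max HU".
* The unit of analysis is the ROI mean (ten structure-specific ROIs per
  structure), matching the study design; voxels within an ROI are not
  treated as independent observations.
* One-way ANOVA is classical (equal-variance). Degenerate conventions:
  zero between-group variation → F = 0, p = 1; zero within-group variation
  with separated means → F = ∞, p = 0.
* Post-hoc tests share the ANOVA's pooled MSE (df = N − k): raw pairwise
  p from t = Δmean/√(MSE(1/nᵢ+1/nⱼ)), Bonferroni = min(1, m·p), Tukey HSD
  from the studentized range (scipy). Sharing the statistic makes
  Tukey ≤ Bonferroni a union-bound theorem and reduces to the ordinary
  pooled two-sample t (F = t²) for two groups. This is the convention of
  standard statistical packages' post-hoc menus; fully independent
  two-sample tests would not satisfy the Tukey/Bonferroni ordering.
* ROIs whose artifact-voxel fraction strictly exceeds 5 % (configurable)
  are excluded, mirroring artifact-free ROI placement.
* The age trend is reported as an ordering check (monotone non-decreasing
  terrestrial fluorine with age, violating pairs named) plus pairwise
  post-hoc comparisons — no absolute-age regression is attempted.

## Numerical and design choices

* Grids are 0-based (i, j, k) with spacing in mm; NIfTI (nibabel) and NRRD
  (SimpleITK) round-trip to identical arrays; each energy is its own file
  (`_80kvp`/`_135kvp` suffixes) for interoperability.
* Basis gradients must be separated by ≥ 1e-6 (degenerate otherwise);
  anchors must reproduce their gradients to 1e-12 relative.
* Volume fractions must sum to 1 within 1e-9.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; phantom builds and full pipeline runs are
  bit-reproducible, and reports carry the seed and a config hash.
* Problem sizes used by the test-suite study reproductions: a 64³ demo
  phantom, 40³ cohort phantoms with ten 4³ ROIs per structure, 10⁴-voxel
  decomposition round trips and 2000-replicate null simulations for the
  type-I-error check — small enough to run anywhere, large enough that
  the standard-error-based tolerances are meaningful.

## Known limitations

* The voxel-noise mapping of printed ROI-level SDs overstates scanner
  voxel noise; combined with clamp bias (above) it inflates
  sediment-region fluorine means at high noise. Contrast-level
  conclusions are unaffected in the test suite.
* The calcium basis is a documented substitute, not the vendor algorithm;
  its absolute map values are not comparable to vendor console output.
* Marine low-fluorine configurations sit near the detection floor; their
  bone-vs-sediment contrast is intentionally borderline.
* No projection-domain physics: virtual monoenergetic images, iodine-style
  two-material projections and streak artifacts are out of scope.
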