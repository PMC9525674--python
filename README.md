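# paleodect

Quantitative dual-energy CT (DECT) material decomposition for fossilized
bone: simulate paired 80/135-kVp phantom volumes, calibrate three-material
decomposition bases from mineral measurements, compute per-voxel **calcium**
and **fluorine** maps, and run the ROI statistics (bone vs sediment,
healthy vs diseased, fluorine-vs-age trend) that make fluorine usable as an
imaging indicator of fossilization.

It is aimed at researchers in vertebrate paleontology and quantitative CT
who want a self-contained, testable implementation of Hounsfield-plane
three-material decomposition — no scanner, vendor console or museum dataset
required.

## The model

A material scanned at two tube voltages traces a ray through the origin of
the (HU₈₀, HU₁₃₅) plane with slope

```
g = HU(135 kVp) / HU(80 kVp)
```

(the *quotient* or *gradient*), a density-independent spectral fingerprint.
Measured on a clinical 320-row scanner: calcite 3000/4248 ≈ 0.706, fluorite
3753/5432 ≈ 0.691, iron rod 18311/24422 ≈ 0.750, NaCl ≈ 0.598.

A **three-material basis** is an ordered triple of gradients g₁ < g₂ < g₃.
Given a voxel (HU₈₀, HU₁₃₅) with quotient q = HU₁₃₅/HU₈₀, the adjacent pair
of directions bracketing q splits the signal by the exact 2×2 solve

```
c_a + c_b = HU80,      c_a·g_a + c_b·g_b = HU135,
```

with winner-take-all assignment outside [g₁, g₃] and all-zero components
for background voxels (HU₈₀ ≤ 100). The reported **material map** value is
cᵢ·gᵢ — the material's contribution on the 135-kVp scale — clamped at zero.

Two bases are bundled:

* **fluorine**: calcium anchor (4248, 3000), iron anchor (10000, 7365),
  fluorine gradient 0.69 (the fluorite quotient rounded to two decimals).
  Fresh hydroxyapatite bone sits on or above the calcium direction and maps
  to 0 HU fluorine; fluorapatite-permineralized bone falls between the
  fluorine and calcium directions and maps to large fluorine values.
* **calcium**: calcite and iron-rod anchors plus a soft-tissue direction at
  g = 1.00, standing in for the clinical calcium algorithm.

ROI statistics follow classical parametric practice: descriptives as
"mean ± SD; median, min–max", one-way ANOVA on ROI means with Bonferroni
(pooled-MSE pairwise t) and Tukey HSD post-hoc tests, two-sided α = 0.05.

## Worked example

```bash
paleodect run --out report --seed 7
```

simulates a 64³ fossil-bone-in-sediment phantom (bone: fluorite/calcite
mixture at 3040 HU mean, 542 HU voxel noise per energy; calcite-rich
sediment; a 2-voxel surface band shifted +300 HU emulating beam hardening),
builds both bases, decomposes both maps, places ten cubic ROIs per
structure, drops ROIs with more than 5 % artifact voxels, and writes
`report/report.txt`:

```
paleodect run (seed 7, config 694abaa5f30deea3)

              fluorine | bone       mean of ROI means   1540.8 HU (10 ROIs)
              fluorine | sediment   mean of ROI means    762.5 HU (8 ROIs)
               calcium | bone       mean of ROI means   1838.8 HU (10 ROIs)
               calcium | sediment   mean of ROI means    820.8 HU (8 ROIs)
   conventional_135kvp | bone       mean of ROI means   3068.1 HU (10 ROIs)
   conventional_135kvp | sediment   mean of ROI means   1364.5 HU (8 ROIs)

              fluorine | bone vs sediment: ANOVA p = 4.69e-14, Bonferroni p = 4.69e-14, Tukey p = 4.85e-14
               calcium | bone vs sediment: ANOVA p = 2.48e-14, Bonferroni p = 2.48e-14, Tukey p = 2.63e-14
```

Fluorine separates bone from sediment decisively (p < 10⁻¹³); two sediment
ROIs landed in the beam-hardening band and were excluded. The noisy-map ROI
means sit below the noiseless bone value (1809 HU) because the narrow
fluorine/calcium bracket amplifies voxel noise and the non-negativity clamp
biases the mean — see `docs/methods.md` for the analysis. Alongside the
report the run writes per-ROI summaries and pairwise comparisons as CSV,
basis JSONs, NIfTI volumes of the phantom and maps, red-overlay PNGs, and
`provenance.json` (seed, config hash, versions). Reruns with the same seed
are byte-identical.

The individual stages are also available as `paleodect simulate`
(`examples/fossil_bone_demo.yaml` is a ready-made phantom spec),
`calibrate`, `decompose` and `analyze`, or from Python:

```python
from paleodect import build_fluorine_basis, build_phantom, material_map
from paleodect.phantom import fossil_bone_phantom_spec

vol = build_phantom(fossil_bone_phantom_spec(seed=7))
fmap = material_map(vol, build_fluorine_basis(), "fluorine")
```

A six-specimen synthetic cohort (`paleodect.pipeline.cohort_roi_means`)
emulates the study design — extant bovine bone through Triassic marine
reptiles — and reproduces its qualitative findings: fluorine
bone-vs-sediment contrasts are significant in terrestrial specimens but not
in the fluorine-free marine configuration, and terrestrial bone fluorine
rises monotonically with geological age from ≈0 HU (extant) to ≈3500 HU
(Late Jurassic).

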