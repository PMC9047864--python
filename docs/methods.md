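# Methods

This note documents the models, conventions and design choices behind
`radrepro`, in the spirit of a statistical-software methods appendix. It
describes what the code computes; every number quoted here is produced by
the package itself (tests or `scripts/acceptance.py`), not asserted.

## 1. The study being emulated

The package reproduces the logic of a delineation-reproducibility study:
a cohort of subjects, each with one liver lesion, contoured under three
image-guidance arms — contrast-enhanced 3D-CT (arm prefix `3DCT`),
maximum-intensity-projection 4D-CT (`MIP`) and multi-sequence MR (`MR`) —
by two observers in two sessions each. Arm labels follow
`<prefix><index>` with index 1, 2 = observer 1, sessions 1 and 2, and
index 3, 4 = observer 2, sessions 1 and 2; hence pairs (1,2) and (3,4) are
intra-observer and the other four pairs inter-observer. Each GTV contour is
paired with its 0–5 mm peritumoral ring, giving

    n_subjects × 3 modalities × 2 observers × 2 sessions × 2 tissues

contour records — 456 at the default 19 subjects. Because no patient images
are used anywhere, the cohort is synthetic; its purpose is to carry the
*statistical structure* the screening assumes (between-subject variance,
observer- and session-level contour noise, modality ordering), not CT
realism.

## 2. Phantom model

Each subject's volume is a constant background (default 40 HU-like units)
with an ellipsoidal lesion (default mean 90) plus a stationary Gaussian
random texture: white noise smoothed with a Gaussian kernel of
`texture_correlation_length_mm` (default 4 mm), rescaled to SD
`noise_sd` (default 12). Across subjects the lesion semi-axes are scaled by
Uniform(0.75, 1.15) per axis and the lesion mean jittered by N(0, 6), so
features genuinely vary between subjects — without between-subject
variance the ICC would be meaningless.

Defaults: grid 64×64×48 voxels at 0.97×0.97×3.0 mm (the in-plane/slice
spacing of the emulated CT protocol), lesion semi-axes (15, 13, 12) mm.
The grid size is the package's own choice: large enough to hold the lesion,
its 5 mm ring and the contour perturbations with margin, small enough that
a full 456-record extraction runs in about a minute.

What the phantom does *not* emulate: scanner physics (beam hardening,
partial volume, respiratory-phase artefacts), anatomy around the lesion
(vessels, liver boundary), registration error between modalities, and
non-ellipsoidal lesion shape. Passing tests therefore demonstrate the
*pipeline's* correctness and the qualitative response of feature
reliability to contour noise — they do not certify feature reliability
magnitudes on real patient data.

## 3. Delineation-variability model

A contour is simulated by displacing the true lesion surface along its
outward normal by a smooth random field:

    delineation = { x : sdf(x) ≤ d(x) },
    d(x) = σ_inter · g_obs(x) + σ_intra · g_ses(x) + bias

where `sdf` is the spacing-aware signed Euclidean distance of the true mask
(positive outside), `g_obs` is a unit-SD Gaussian random field drawn once
per observer (shared by that observer's sessions) and `g_ses` one drawn per
session. Fields are white noise smoothed at `correlation_length_mm`
(default 10 mm) — band-limited, spatially coherent deviations rather than
voxel-level salt-and-pepper, which is how real contour disagreement looks.
The result keeps its largest 26-connected component; a perturbation that
empties the mask raises an error advising smaller σ.

Default magnitudes (mm), chosen to encode the guidance-contrast ordering
MR < CECT < MIP and intra < inter:

| modality | σ_intra | σ_inter |
|----------|---------|---------|
| MR       | 0.5     | 1.0     |
| CECT     | 1.0     | 2.0     |
| MIP      | 1.5     | 3.0     |

All are config-overridable. Seeds derive from the master seed through
`numpy` `SeedSequence` spawn keys of (subject, modality, observer, session),
so every record has an independent, reproducible stream and the whole
cohort regenerates bit-identically.

## 4. Peritumoral ring

The ring is the set of voxels whose spacing-weighted Euclidean
centre-to-centre distance to the GTV is in (0, r] with r = 5 mm by default,
computed by distance transform — so on the 3 mm slice axis a 2.9 mm radius
recruits no out-of-plane voxels, which is the intended "radius in mm"
semantics on anisotropic grids. The ring is built from each *delineated*
GTV (not the ground truth), so contour noise propagates to the peritumoral
tissue exactly as it would in the emulated study. The ring is not clipped
by any body/organ mask by default (an optional clip mask exists), since the
emulated protocol does not state such clipping.

## 5. Feature bank

107 features in 7 classes (18 first-order, 14 shape, 24 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM, 5 NGTDM), following the open radiomics reference
definitions, on the original image only (no filtered-image features, no
resampling, no per-slice mode).

Conventions that matter:

* **Discretization** — fixed bin width `w` (default 25), level
  `⌊x/w⌋ − ⌊min_ROI/w⌋ + 1`; the min-anchoring makes texture features
  invariant to intensity shifts by whole bins (property-tested).
* **Texture neighbourhoods** — voxel-unit offsets: 13 unique directions at
  Chebyshev distance 1 for GLCM/GLRLM (features averaged with equal weight
  over directions that contain at least one pair/run), 26-connectivity for
  GLSZM zones and the GLDM/NGTDM neighbourhoods. GLDM dependence threshold
  α = 0 and distance 1 (the reference implementation's defaults, since the
  emulated protocol states none).
* **Degenerate denominators** — entropy-like and correlation-like
  quantities return 0 (with a warning) when their denominator vanishes
  (single gray level, single voxel); NGTDM coarseness is capped at 10⁶.
  Tables never carry NaN.
* **Shape** — the surface mesh is the zero isosurface of the lightly
  smoothed (σ = 0.5 voxel) signed distance of the mask, marching-cubes
  triangulated in physical mm. Meshing the raw binary mask instead produces
  staircase facets that overestimate surface area by ~9 % even for large
  spheres (driving sphericity of a ball to ~0.92 instead of ~0.96); the
  smoothed signed distance restores sub-voxel surface placement while a
  0.5-voxel kernel still preserves one-voxel-thin structures such as ring
  caps on the 3 mm axis (binary fallback if the zero crossing ever
  vanishes). Axis lengths are 4·√λ from the PCA of foreground voxel-centre
  coordinates (population covariance); maximum 2D diameters are the largest
  in-plane pairwise boundary-voxel distances per plane, with axis 2 as the
  slice axis.

The whole 107-vector is verified in the test suite against an independent
brute-force reference implementation (naive per-voxel loops, literal
formulas, no shared code) on random phantoms, and against hand-enumerated
examples per class.

## 6. Reliability statistics

* **QCD** = (Q3 − Q1)/(Q3 + Q1) × 100 across subjects within one arm,
  quartiles by linear interpolation between order statistics. Undefined
  (and never "small") when Q1 + Q3 ≤ 0, which signed features such as
  skewness can produce. Classes: < 10 small, 10–20 intermediate, ≥ 20
  large; a config switch makes 10 inclusive.
* **ICC** — two-way random-effects, single-rater, absolute-agreement,
  computed from the two-way ANOVA mean squares; classes poor (< 0.4), fair
  (0.4–0.59), good (0.6–0.74), excellent (≥ 0.75). A constant rating
  matrix yields an explicit "undefined" marker, not NaN. The implementation
  is cross-checked against a brute-force sums-of-squares oracle and against
  `pingouin`'s ICC2 in tests.
* **Robust selection** — a feature is robust when ICC ≥ 0.75 in *all* six
  MR arm pairs and QCD < 10 in *all* four MR arms, in both tumor and
  peritumor ("all" semantics; an "any" alternative is config-selectable).
  The MR group is the default reference because it is the least-perturbed
  arm; this too is configurable.

## 7. Comparison and PCA

Robust features are compared between tumor and peritumor values of one arm
(default `MR1`): one-way ANOVA when both groups pass Shapiro–Wilk at
α = 0.05, Kruskal–Wallis otherwise; significance at p < 0.05; no
multiple-testing correction by default (a Benjamini–Hochberg option is
off by default). Two identical constant groups report p = 1 and a
"degenerate" flag.

PCA acts per tissue on the subjects × features matrix of the features with
ICC ≥ 0.75 across all MR pairs, values from the default arm, z-scored
column-wise (correlation-matrix PCA — feature scales differ by orders of
magnitude); zero-variance columns are dropped with a warning. Reported:
eigenvalues, variance proportions, cumulative proportions, scores, and the
smallest component count reaching 90 % cumulative variance.

## 8. Problem sizes and determinism

Defaults everywhere are the full study scale: 19 subjects, 456 records,
107 features. The test suite exercises the full scale in its study-level
checks (cohort cardinality; modality/observer ordering of ICC-excellent
counts over 3 master seeds) and reduced designs (3–6 subjects, 32³-scale
grids) in per-module tests. `scripts/acceptance.py` always runs the full
default scale. Every random quantity descends from a single master seed;
pipeline runs write a manifest with SHA-256 hashes of all artifacts, and
re-running a config reproduces identical hashes.

## 9. Known limitations

* Phantom realism is deliberately minimal (Section 2); absolute feature
  values and reliability counts are not transferable to patient data.
* The observer model has no systematic inter-observer bias by default
  (`bias_mm = 0`); bias is supported but unexercised by the default study.
* ICC confidence intervals and Bland–Altman analyses are out of scope.
* 2D (per-slice) feature extraction and filtered-image (wavelet/LoG)
  features are not implemented.
* With k = 2 raters the rater variance component rests on a single
  contrast, so individual ICC estimates scatter around the
  variance-component truth; tests therefore judge recovery on replicate
  means.
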