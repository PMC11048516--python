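# Methods

This note documents the models, numerical conventions and design choices
behind `octacrmb`, in the spirit of a statistical-software methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scan model and regions

An en-face angiogram is a square grayscale raster covering a known
physical extent (default 3 × 3 mm, 304 × 304 px — the common export size
for macular scans — giving 9.87 µm/px; any square size is accepted). The
digital vasculature map (DVM) is min–max normalized to [0, 1] at load.
The fovea center defaults to the geometric image center (devices center
the scan on the fovea) and can be overridden. Coordinates are 0-based
(row, col); physical distances are measured between pixel centers.

ETDRS regions: fovea = Euclidean distance < 0.5 mm from the center;
parafovea = [0.5, 1.5) mm. Quadrant subdivision is not computed — no
downstream metric uses it. Perfusion densities are reported over the
parafovea; fractal dimensions over the full scan; FAZ metrics are
center-anchored by construction.

## Binarization

Default `local_mean`: the image is lightly denoised (Gaussian, σ = 0.5 px),
then a pixel is vessel when it exceeds the mean of a 0.2-mm window by an
offset equal to 5% of the image intensity range; connected components
under 15 px are removed as speckle. Two points deserve note:

* the offset is **added** to the local mean. For bright vessels on a dark
  background a threshold below the local mean would admit every uniform
  background region, where pixel ≈ local mean ± noise.
* expressing the offset as a fraction of the intensity range makes the
  whole chain exactly invariant to affine intensity rescaling (a property
  the test suite checks), so device-dependent display scaling does not
  change the mask.

`global_otsu` (no smoothing, no speckle removal) is the config-exposed
alternative. Empty and full masks raise a diagnostic error. On the default
synthetic conditions (noise σ = 0.05) local-mean segmentation scores
Dice ≈ 0.98 against generator truth; the tested floor is 0.90.

## Large-vessel / capillary separation

Seeds are vessel pixels whose local diameter is ≥ 25 µm (the conventional
capillary/arteriole caliber boundary) **and** whose intensity reaches the
threshold (default: 80th percentile of vessel-pixel intensities; a fixed
value of 0.8 is used for cohort studies, because a percentile adapts to
image composition and would confound group contrasts). Cross-sections are
reconstructed as the union of the seeds' inscribed discs clipped to the
vessel mask. A full geodesic reconstruction was rejected: wherever one
capillary touches a large vessel it floods the entire connected mesh. The
disc-union variant is also monotone — raising the diameter threshold only
removes seeds, so the mask never grows — and partitions the vessel map
exactly into large-vessel and capillary compartments. Components below
50 px are dropped as speckle (logged). When both thresholds are zero the
mask degenerates to the full vessel map by construction.

Diameter convention: the Euclidean distance transform measures
center-to-center distance to the first background pixel, overstating the
half-width by half a pixel per side; local diameter is therefore
(2·EDT − 1) px, which makes a 1-px line read 1 px and an 11-px bar read
11 px, and the reconstruction disc for a seed with EDT ∈ (r−1, r] has
radius r − 1.

## Skeletons, tortuosity, dispersion

Skeletons come from topology-preserving thinning; polyline segments are
traced between pixels of degree ≠ 2 (8-connectivity). Thinning leaves
small clusters of adjacent branch pixels at junctions; connectors internal
to one cluster are dropped so a plus-shaped crossing yields its four arms.
Closed loops (annuli) are traced as single cycles.

Arc length of a pixel polyline is chord-summed over every 7th point: raw
8-connected chain-code length overestimates smooth curves by up to ~8%
(worst at 22.5°), which would push a rasterized half-circle's arc/chord
ratio ~5% above π/2; at step 7 the residual error is < 0.5%. MVT is the
length-weighted mean ratio over large-vessel segments clipped to the
parafovea, excluding chords under 10 px (too short to define a
direction); with no qualifying segment the metric is reported missing,
never zero.

MVDisp estimates the local tangent at each skeleton pixel by PCA over
skeleton pixels within a 5-px radius and averages 1 − |cos θ| against the
radial direction over the parafoveal SCP skeleton (all vessels, not just
large ones — capillary organization is what the metric is about). The
scale is anchored by three analytic limits, all tested: radial spokes → 0,
concentric rings → 1, isotropic orientations → 1 − 2/π ≈ 0.363 (since a
uniform acute angle has E[|cos θ|] = 2/π). Fewer than 20 qualifying pixels
→ missing.

## FAZ demarcation

360 equally spaced rays leave the fovea center; each is traversed with an
exact grid walk (Amanatides–Woo DDA) so that every crossed pixel is
tested — fixed-step nearest-neighbour sampling skips 1-px diagonal vessels
and produced spurious spikes through the terminal capillary ring. The
entry point into the first vessel-positive pixel fixes the boundary
radius; rays reaching the border are clamped there and counted as open
(flagged in provenance).

The radius profile r(θ) is low-pass filtered with a 9° circular moving
average before the polygon is built. Adjacent rays a fraction of a pixel
apart inherit independent ±half-pixel quantization jitter; unsmoothed,
this jitter inflates the perimeter of a perfect disc to acircularity
≈ 1.4 while leaving the area almost unbiased. 9° ≈ the correlation length
needed to suppress that jitter while passing both analytic fixtures
(punched 0.3-mm disc: area within 3%, acircularity ≤ 1.05; 0.2/0.1-mm
ellipse: acircularity within 2% of the quadrature oracle); genuine
low-order lobes (modes ≲ 10) survive it. Area is computed by the shoelace
formula, perimeter as the polygon edge sum; acircularity
= perimeter / 2√(πA) ≥ 1 by the isoperimetric inequality.

## Synthetic angiogram generator

The generator renders what the pipeline measures, not OCT physics — no
speckle or flow modelling; noise is additive Gaussian (σ = 0.05), vessel
intensities are flat (large vessels 0.95, capillaries 0.65, background
0.12). Per layer:

* **FAZ**: an area-preserving ellipse (semi-axes r/(1−e²)^¼, r·(1−e²)^¼,
  so the true area is πr² at any eccentricity) with low-order radial
  lobes (Fourier modes 3–6, relative amplitude `faz_irregularity`).
  Lobes, not eccentricity, drive acircularity: an area-preserving ellipse
  at e = 0.45 raises acircularity by < 0.01, far below measurement
  jitter. A terminal capillary ring hugs the boundary — the perifoveal
  arcade that actually bounds the FAZ in vivo; without it, ray casting
  leaks through mesh gaps and overshoots the area by ~10%.
* **Large vessels** (SCP only): 5 radial arcs with sinusoidal meander
  (amplitude `vessel_wobble_mm`, wavelength 0.9–1.5 mm), rendered at the
  requested caliber by polyline dilation. The count is fixed at 5: the
  number of major perifoveal branches in a 3 × 3 mm window is roughly
  constant across eyes, and at cohort sizes of ~10/group random count
  variation would otherwise dominate the caliber effect on PDL.
* **Capillary mesh**: short strokes (~0.25 mm) placed until the target
  vessel-area fraction is reached, each radial or tangential (share
  `tangential_fraction`) with angular jitter — orientation control is
  what the dispersion tests need.
* **DCP**: its own mesh and a 1.1× larger FAZ, no large vessels.

Cohorts draw per-subject parameters from group distributions; the RVO
group shifts encode rarefied capillaries (−0.10 area fraction), narrower
(−10 µm) and more meandering (+0.05 mm) large vessels, and a larger
(+0.10 mm), more eccentric (+0.25), more lobulated (+0.15) FAZ with more
tangential capillaries (+0.30). Visual acuity is generated from a stated
linear model (BCVA = 0.20 + 2.2·capillary_density − 1.5·faz_radius + ε,
ε ~ N(0, 0.06²)) — plumbing for recovery tests, not a biological claim.
Comorbidity and age distributions differ by group so the demographics
machinery has realistic input. Everything is reproducible from one seed.

What passing tests show — and don't: recovery and direction-of-effect
results demonstrate that the measurement chain responds correctly to
controlled anatomy. They do not certify performance on device exports,
which add projection artifacts, motion, segmentation errors and
signal-dependent noise that the generator deliberately omits.

## Statistics

* Kendall tau-b (tie-corrected) pairwise over the twelve biomarkers;
  Bonferroni = raw p × number of distinct pairs, capped at 1, α = 0.05.
  The implementation is pinned to an O(n²) pair-enumeration oracle in the
  tests.
* Biomarker clustering: complete linkage on distance 1 − τ (signed, not
  1 − |τ|, so anticorrelated markers stay apart), dendrogram cut to 5
  subtrees by default.
* Group differences: Welch (unequal-variance) two-sided t-tests,
  Benjamini–Hochberg across the twelve biomarkers, significance at
  adjusted p < 0.1. Welch is also used for demographics: on the bundled
  cohort's printed age summaries it reproduces the published p (0.0029)
  where a pooled test does not (≈ 0.0020).
* Proportion tests: Pearson chi-square on the 2 × 2 table without
  continuity correction — the convention that reproduces the published
  binary-row p-values.
* Demographics adjusted column: BH across the eight tested rows, applied
  to the raw p-values at printed (4-decimal) precision — published tables
  derive their adjusted columns from the rounded raw column, and this
  convention reproduces the bundled cohort's adjusted values exactly.
* LASSO: predictors standardized; binomial deviance (log loss) for
  disease status, squared error for acuity; λ on a log grid chosen by
  seeded 10-fold CV. Default rule is the deviance minimum; the 1-SE rule
  is exposed (`rule="1se"`) and is the right choice when false selections
  are costly — on pure-noise outcomes the minimum rule occasionally keeps
  several near-zero coefficients, while 1-SE selects none.

## Problem sizes and determinism

Synthetic validation runs at 304 px (single samples, acceptance) and
192–224 px (parameter-recovery grids and exchangeability checks, where
many samples are rendered); the direction-of-effect study uses 10
eyes/group. Every stochastic routine takes an explicit seed; CLI runs
write a provenance JSON (thresholds, ray counts, seeds) sufficient to
reproduce outputs bit-identically.

## Known limitations

* No projection-artifact removal, B-scan/volume processing, or
  artery/vein classification.
* The large-vessel heuristic assumes large vessels are both brighter and
  wider than capillaries; pathologies that invert either cue would need
  re-tuned thresholds.
* MVDisp's functional form (1 − |cos θ|) is this package's concretization
  of "degree of centripetalism"; it is versioned in provenance and should
  be cited with the package version.
* FAZ smoothing (9°) bounds the angular resolution of acircularity;
  extremely fine boundary crenellation is deliberately not scored.
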