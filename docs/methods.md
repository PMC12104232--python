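# Methods

`contourvar` quantifies how inter-observer variability (IOV) in
radiotherapy structure delineation propagates into dose coverage and
radiobiological outcome estimates, and screens geometric IOV metrics as
risk predictors of that propagation. This note documents the models, the
conventions that had to be fixed where the field admits several, and the
synthetic cohort on which the package validates itself.

## Geometric variability metrics

For a structure delineated by observer *M* with gold-standard volume *S*:

* **ΔV = V_M − V_S** (cc), signed: under-contouring is negative.
* **MMR = V_max / V_min** over the observer panel (≥ 1). Undefined if any
  volume is zero; such inputs are rejected.
* **CV = SD(V) / mean(V)** over the observer panel. The **sample** SD
  (n − 1 denominator) is used — the appropriate convention for observer
  panels of 4–10. MMR and CV are computed over observer volumes only; the
  gold standard is excluded.
* **DSC = 2|A∩B| / (|A| + |B|)**. Two empty masks have no defined overlap
  and raise.
* **HD95**: distances are measured between boundary-voxel centers,
  respecting anisotropic spacing (slice spacing in CT is typically 2–3×
  the in-plane spacing). A voxel is boundary iff occupied with an
  unoccupied 6-neighbor (the volume edge counts as unoccupied). The
  package reports the **symmetric** HD95 — the maximum of the two directed
  95th percentiles — because a similarity measure between two contours
  should not depend on argument order; both directed values are exposed
  (`hd95_directed`) so either convention can be recovered. Percentiles use
  linear interpolation between order statistics, making ties
  deterministic. Distances are computed with an exact Euclidean distance
  transform; an O(n²) all-pairs enumeration serves as the test oracle and
  the two agree exactly.

## STAPLE consensus

The consensus gold standard for a validation panel is estimated with the
binary STAPLE model: observer *j* has sensitivity *p_j* and specificity
*q_j* with respect to an unknown true segmentation. EM alternates a
per-voxel posterior (E-step, computed in log space) with performance
re-estimation (M-step), until max|Δp|, |Δq| < 1e−6 or 100 iterations.
Conventions that the model leaves open, fixed here and recorded in the
result object: global foreground prior = mean observer foreground
fraction (configurable); initial p = q = 0.99; consensus threshold 0.5
with posterior ties falling inside; rates clamped to [1e−6, 1 − 1e−6]
(an all-empty observer is warned about, not fatal).

A caution established while testing: with full EM the consensus does
**not** generally equal majority vote — the M-step learns unequal
reliabilities and re-weights observers, which on small or structureless
inputs can deviate substantially from vote counting. The classical
reduction "equal reliabilities + uniform prior ⇒ majority vote" holds
when equal performance is imposed; `staple(..., estimate_performance=False)`
provides exactly that mode and reduces to majority vote provably and in
tests.

## Dosimetric statistics

Masks define the integration domain: when dose and mask grids differ, the
dose is resampled trilinearly onto the mask grid, never the reverse
(binary masks under trilinear interpolation would produce ambiguous
partial volumes). Cumulative DVHs use 0.01 Gy bins by default, but the
exact voxel doses are retained alongside, so EUD, D1cc and PDC are
bin-free.

* **PDC** (prescription dose coverage) = percent of PTV voxels with dose
  ≥ prescription, whole-voxel counting. "Receives the prescribed dose" is
  read literally as ≥, with no tolerance band.
* **Dmax / Dmean / D1cc**: D1cc (minimum dose to the hottest 1 cc) is
  computed on the exactly sorted voxel doses with linear interpolation at
  the 1 cc boundary, removing bin-width sensitivity from a serial-organ
  metric; it agrees with the binned-DVH estimate within one bin width.
  Structures smaller than 1 cc report D1cc = Dmin with a warning. Serial
  organs are summarized by Dmax (or D1cc), parallel organs by Dmean (or
  D1cc).
* **ΔD_diff = 100 · (D_M − D_S)/D_S** (%), signed, per organ, observer
  plan versus gold-standard plan evaluated on the *gold-standard*
  structure.

## Radiobiological endpoints

**EUD** is the generalized power mean `(Σ v_i d_i^a)^(1/a)`; the target
exponent a = −8 makes cold spots dominate, which is the mechanism that
couples target under-contouring to loss of tumor control. For a < 0,
voxel doses below 0.01 Gy are clamped to 0.01 Gy (configurable constant
`EUD_EPS_GY`) so the power mean stays finite; a single near-zero voxel
still collapses the EUD, as intended. Evaluation is in log space
(logsumexp) so exponents of ±20 remain exact to ~1e−12 relative.

**TCP** follows the Schultheiss logistic form
`TCP = 1 / (1 + (TCD50/EUD)^(4·γ50))` with TCD50 = 61.69 Gy, γ50 = 3.38
and a = −8 as defaults (Okunieff-derived nasopharyngeal parameters). The
exponent is implemented literally as 4γ50; no re-parameterization is
attempted. TCP(TCD50) = 0.5 identically for any slope — the analytic
anchor the acceptance script recomputes.

**NTCP** uses a modified linear-quadratic (Zaider-style) Poisson form
`NTCP(D, V) = exp[−N0 · V^(−k) · exp(−α·D·Γ)]`, with D the organ's
class-appropriate summary dose and V the relative irradiated volume
(V = 1 in the default uniform-summary mode; no per-DVH-bin evaluation is
provided). The fractionation factor Γ is written ambiguously in the
source material; the default here is the standard LQ per-fraction
correction **Γ = 1 + d_f/(α/β)** with d_f = D/n_fractions (33 fractions
default), and `gamma_mode="total_dose"` switches to Γ = 1 + D/(α/β).
N0 = 0 would force NTCP = 1 at every dose and is rejected at parameter
validation. No published per-organ (N0, k, α, α/β) table is bundled: the
pipeline ships a clearly-labelled synthetic placeholder set
(`DEFAULT_NTCP_PARAMS`) and expects users to supply organ parameters for
any clinical interpretation.

## Statistical layer

Paired observer-vs-standard comparisons choose between the paired t-test
and the Wilcoxon signed-rank test by Shapiro–Wilk normality of the paired
differences at α = 0.05 (degenerate differences fall through to
Wilcoxon); the chosen test is reported per row so either convention can
be audited. All-zero differences short-circuit to a flagged
"no difference" with p = 1. Wilcoxon uses zero-difference exclusion and
the exact distribution for n < 25 when ties permit.

Spearman correlations use average ranks for ties; the p-value is exact
(permutation enumeration) for n ≤ 10 and the t-approximation above. The
risk-predictor rule keeps correlations with **p < 0.05 and |r| > 0.4**,
sorted by |r|; under an independent null at n = 48 this double gate fires
in well under 5% of simulations (verified at 500 replicates). No
multiple-testing correction is applied by default, matching the raw-P
plus |r|-gate screening convention; the pooling mode (all
patient × observer pairs pooled, the default, versus per-patient observer
means) is recorded in the manifest.

## Synthetic cohort

The generator reproduces the *statistical structure* the analysis
assumes, not patient realism:

* **Phantom**: ellipsoidal nasopharyngeal target (~29 cc, matching the
  reported gold-standard scale), a posterior spinal-cord tube (serial,
  ~10 cc), paired parotid ellipsoids (parallel, ~12 cc), paired optic-nerve
  ellipsoids (~0.2 cc — the small-organ regime where relative IOV is
  largest). Default grid 128 × 128 × 96 at 1 × 1 × 2.5 mm (the 2.5 mm
  slice matching the typical dose-grid scale). Per-patient jitter: ±7%
  axis scaling, ~1.5 mm center displacement. GTV–cord disjointness is
  asserted.
* **Observers**: each structure's signed distance field is rigidly
  shifted (per-axis N(0, shift_mm)), then re-thresholded at
  `volume_bias + noise(x)`, where noise is a smooth Gaussian random field
  (correlation length ~10 mm) — boundary perturbations are anatomically
  coherent rather than voxel salt-and-pepper. Perturbation magnitudes
  scale with the structure's equivalent-sphere radius (capped at 1 at
  r = 15 mm), so small organs receive smaller absolute but much larger
  *relative* perturbations, reproducing the observed pattern that DSC and
  CV degrade most for small structures. The four default observers span
  volume_bias ∈ {−4, −2, +1, +3} mm with 1 mm surface noise and 0.5 mm
  shifts, giving GTV MMR ≈ 2.7 and CV ≈ 0.4 at the default seed —
  the qualitative scale reported for nasopharyngeal target panels.
* **Dose surrogate**: dose = prescription inside the planning PTV (the
  observer's own target + 3 mm margin) and
  `prescription · exp(−d²/2σ²)` outside it, σ = 3 mm. This is *not* an
  IMRT dose engine; it is the minimal field with the one property the
  analysis exploits — conformality to the planned target with a finite
  penumbra — so under-contouring produces cold spots on the gold-standard
  target while over-contouring leaves its coverage intact.
* **Reproducibility**: one master seed feeds a `SeedSequence` spawn tree
  (per patient, then per observer); cohort regeneration is byte-identical,
  and the run manifest records the seed and a config hash.

What passing tests on this cohort do **not** show: real contour
variability is structured by image contrast and anatomical ambiguity, not
by isotropic distance-field offsets; real dose distributions have
streaks, hot spots and constraint-driven shapes the Gaussian-penumbra
surrogate lacks; and the NTCP parameter placeholders are synthetic. The
end-to-end claims validated here are directional and structural (the
ΔV → ΔPDC/ΔTCP coupling, the over/under-contouring asymmetry, selection
calibration), not clinical effect sizes.

## Numerical choices and degenerate inputs

* Distance transforms, margin expansion and observer perturbation run on
  padded bounding boxes; padding is chosen from the perturbation
  magnitude and the result is verified not to touch the box border, so
  the cropping is exact, not approximate.
* Margin expansion: voxel occupied iff center-to-center Euclidean
  distance to the original set ≤ margin (+1e−9 guard); margin 0 is the
  identity; negative margins are rejected (erosion exists only as an
  observer-model bias).
* Mask binarization on read: value > half of the volume maximum, so
  {0,1}, {0,255} and probability maps binarize consistently; all-zero
  volumes are valid empty masks (warned).
* Problem sizes in the test suite: module tests run on ≤ 64³-scale grids;
  the end-to-end recovery test runs the full default cohort
  (12 patients × 4 observers at 128 × 128 × 96), chosen to mirror the
  12 × 4 clinical design while keeping a full suite run in the minutes
  range.

## Known limitations

* DICOM-RT polygon import is not implemented; masks enter as volumetric
  images (NIfTI).
* NTCP is evaluated at a single (D, V) summary point per organ, not
  integrated over the DVH.
* The dose surrogate cannot represent plan-optimization trade-offs
  (e.g. an OAR constraint carving dose out of a PTV).
* No alternative TCP/NTCP families (Poisson TCP, LKB, relative
  seriality) and no parameter fitting to outcome data.
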