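# Methods

This note documents the models and procedures implemented in `detensio`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical decisions that matter for
reproducing results.

## Fiber-orientation entropy

### Model

A 2D SHG-style micrograph is treated as bright curvilinear fibers on a
dark background. The pipeline is:

1. **Projection** (3D stacks): maximum-intensity projection over the
   first `projection_depth_um` of the stack (default 13 µm, the
   superficial endometrial layer in the motivating application);
   slices = round(depth / z-step), minimum 1.
2. **Tubeness**: Gaussian smoothing at σ = `tubeness_scale_um` (default
   1.0 µm), the 2×2 Hessian per pixel by central finite differences, and
   the bright-ridge response max(0, −λ₂) with λ₂ the more-negative
   eigenvalue. Single-scale: collagen fiber width varies little within
   one acquisition, and a fixed scale keeps the response comparable
   across images.
3. **Masking**: for the *orientation* analysis the default mask is every
   pixel with positive tubeness response (`orientation_mask =
   "tubeness_positive"`, floor 10⁻⁴ × max to drop numerically-zero
   background). A hard intensity threshold (IsoData) is also available
   but is not the default here: in fields with overlapping fibers the
   auto-threshold settles above the response of isolated fibers' flanks,
   silently over-representing bright fiber bundles and biasing the
   orientation histogram toward the dominant direction. The squared
   gradient-magnitude weighting (below) already suppresses background,
   so the permissive mask loses nothing.
4. **Orientation histogram**: Gaussian-derivative gradients at
   `gradient_scale_um`; local fiber orientation = gradient direction
   + 90°, folded into the axial interval [−90°, +90°) (orientations are
   defined mod 180°); each masked pixel contributes weight |∇I|².
   Pixels within 3σ of the frame border are excluded — their derivative
   filters are truncated and produce artifactual orientations. With
   `circular_fov=True` the analysis is further restricted to the
   inscribed disc: chords of a square field are longer for frame-aligned
   fibers (up to √2), so a square region of interest over-weights 0°/90°
   orientations; a disc is isotropic.
5. **Entropy**: H′ = −Σ pᵢ ln pᵢ in nats, with 0·ln 0 = 0. The ceiling
   is ln n_bins and is always reported alongside H′.

### Bin count

The default reporting resolution is 180 bins of 1° on [−90°, +90°),
half-open so the axial identity −90° ≡ +90° is counted once. For
*recovery benchmarks against a finite sample of fiber angles* the
comparisons in the test-suite and acceptance script use 16 bins
(11.25°): a histogram of a few hundred sampled angles at 1° resolution
is dominated by occupancy noise (its entropy is biased low by roughly
(K−1)/2N), which no estimator of per-pixel orientation can or should
reproduce bin-for-bin. Matching bin width to sample size is standard
practice; the bin count is a parameter everywhere and is echoed in every
result record.

### Known estimator limitations

Per-pixel gradient orientations are corrupted where fibers cross or run
close together: the blended intensity profile yields intermediate
orientations, which slightly concentrates the histogram toward the
locally dominant direction at moderate alignment (a few hundredths of a
nat under the benchmark conditions) and adds a small broad background at
high alignment. These are properties of all local-gradient estimators,
not of this implementation; the acceptance benchmarks quantify them.

### Coverage analysis

Independent of the entropy path: IsoData threshold on the (projected)
intensity image — the iterative intermeans fixed point t = (mean below +
mean above)/2 computed on the raw values — then 8-connected component
labeling and removal of particles below `min_particle_area_um2`
(default 0.172 µm²; the value is interpreted in µm² on calibrated
images). Output is retained area / analyzed area and the retained
particle count. An optional polygonal ROI restricts the analysis; a
zero-area polygon is rejected.

## Perfusion (fBV / PS)

Normalized enhancement y(t) = C_t/C_blood is modeled as linear in time:
y = fBV + PS·t. The fit is ordinary least squares over 0 < t ≤ 15 min
(the window is a parameter); the pre-injection baseline t ≤ 0 is
excluded. C_blood may be a scalar (already extrapolated to t = 0) or a
series, in which case the t = 0 value is obtained by OLS extrapolation
and must be positive. Negative fitted parameters are *reported* with a
`nonphysical` flag rather than clipped — clipping would bias group
means. Per-site fits are aggregated as plain means with SEM. Weighted
regression is deliberately not used: with uniform sampling and additive
noise OLS is the maximum-likelihood estimator, and exact recovery from
noiseless input (to 1e−12) is part of the test contract.

## Degradomics

### Protein level

Intensities are log2-transformed (zeros treated as missing); a protein
is tested only with ≥ 2 values per group. log2fc is the difference of
group means of log2 abundance. The test is Welch's unequal-variance
two-sample t-test with Welch–Satterthwaite degrees of freedom; when both
group variances are zero an ε-guard (ε = 1e−12) replaces the collapsed
standard error so equal means give p = 1 and unequal means p → 0.
q-values are Benjamini–Hochberg step-up over all tested proteins
(computed via `statsmodels.multipletests`; a brute-force step-up oracle
pins the semantics in the tests). The substrate filter is strict:
log2fc > 0.4 AND q < 0.1, both configurable, results ordered by
descending log2fc.

### Peptide level

Coordinates are 1-based inclusive. A terminus conforms to the digest
rule (default: cleave after K or R, no proline suppression, matching the
common semi-trypsin search configuration; one missed cleavage for
digest generation) if the preceding residue is in the cleavage set or
the terminus coincides with a protein terminus. Class = tryptic (both
conform), semi-tryptic (exactly one), non-tryptic (none). For each
non-conforming terminus the P1 residue (immediately N-terminal to the
implied cleavage) is extracted — from the protein for an N-terminal
boundary, from the peptide's last residue for a C-terminal boundary —
and the peptide is *favorable* if any P1 is Leu or Ile, the documented
collagenase-1 preference (MEROPS M10.001). A non-conforming N-terminus
at position 1 (only possible under non-default rules) has no P1 and is
never favorable by that boundary.

## Expression (2^−ΔΔCT)

Technical replicates are averaged on the CT scale per sample. ΔCT =
CT_target − CT_reference; ΔΔCT = ΔCT − mean control ΔCT (arithmetic mean
of the control group as calibrator); fold change = 2^−ΔΔCT. Group
summaries (mean, SEM) are computed on the fold-change scale. Because the
calibrator is the control mean, the control group's mean fold change is
≥ 1 by Jensen's inequality and equals 1 only when all control ΔCTs
coincide — a property test, not a bug. CT values outside 5–40 trigger a
warning; rows missing either CT are dropped with a warning. Primer
efficiency is assumed to be 2 (no Pfaffl correction).

## Synthetic generators

All generators take a mandatory seed, use one `numpy` Generator per
call (no global state), are bitwise reproducible, and emit their ground
truth with the data.

**Fiber fields.** Axial orientations are sampled by the doubled-angle
construction (von Mises on 2θ, halved, folded into [−90°, 90°));
κ = 0 means uniform. Fibers are drawn as sub-pixel-sampled strokes —
straight chords spanning the frame by default (collagen fibers are long
relative to a field of view; finite `fiber_length_um` gives short
segments), with optional sinusoidal waviness — bilinearly deposited,
blurred by stroke width and PSF, peak-normalized, then degraded by
optional Gaussian and/or Poisson noise. Defaults model a tiled
two-photon acquisition: 1440×1440 px at 0.5 µm/px (720 µm field),
210 fibers (sparse enough that fiber crossings corrupt few pixels,
dense enough that the sampled orientation histogram is stable), 1 µm
stroke width, 0.4 µm PSF. The ground-truth distribution is the exact
binned histogram of the sampled angles. What the phantom does *not*
emulate: coherent SHG physics (polarization dependence,
forward/backward ratio), fiber bundling and curvature beyond a single
sinusoid, depth attenuation, and detector artifacts — so passing
recovery tests demonstrates correctness of the estimator on idealized
fibers, not robustness to every property of real tissue.

**Kinetics.** C_t = C_blood·(fBV + PS·t) + N(0, σ); defaults fBV = 0.05,
PS = 0.003/min, one sample per minute for 15 min — mid-range values for
implantation-site imaging. The generator is exactly the fitted model, so
noiseless closure is exact by construction; tests of bias and variance
use the seeded noise path.

**Proteomes.** Per-protein base log2 abundance ~ U(20, 30) (typical
label-free intensity range), replicate noise N(0, 0.3) on the log2
scale, 6 replicates per group, 10 true substrates of 200 shifted by
log2fc = 1 in the treated group. The digested parent is a random
250-mer with vertebrate residue frequencies; fully-tryptic peptides with
≤ 1 missed cleavage are emitted, plus one semi-tryptic fragment per
planted Leu/Ile cleavage (the C-terminal fragment, whose N-terminus
evidences the cut — one detected peptide per cleavage event, so the
favorable-peptide count equals the planted count exactly). Missingness,
ion-competition effects and shared peptides are not modeled.

## Batch runner

One stage (entropy, coverage or perfusion) over a manifest CSV
(path, group, optional animal_id). Each row carries the full parameter
echo and a SHA-256 of its input; failing inputs become `failed` rows and
the batch continues. The group comparison is an unpaired two-tailed
Welch t-test (pooled-variance Student available via `equal_var=True`)
with per-group mean, SEM and n; with ≥ 2 animals per group a per-animal
comparison (mean of per-image values per animal) is reported alongside
the per-image one, since the appropriate unit of analysis differs
between studies.

## Problem sizes in the benchmarks

The acceptance script and the acceptance tests use: 10 images per κ for
entropy recovery and 10 per group for the cohort comparison (1440×1440
phantoms); 20 random 32×32 images for the tubeness oracle; 500
Monte-Carlo replicates for fBV/PS bias; 100 random p-vectors (m ≤ 1000)
and 100 seeded null tables for the BH checks; 100 spike-in replicates
for sensitivity/FDR; 20 random 60-mers, all substrings of length ≥ 5,
for the digestion oracle. These sizes make every stochastic check stable
at its stated tolerance while the whole suite completes in minutes.
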