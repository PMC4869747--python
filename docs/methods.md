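# Methods

This note records the models implemented by `fibermech`, the defaults that
matter, the design choices made where the method description left room, and
what the synthetic benchmarks do and do not establish.

## Fiber segmentation (eLoG bank)

The base kernel is the negated Laplacian of an anisotropic Gaussian,
elongated along the fiber axis. Defaults: σ_across = 1.5 px (matched to the
apparent width of a diffraction-limited fiber at ~20× magnification),
σ_along = 12 px, support = ceil(6 σ_along) rounded odd, 30 rotations at
π/30. The strong elongation is deliberate: with σ_along ≲ 6 px the
responses of adjacent rotations are so correlated that the per-pixel argmax
orientation jitters by one or two 6° steps even on noiseless fibers, which
defeats the downstream orientation-agreement criterion. Kernels are
mean-subtracted, so the response ignores constant offsets; convolution uses
reflective padding (FFT-based).

Thresholding of the maximum-response image defaults to Otsu over the
positive responses inside the cell mask, applied with hysteresis (low cut
0.55 × Otsu, connected to above-Otsu ridges). A single hard cut keeps only
the ridge crest (~±1 px) and loses the fiber's intensity skirt; pushing the
hysteresis floor much lower is counterproductive because beyond ~2 px from
a ridge centerline the argmax orientation is no longer meaningful (the
aligned kernel's cross-profile crosses zero there). Responses below
numerical round-off of the image scale are treated as blank. Absolute and
relative threshold overrides exist.

The per-pixel winning angle is refined by quadratic interpolation across
the circularly adjacent rotations, giving sub-step orientations; the raw
argmax is recoverable by snapping to the π/30 grid. Bright spots are *not*
removed at this stage; that is the refinement step's job.

## Refinement (CEDF + orientation trimming)

Enhancement diffuses a real-valued relaxation of the binary mask with
Weickert's coherence-enhancing tensor: structure tensor at gradient scale
σ = 1 px and integration scale ρ = 4 px, diffusivity α = 10⁻³ across
coherent structures and `α + (1−α)·exp(−C/(μ₁−μ₂)²)` along them with
C = 10⁻⁵, 15 explicit steps of Δt = 0.2, re-binarized at 0.5. These values
are chosen so a 2-px interior gap in a 1-px fiber closes in a single
enhancement pass while an isolated pixel (no coherent direction) does not
grow; the commonly cited 4–5 diffusion steps are too few to lift the gap
midpoint above the 0.5 re-binarization level.

Trimming keeps a pixel only if the mean of cos(Δθ) over the fiber pixels in
its 9×9 neighborhood exceeds 0.995, where Δθ is the *minimal axial*
difference (so 1° and 179° count as 2° apart; equivalently |cos| of the raw
difference). Pixels with no fiber neighbor are removed. The threshold is
numerically unforgiving: one π/30 bank step already has cos 6° = 0.9945 <
0.995, so any pixel-level orientation noise of a few degrees trims real
fibers. The orientation field is therefore regularized before each trim
pass: axial orientation vectors (cos 2θ, sin 2θ) are averaged over a
radius-4 window with weights equal to the eLoG response capped at 2× the
segmentation threshold (centerline pixels dominate, and over-bright
aggregates cannot), and the result is snapped back to the π/30 grid so
coherent regions become exactly uniform. Where the local axial coherence of
that average falls below 0.7 — bright dots and junk clusters have no
dominant direction — the raw per-pixel angle is kept, so incoherent
structures stay incoherent and are trimmed. Enhancement and trimming
iterate to a fixed point (hard cap 50 iterations, with a warning); pixels
added by enhancement take the full-image argmax orientation.

Consequence worth knowing: fiber crossings and converging near-parallel
fibers are trimmed wherever two orientations share a 9×9 window — the
criterion cannot distinguish a crossing from an artifact. High fiber-pixel
recall is therefore only achievable for cells whose fibers form
near-parallel families, which is also the morphology of strongly polarized
adherent cells; randomly oriented dense fiber fields lose their
intersection neighborhoods by construction.

## Background and F-protein map

The unbound-protein background is the per-pixel median over a 21×21 window
of the non-fiber pixels, windows clipped at the image border (padding would
import fictitious intensities into what is effectively a thickness
estimate). Windows left with fewer than 10 usable pixels grow in 10-px
steps. Two apertures matter because rendered and real fibers have
diffraction tails beyond the segmented ridge: the median excludes the mask
dilated by 3 px (otherwise tails bias the background up by several AU), and
the F-protein photometry sums positive residuals over the mask dilated by
2 px (otherwise ~20 % of the fiber flux is left on the floor). Pixels whose
background-subtracted value is non-positive are dropped from the map. P_GFP
is the raw intensity sum over the cell mask, minus an optional camera
offset.

The cell mask (not part of the original method description) is estimated
from the diffuse cytoplasmic signal: Otsu on an 8-px-smoothed image,
hysteresis down to 0.25 × Otsu to capture the dim cell rim, erosion by
σ/2 px to undo the smoothing spread, closing, largest component, hole
filling. A manual mask can be supplied instead and is preferred when the
cell outline is curated by hand.

## Calibration

`F_total = F_GFP (1 + P_endo/P_GFP)`; the filamentous fraction
`F_total/(P_endo + P_GFP)` reduces algebraically to `F_GFP/P_GFP` and is
therefore invariant to global intensity scaling — P_endo only matters for
absolute amounts (F_total, calibrated FT). P_endo is found as the root of
the OLS intercept of dye-channel fiber intensity regressed on
F_total(P_endo). The intercept is monotone near the physical root but can
re-approach zero at implausibly large P_endo, so the estimator brackets the
*first* sign change on an ascending grid from zero before calling Brent's
method (tolerance 10⁻⁶ relative); only the intercept is constrained, the
slope is free. P_endo is a batch-level constant of one cell line /
transfection protocol, never per-cell. At 5 % multiplicative dye noise and
n = 30 cells the estimator's per-replicate error spans ±25 % with a median
near 11 %; single replicates should not be over-interpreted.

## Architecture metrics

FA and the mean orientation are computed exactly as the printed first-order
circular statistics on the LOF angles in [0°, 180°): C̄ = mean cos θ,
S̄ = mean sin θ, FA = 1 − √(C̄²+S̄²). On a uniform orientation distribution
this statistic gives 1 − 2/π ≈ 0.363 (not 0.5, and not the 1.0 of the
doubled-angle axial convention); an `axial=True` variant with angle
doubling is provided for users wanting standard axial statistics, but the
plain form is the default for fidelity. RL peels the cell mask into 1-px
erosion rings (4-connected structuring element), maps ring i of K to radius
1 − i/(K−1), scores each ring by its mean F-protein intensity (0 for empty
rings), and reports the radius of the maximum, ties broken toward the
periphery. Cell area, aspect ratio and major-axis direction come from the
mask's second central moments, in the same angle convention as the LOF map
(0° toward the image bottom edge).

## AFM mechanics

The BECC force for a cone of half-angle θ on a bonded sample of height h at
Poisson ratio 0.5 (baked into the constants) is implemented as written in
the package README. Kinematics: Z is piezo displacement increasing toward
the sample, F = k d, δ = (Z − Z_CP) − d, and the local height is
h = Z_glass − Z_CP with Z_glass the bare-glass contact recorded at the
start of each line scan. Curves are baseline-corrected by a line fitted on
the first 25 % of samples. Because E enters the force linearly, the modulus
for a candidate contact point is a one-parameter projection onto the BECC
shape function over the contact samples (δ > 0), clamped at E ≥ 0; r² is
computed on the contact-segment forces. The sequential search tries every
sample index leaving ≥ 10 % of the ramp (and ≥ 10 samples) in contact,
keeps the candidate maximizing r² with ties resolved toward the shallower
contact, and declares "no contact" if the best fit's maximum model force
does not rise at least 10× above the baseline force noise (MAD-based).
Fits with r² ≤ 0.75 are flagged rejected. Per-cell pooling takes medians of
accepted fits below 4 µm (cytoskeleton) and above 5 µm (nuclear region);
heights between belong to neither.

At 2 nm deflection noise the per-curve modulus scatters ±11 % (almost
entirely through contact-point jitter, to which E is locally linear), but
the estimator is unbiased: the median over repeats recovers the true
modulus within 1 %. This is the same median pooling the per-cell analysis
applies.

## Statistical layer

The stiffness fit `E = E0 + α[F]` is OLS with heteroscedasticity-robust
(HC3) standard errors by default: per-cell stiffness scatter grows with the
mean, and plain OLS intervals undercover the slope badly in that regime
(`robust=False` restores textbook OLS). Binning sorts by fraction and
averages consecutive groups (10 cells for cytoskeletal fits, 4 for
nuclear-region fits in the original pooling), dropping a short final bin.
ANCOVA fits the joint interaction regression `E ~ F + group + F:group`; the
"fits differ" decision is the joint F-test on the group terms, and the
slope/intercept contrasts are reported raw and Scheffé-adjusted for the
two-contrast family. The modulation model regresses E/E_fit on the
requested subset of {FA/⟨FA⟩, FT/⟨FT⟩, RL/⟨RL⟩} (normalizers are the sample
means of the included cells, so each regressor averages 1); subset
selection is forward stepwise over the 2³ lattice with nested F-tests at
α = 0.05, stopping early when the current model is exact to rounding. Cells
with non-positive predicted E_fit are excluded with a warning.

`derived_quantities` turns fitted linear models into the two headline
numbers: equating the actin and myosin cytoskeletal models gives
[M] = (E0_A−E0_M)/α_M + (α_A/α_M)[A], whose high-concentration slope is
α_A/α_M; equating the actin cytoskeletal and nuclear-region models gives
the critical fraction (E0_NR − E0_CSK)/(α_CSK − α_NR), reported in percent.
Equal slopes leave no crossing and are flagged.

## Synthetic data: what it emulates and what it does not

Images: an elliptical cell with a hemispheroid thickness dome minus a
Gaussian nucleus dip as the unbound-protein background, straight fibers
with Gaussian cross-sections (σ = 1.5 px) and hard longitudinal caps,
isotropic bright dots, additive Gaussian noise, all clipped at zero. Ground
truth: the fiber mask is the ±1 σ band around each centerline, the truth
LOF is the programmed angle (later fibers win at crossings), and the truth
F-protein sum is the painted fiber layer's total. Not modelled: the optical
PSF, photobleaching, camera gain/shot noise, 3-D fiber distribution — so
passing benchmarks demonstrate algorithmic correctness on idealized
epifluorescence-like data, not instrument-level performance.

The pipeline-recovery scene is a strongly polarized cell: 512×512 px at
0.3 µm/px, cell semi-axes 230×170 px (area ≈ 9900 µm², inside the observed
600–12000 µm² range), 30 fibers in one near-parallel family (orientation
σ = 1°, perpendicular spacing 11 px, lengths 150–210 px), 20 bright dots
kept ≥ 9 px from fiber centerlines and ≥ 12 px apart so every pixel has an
unambiguous label, noise σ = 2 AU against fiber amplitudes 60–120 AU.
Orientation-distribution checks (FA against closed forms) instead program
orientations on a regular 3° grid, because FA of ~40 randomly drawn
orientations carries ±0.05 sampling noise regardless of the estimator.
Measured on this scene: fiber-pixel recall 0.97–1.00, dot rejection
0.96–1.00, F_GFP within 2 % of truth, RL within one ring of a programmed
annulus.

Force curves solve the implicit balance k d = F_BECC((Z−Z_CP)−d) by
bisection (monotone, unconditionally convergent; 80 iterations) on a 5-µm,
300-sample ramp with a 0.1 N/m cantilever and 20° tip by default.

Cohorts: fractions are log-uniform over ~1.5 decades centered at the
observed medians (actin 5.9 %, myosin 3.4 %); per-cell stiffness scatter is
multiplicative lognormal with σ_log = 0.35, calibrated so the slope
estimator's empirical SD at n = 100 matches the reported fit uncertainties
(1.05 vs 1.02 kPa actin, 1.73 vs 1.91 kPa myosin). An additive-noise model
with equivalent spread truncates at E = 0 and biases the intercept.
Architecture descriptors draw FA ~ N(0.22, 0.07) truncated, FT lognormal
with tenfold spread around the cohort mean, RL ~ N(0.70, 0.08) clipped, and
the modulation ratio carries N(0, 0.10) residual noise — a
signal-to-noise regime in which term-set selection is reliable (the
original single-experiment scatter, r² ≈ 0.07, makes selection borderline
by construction; the benchmark demonstrates method correctness, not that
one experiment of that size decides the model).

## Known limitations

- Orientation trimming removes genuine fiber crossings along with
  artifacts; per-pixel recall on isotropic dense fiber fields is
  structurally low.
- Fiber ends lose ~5–6 px to the elongated kernel's support; short fibers
  (< ~50 px) are disproportionately penalized.
- The LOF map is a 2-D projection; out-of-plane orientation is invisible,
  so FA is a lower bound on true 3-D disorder.
- RL is sensitive to the cell-mask radius; an 8 % mask underestimate biases
  RL by ≈ +0.08. Prefer curated masks when available.
- The BECC model assumes a bonded, homogeneous, incompressible sample and a
  perfectly conical tip; blunt or pyramidal tips and viscoelastic response
  are out of scope.
- P_endo transfers only within one cell line, transfection protocol and
  imaging configuration.
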