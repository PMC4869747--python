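# fibermech

Quantitative tools for relating **stress-fiber amount and architecture** to
**single-cell stiffness**, for labs that combine live-cell epifluorescence
imaging of GFP-tagged cytoskeletal proteins (actin, myosin II, tubulin) with
AFM force–indentation mapping of the same cells.

The package covers the full chain:

1. **Fiber quantification from images.** Fibers are segmented with a bank of
   30 rotated elongated Laplace-of-Gaussian (eLoG) kernels (π/30 steps);
   the winning rotation angle per pixel gives the local orientation of
   fibers (LOF). The binary map is refined by iterating coherence-enhancing
   diffusion filtering (gap completion) with orientation trimming: a pixel
   survives only if the mean cosine of its axial orientation difference to
   the fiber pixels in a 9×9 neighborhood exceeds 0.995, which removes
   bright-dot artifacts. The unbound-protein background (a 21×21 masked
   median that tracks the cell's thickness profile) is subtracted, and the
   positive fiber residuals form the F-protein map whose sum is F_GFP.
2. **Expression calibration.** Assuming tagged and endogenous monomers
   incorporate with equal probability,
   `F_total = F_GFP (1 + P_endo / P_GFP)` and the filamentous fraction is
   `F_total / (P_endo + P_GFP)`; the batch-level scaling factor `P_endo` is
   estimated from paired GFP/dye images as the value whose dye-vs-F_total
   fit passes through the origin.
3. **Architecture descriptors.** Fiber alignment `FA = 1 − √(C̄² + S̄²)`
   from the circular statistics of the LOF map (0 = perfectly aligned),
   apparent fiber thickness FT (mean calibrated fiber-pixel intensity), and
   radial location RL (normalized radius of the peak fiber density over
   1-px erosion rings of the cell mask; 1 = periphery), plus cell area and
   aspect ratio.
4. **AFM mechanics with the bottom-effect cone correction (BECC).** For a
   conical tip on a thin sample of height `h` bonded to glass,

   ```
   F = (8 E tanθ δ²)/(3π) · {1 + 1.7795·(2 tanθ/π²)(δ/h)
                               + 16·1.7795²·tan²θ·(δ²/h²)}
   ```

   with `F = k d` and `δ = (Z − Z_CP) − d` (Poisson ratio 0.5). The contact
   point Z_CP is found by a sequential search maximizing the fit r²;
   fits with r² ≤ 0.75 are rejected; `h` follows from the bare-glass
   contact reference. Per-cell stiffness pools location medians into
   cytoskeletal (h < 4 µm) and nuclear-region (h > 5 µm) values.
5. **Statistics.** Linear stiffness models `E = E0 + α[F]` per protein and
   compartment (optionally on 10-cell bins), ANCOVA between cohorts with
   Scheffé-adjusted contrasts, and the architecture-modulation model
   `E/E_fit = a + b·FA/⟨FA⟩ + c·FT/⟨FT⟩ + d·RL/⟨RL⟩` with the regressor
   subset chosen by nested F-tests.

A first-class synthetic-data module generates ground-truth-labelled
fluorescence images (fibers with programmed orientation distributions, a
thickness-profile background with a nucleus dip, bright-dot artifacts) and
AFM ramps from the BECC forward model, so every stage is benchmarked
without any real data.

## Worked example

```bash
fibermech simulate --out sim --seed 7 --n-fibers 12 --n-dots 5 --n-curves 4
fibermech quantify sim/image.tif --out quant
# F_GFP=1.42e+05  FA=0.232  RL=0.62
fibermech fitcurves sim/manifest.tsv --out fits
# 4 fits, 0 failures
```

`quantify` prints the filamentous GFP amount (F_GFP, AU), the fiber
alignment (FA 0.23: moderately aligned fibers) and the radial location
(RL 0.62: fiber density peaks outside mid-radius) and writes the per-cell
table plus mask/LOF/background/F-protein TIFFs. `fitcurves` writes per-curve
`(Z_CP, E, r², h, accepted)` rows and per-cell pooled stiffness.

The same flows are available as a library:

```python
from fibermech.synthetic import simulate_stiffness_cohort, ACTIN_CSK
from fibermech.stats import fit_stiffness_model

cohort = simulate_stiffness_cohort(ACTIN_CSK, 100, seed=1)
fit = fit_stiffness_model(cohort)
print(f"E0 = {fit.e0_kpa:.2f} kPa, alpha = {fit.alpha_kpa:.2f} kPa")
# E0 = 0.42 kPa, alpha = 8.64 kPa   (programmed: 0.37 and 9.48)
```

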