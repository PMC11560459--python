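# leafspec

Chemometric modeling of foliar traits from leaf visible-to-shortwave-infrared
(VSWIR, 350–2,500 nm) reflectance spectra.

Fresh-leaf reflectance carries signatures of pigments, water, and mineral
nutrition, which makes spectroscopy an attractive non-destructive substitute
for wet-lab tissue assays in crop phenotyping and precision agriculture. The
statistical challenge is that a spectrum supplies ~2,000 highly collinear
1-nm wavebands for a few hundred samples. `leafspec` implements the standard
chemometric answer — partial least squares regression — together with the
model-selection machinery needed to use it honestly:

- **SIMPLS** (de Jong's PLS algorithm) for a single response on
  mean-centered, unscaled data: orthonormal scores `T`, weights `R`,
  loadings `P`/`q`, regression vector `B = Rq`, with one fit yielding the
  whole family of sub-models `1..A`.
- **A repeated-split cross-validation harness**: by default 1,000 random
  80/20 calibration/validation splits, with fivefold cross-validation inside
  each calibration set; PRESS, RMSE (also as % of the full-dataset trait
  mean), R², and RPD = SD/RMSE per component count, averaged over
  iterations into a component curve.
- **Three component-selection rules** operating on the mean validation
  PRESS curve: the global minimum (`press_min`); a backward penalty
  (`press_adj`) that walks down from the minimum while each removal costs at
  most 1.5% of the maximum validation PRESS; and Van der Voet's two-sided
  randomization *t*-test (`voet`, sign-flip permutations on paired squared
  residuals, α = 0.01) choosing the smallest model not significantly worse
  than the PRESS minimum. RPD reliability classes: excellent (> 2.0), fair
  (1.40–2.00), non-reliable (< 1.40).
- **Interpretation tools**: variable-importance-in-projection (VIP) scores
  (mean square exactly 1, threshold 1), top-peak spectral regions, and
  standardized (mean-0, SD-1) coefficient profiles.
- **Descriptive analyses**: trait summary statistics (min/max/mean/median/
  sample SD/CV%), per-wavelength Pearson correlation spectra with exact
  *t*-test significance masking (α = 0.01), trait cross-correlation
  matrices, wet-basis moisture content `(WW − DW)/WW × 100`.
- **A synthetic leaf-spectra generator** with known latent structure:
  a realistic green-leaf base spectrum, a configurable number of latent
  chemical factors that modulate Gaussian absorption features, traits that
  are exact affine functions of the factors plus relative noise, and
  additive spectral noise — so every stage of the pipeline can be tested
  against planted ground truth.

## Worked example

```python
import leafspec as ls

cfg = ls.SyntheticConfig(n_samples=360, step_nm=10.0, seed=7)
spectra, traits, truth = ls.generate_dataset(cfg)
spectra = ls.trim_spectra(spectra)            # 450-2400 nm modeling range

print(ls.trait_stats(traits).round(2))

y = traits.trait("MC").to_numpy()             # wet-basis moisture content
curve = ls.run_cv(spectra.reflectance, y,
                  ls.CVConfig(n_iterations=50, max_components=10, seed=1))
for rule in (ls.select_press_min(curve),
             ls.select_backward_penalty(curve),
             ls.select_voet(curve, seed=1)):
    print(f"{rule.method:>9}: A={rule.n_components}  val R2={rule.val_r2:.3f} "
          f"val RPD={rule.val_rpd:.2f} ({rule.rpd_class})")

model = ls.fit_simpls(spectra.reflectance, y, 2, wavelengths=spectra.wavelengths)
print("top VIP regions (nm):", ls.top_peak_regions(ls.vip_scores(model), k=3))
```

prints

```
           min      max     mean   median       sd  cv_percent
trait
N         2.10     5.04     3.57     3.58     0.53       14.93
Ca     1550.19  9746.30  6118.54  6143.90  1339.85       21.90
Mg      192.61  4138.97  2319.53  2294.98   558.83       24.09
Fe       37.48   142.27    91.89    91.74    18.42       20.05
MC       59.49    77.75    68.72    68.77     3.48        5.07
press_min: A=3  val R2=0.997 val RPD=17.32 (excellent)
press_adj: A=2  val R2=0.996 val RPD=17.13 (excellent)
     voet: A=3  val R2=0.997 val RPD=17.32 (excellent)
top VIP regions (nm): [(2075.0, 2125.0)]
```

The trait table mimics wheat-like foliar chemistry (CVs between ~5% and
~25%). The backward-penalty rule trades a 0.001 loss in validation R² for a
simpler two-component model, while the minimum-PRESS and randomization
rules keep three. The moisture trait was planted on the latent factor whose
absorption feature sits at 2,100 nm, and the VIP profile points exactly
there — on real spectra this is how important water- or pigment-related
wavebands are located.

The same analyses are available from the shell:

```bash
leafspec simulate --seed 7 --out run/
leafspec stats --traits run/traits.csv --out run/stats.csv
leafspec correlate --spectra run/spectra.csv --traits run/traits.csv --out run/
leafspec fit --spectra run/spectra.csv --traits run/traits.csv \
             --method all --iterations 50 --max-components 10 --seed 1 --out run/
leafspec report --run-dir run/ --out run/summary.csv
```

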