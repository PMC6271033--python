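# hsiauth

Short-wave-infrared (SWIR, 920–2514 nm) hyperspectral-imaging chemometrics
for authenticating herbal raw material, built around the *Echinacea* use
case: telling *E. angustifolia*, *E. purpurea* and *E. pallida* powders
apart, and screening commercial products for the species they actually
contain.

The package is aimed at chemometricians and QC analysts who want a fully
scripted, reproducible version of the classic imaging workflow that is
usually driven interactively in commercial software:

1. **ENVI I/O and calibration** — read/write ENVI header/data pairs
   (BIL/BIP/BSQ), convert raw counts to reflectance against internal dark
   and white references, `R = (raw − D̄)/(W̄ − D̄)`, then to pseudo-absorbance
   `A = log₁₀(1/R)`.
2. **Automated masking** — background (the stage) is removed with a
   one-component PCA plus an Otsu threshold on the PC1 score histogram;
   dead pixels by per-pixel variance; edge effects by binary erosion.
3. **Spectral pretreatment** — wavelength cropping (bands ≤ 996 nm are
   noise-dominated and dropped), SNV or MSC scatter correction,
   Savitzky–Golay derivatives, mean centering — with fitted state stored so
   prediction pixels get exactly the calibration treatment.
4. **NIPALS PCA** — score images, loadings line plots, per-component and
   cumulative explained variance R²X, and cross-validated component-count
   selection.
5. **PLS-DA** — NIPALS PLS2 against a one-hot class matrix, 7 random
   cross-validation segments giving `Q²Y_cum = 1 − PRESS/SS`, factor count
   chosen by marginal Q²Y gain, pixel classification through the dummy-Y
   cut-off window `[0.5, 1.5]` with "no class" for pixels matching no
   species, and per-sample composition tables.
6. **Synthetic scenes** — no public hypercubes of authenticated *Echinacea*
   powders exist, so a seeded generator renders ENVI scenes with full ground
   truth (stylized endmembers, multiplicative scatter + baseline + white
   noise, known references) that the whole pipeline is tested against.

## Worked example

One command simulates the two study scenes (18 authentic wells; 20 products
plus 4 controls), trains on a stratified half of the authentic wells and
quantifies the product scene:

```sh
hsiauth replicate --seed 1 --out run/
```

Training output (`run/train/factor_table.csv`): two PLS factors are kept,
with cross-validation tracking the fitted Y-variance almost exactly —

```
factor,r2x_cum,r2y_cum,q2y_cum
1,0.6037,0.4925,0.4925
2,0.8687,0.9825,0.9824
```

All 9 held-out authentic wells are assigned the correct species (per-pixel
accuracy 1.00), and the PC1 loadings localize the discriminating chemistry
to 1995–2289 nm. The composition report (`run/predict/composition_report.csv`)
begins:

```
    region           label_claim  pct_angustifolia  pct_pallida  pct_purpurea  pct_no_class  dominant      verdict
product-01 purpurea+angustifolia              10.0          0.0          90.0           0.0  purpurea        match
product-02          angustifolia               0.0          0.0           0.0         100.0  no_class  no_authentic_material
product-03              purpurea              86.8          0.0          13.2           0.0  angustifolia mismatch
```

Read these rows as a QC analyst would: product 1 is a genuine two-species
blend dominated by *E. purpurea*; product 2, sold as *E. angustifolia*
extract, contains no pixel resembling authentic raw material ("no class" —
processing destroyed the native chemistry); product 3 is mislabeled — the
powder is *E. angustifolia*, not the claimed *E. purpurea*. Percentages per
row sum to 100 over kept (non-background) pixels.

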