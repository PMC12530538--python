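# morphspec

Visual-ecology toolkit for asking whether discrete animal colour variants
("morphs") are distinguishable — to the animals themselves and to their
predators — from reflectance spectrometry data. It was built around the
classic three-morph (orange / white / yellow) throat polymorphism of wall
lizards, but every visual system, illuminant and group structure is
configurable.

The pipeline goes from raw replicate reflectance measurements to
receptor-noise-limited (RNL) discriminability:

1. **Spectral processing** — restrict to 300–700 nm on a 1 nm grid, average
   the replicate measurements per individual, smooth with a local quadratic
   (loess-style) regression at span 0.2, and verify non-negativity.
2. **Colorimetrics** — brightness (mean reflectance R̄), chroma
   ((R_max − R_min)/R̄) and hue (λ at mid-reflectance), summarised by
   morph × sex.
3. **Visual modelling** — quantum catches Q_i = Σ_λ R(λ) I(λ) S_i(λ) for
   each receptor channel of a configured visual system (pigment-template
   sensitivities S_i, cone abundances η_i, Weber fractions ω) under a
   chosen illuminant I (bundled CIE D65 and a parametric forest shade).
4. **Discriminability** — chromatic contrast ΔS and achromatic contrast
   ΔL in just-noticeable-difference (JND) units from the receptor-noise
   model with channel noise e_i = ω·√(η_ref/η_i); tetrahedral colour-space
   coordinates from relative catches.
5. **Inference** — bootstrap CIs for JND distances between morph
   centroids, distance-based pairwise PERMANOVA (999 permutations,
   Bonferroni adjustment) and a multivariate dispersion check.

Three visual systems ship as editable YAML configs: a tetrachromatic
lizard (cone ratio 1:1:1:4, ω_LW = 0.05), a violet-sensitive raptor
(1:2:2:4, ω = 0.10) and a colubrid snake (1:1:1:4, ω = 0.05). A synthetic
study generator reproduces the structure of a real field dataset — 102
individuals (52M:50F) across the three morphs, six replicate spectra
each, long-wavelength cut-ons for orange/yellow, a high flat white, and a
UV reflectance spike near 370 nm in a subset of white and orange
individuals — so the entire pipeline is testable with no downloads.

## Worked example

```python
import morphspec as ms

cfg = ms.default_study_config(seed=1)          # 102 individuals x 6 replicates
spectra, meta = ms.generate_dataset(cfg)
model = ms.ReceptorNoiseModel.from_raw(spectra, meta, "lizard", "d65")
print(model.fit(n_boot=1000, n_perm=999, seed=1).summary())
```

```text
Receptor-noise-limited discrimination results
=============================================
visual system: lizard   illuminant: d65
individuals: 102   channels: 4
seed: 1   bootstrap B: 1000   permutations: 999

Group distances (JND, 95% percentile CI)
---------------------------------------------
    orange-white  chromatic  20.810 [20.550, 21.076] ***
    orange-white achromatic   3.656 [ 2.921,  4.404] ***
   orange-yellow  chromatic   7.984 [ 7.595,  8.327] ***
   orange-yellow achromatic   3.823 [ 3.184,  4.453] ***
    white-yellow  chromatic  15.766 [15.437, 16.097] ***
    white-yellow achromatic   0.167 [ 0.011,  1.051]

Pairwise PERMANOVA (Bonferroni-adjusted p)
---------------------------------------------
    orange-white  chromatic df=1 SS=6959.7400 F= 6434.621 R2=0.9895 p(adj)= 0.003
   orange-yellow  chromatic df=1 SS=1191.9519 F=  974.044 R2=0.9285 p(adj)= 0.003
    white-yellow  chromatic df=1 SS=3488.7406 F= 3565.376 R2=0.9848 p(adj)= 0.003
    orange-white achromatic df=1 SS=214.8736 F=   84.550 R2=0.5542 p(adj)= 0.003
   orange-yellow achromatic df=1 SS=273.3580 F=  133.673 R2=0.6406 p(adj)= 0.003
    white-yellow achromatic df=1 SS=  0.3902 F=    0.188 R2=0.0034 p(adj)= 1.000

Dispersion (Levene analogue): chromatic F=3.218 p=0.041; achromatic F=1.350 p=0.252
(* > 1 JND threshold, *** >= 3 JND easily discriminable)
```

Reading it: every morph pair is chromatically far above the 1 JND
discrimination threshold for the lizard eye under daylight (orange–white
most of all), and the white–yellow pair is achromatically
indistinguishable (ΔL ≈ 0.17 JND, PERMANOVA p(adj) = 1.0) — the morphs
differ in colour, not in brightness, for that pair. The dispersion test
reports whether groups differ in multivariate spread, a PERMANOVA
assumption worth checking before reading its p-values.

The same analysis runs from the shell across the full 3 visual systems ×
2 illuminants grid:

```bash
morphspec simulate --seed 1 --out sim/
morphspec run-all --simulate --seed 1 --out results/full/
morphspec run-all --spectra sim/spectra.csv --meta sim/metadata.csv \
    --vision lizard --illum d65 --seed 1 --out results/lizard_d65/
```

Outputs are plain CSV tables: group colorimetrics, per-configuration
quantum catches, ΔS/ΔL distance matrices, tetrahedral coordinates,
bootstrap distances with CIs, and PERMANOVA tables, plus a JSON run log
with seeds and a content hash.

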