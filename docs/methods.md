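# Methods

## The discrimination model

The package implements the receptor-noise-limited (RNL) model of colour
discrimination. A stimulus with reflectance R(λ), viewed under ambient
irradiance I(λ) by a receptor class with spectral sensitivity S_i(λ),
produces a quantum catch

    Q_i = Σ_λ R(λ) I(λ) S_i(λ)      (unit-step Riemann sum, 1 nm grid)

and a Weber–Fechner signal f_i = ln Q_i. The perceptual distance between
two stimuli is limited by channel noise

    e_i = ω_ref · √(η_ref / η_i)

where η_i are relative cone abundances and ω_ref the Weber fraction of
the reference (long-wavelength) cone, so the stated Weber fraction holds
exactly for the LW channel and rarer cones are noisier. For a
tetrachromat, with Δf_i the per-channel signal differences,

    ΔS = √(N / D)
    N  = e₁²e₂²(Δf₄−Δf₃)² + e₁²e₃²(Δf₄−Δf₂)² + e₁²e₄²(Δf₃−Δf₂)²
       + e₂²e₃²(Δf₄−Δf₁)² + e₂²e₄²(Δf₃−Δf₁)² + e₃²e₄²(Δf₂−Δf₁)²
    D  = (e₁e₂e₃)² + (e₁e₂e₄)² + (e₁e₃e₄)² + (e₂e₃e₄)²

in JND units. The n-channel generalisation (each numerator term weighted
by the product of the squared noises of the *other* channels) is the
implementation; the code also carries an algebraically independent
Mahalanobis form — the norm of Δf under covariance diag(e_i²) restricted
to the hyperplane orthogonal to uniform intensity shifts — used in tests
to cross-check the closed form. Achromatic contrast uses a single
luminance channel: ΔL = |Δf_A| / ω_A.

Consequences asserted as properties: ΔS and ΔL are invariant to the
illuminant's overall scale and to per-receptor gain factors (a von Kries
transform is therefore irrelevant to distances, though it would move
points in colour space); ΔS is a metric; a pure intensity change has
ΔS = 0. Thresholds of 1 JND ("just discriminable") and 3 JND ("easily
discriminable even in poor light") are reporting flags only.

Receptor sensitivities come from the A1 visual-pigment nomogram
(Govardovskii-type α band plus standard β band) evaluated at configured
peak wavelengths and area-normalised; because every curve integrates
to 1, a flat stimulus under a flat illuminant yields Q_i = 1 in all
channels. Catches for colour-space plotting use relative values
q_i = Q_i/ΣQ mapped into the standard tetrahedron (UV apex at
(0, 0, 0.75), achromatic point at the origin); distances use raw catches.

## Visual systems and illuminants

Three observer configurations ship as editable YAML:

| system | λmax (nm) | η | ω_ref | achromatic |
|--------|-----------|---|-------|------------|
| lizard | 367, 456, 497, 562 | 1:1:1:4 | 0.05 | LW, ω = 0.05 |
| bird (VS raptor) | 405, 450, 504, 567 | 1:2:2:4 | 0.10 | LW, ω = 0.10 |
| snake (colubrid) | 360, 458, 482, 554 | 1:1:1:4 | 0.05 | LW, ω = 0.05 |

The abundance ratios and Weber fractions are the study design's fixed
quantities; the peak wavelengths are transcriptions from the source
literature for each taxon and are deliberately config-level, not
hard-coded. The snake deserves a caveat: the garter-snake literature
documents three cone pigments (≈360/482/554 nm). The shipped config adds
an interpolated blue-sensitive channel at 458 nm so the snake occupies
the same tetrahedral space as the other observers; the distance code
accepts any channel count, so deleting that channel yields a literal
trichromat snake. The achromatic channel uses the LW sensitivity curve as
a stand-in for double-cone luminance perception. No ocular-media
transmission is applied by default; a per-system transmission hook
exists.

Illuminants: the bundled CIE standard D65 table (300–700 nm, 5 nm steps,
interpolated) converted from energy to relative quanta (I·λ, unit mean) —
the units flag prevents double conversion; and a parametric forest shade,
a broad Gaussian at 550 nm (σ = 60 nm) plus a logistic far-red rise at
680 nm (scale 8 nm, weight 0.5), capturing the yellow-green peak and
sharp far-red increase characteristic of canopy shade. Measured
irradiance files can be substituted for either. Absolute illuminant scale
cancels in all JNDs.

## Spectral processing

Processing order is restrict (300–700 nm, linear interpolation onto the
integer grid) → replicate averaging (pointwise mean per individual) →
smoothing → non-negativity check. Averaging before smoothing is the
default; the reverse order is a flag. The smoother is a tricube-weighted
local *quadratic* regression with span interpreted as the fraction of
grid points per window (span 0.2 ≈ 80 of 401 points), implemented as a
precomputed hat matrix per (grid size, span) — it reproduces constants
and straight lines exactly and never changes the grid. Exact numerical
agreement with other ecosystems' loess variants is not promised; the
package's tolerances absorb sub-percent smoother differences. Negative
reflectance is an error by default (`clip_zero` is available for foreign
data, with the clip count reported).

Colorimetrics: brightness is the arithmetic mean of R over the grid;
chroma (R_max − R_min)/brightness; hue the grid wavelength closest to
(R_max + R_min)/2, ties toward the shorter wavelength, flagged when the
mid-level is crossed more than once (UV-spiked spectra). Group tables
report mean brightness/chroma across individuals and the hue of the
group-mean spectrum (printed convention); the mean of per-individual hues
is emitted alongside.

## Group inference

*Bootstrap distances.* The point estimate for a morph pair is the RNL
distance between group centroids, a centroid being the per-channel mean
of log catches (mean of raw catches is a flag). Each of B = 1000
replicates resamples individuals with replacement within each group;
the CI is the 2.5/97.5 percentile interval. Centroid distances are not
means of pairwise distances — with heavy within-group overlap the
centroid distance can sit near zero while all pairwise distances are
positive.

*PERMANOVA.* SS_total = (1/N)Σ_{i<j} d²_ij, SS_within the analogous
per-group sum, pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)),
R² = SS_between/SS_total. p-values come from free permutation of labels
with the +1 convention, p = (1+#{F* ≥ F})/(1+n_perm), n_perm = 999 by
default; an exact enumeration mode exists for small N and is tested
against an independent enumeration. Pairwise comparisons run one
PERMANOVA per morph pair with a Bonferroni multiplier equal to the number
of pairs within one system × illuminant × channel block. On
Euclidean-embeddable distances the SS decomposition equals the
coordinate-space one-way decomposition, which the tests assert to 1e-9.

*Dispersion check.* Classical metric scaling of the distance matrix
(negative eigenvalues truncated with a warning), distances to own-group
centroids, one-way ANOVA F with a permutation p — the multivariate
Levene analogue. It is reported alongside PERMANOVA and never triggers
any automatic transformation: unequal dispersions are the analyst's call.

All Monte-Carlo results carry their seed and replicate count; per-cell
seeds in the full grid are spawned deterministically from the one run
seed, so a bundle is bit-reproducible (content hash in the run log).

## The synthetic study

The generator emulates a 102-individual field study (23/22 orange M/F,
13/12 white, 16/16 yellow; six replicate spectra each). A morph's latent
spectrum is baseline + amplitude·logistic((λ−centre)/steepness), plus a
Gaussian UV spike at 370 nm (width 12 nm) drawn per individual with
morph-specific probability (0.4 of white, ~0.09 of orange, matching the
observed subsets); replicates add iid Gaussian noise (sd 1.5%) clipped at
zero. Between-individual variation enters through the cut-on centre
(sd 4–5 nm) and amplitude (sd 5–6%). Default centres/levels were chosen
once so that processed group hues land near the published pattern —
orange ≈ 540 nm, yellow ≈ 502 nm, white rising near 410 nm with the
highest brightness floor and lowest chroma. One scalar
(`separation_scale`) moves the orange and yellow cut-ons toward or away
from white for sensitivity analyses; the orange–yellow pair isolates
cut-on separation (same shape family), and its bootstrap ΔS responds
monotonically to it, whereas pairs involving white confound cut-on
position with baseline level.

What the generator does *not* emulate: pigment-specific spectral
curvature (real carotenoid/pterin spectra are not logistic), correlated
measurement error across wavelengths, sex differences within morphs, and
realistic within-group overlap in colour space — synthetic groups are
cleaner than field data, so synthetic effect sizes (R² ≈ 0.9+) run much
higher than a field study's. Passing tests therefore demonstrate the
correctness and determinism of the machinery, not field-realistic effect
magnitudes. Re-analysis of a real deposited archive is wired through
`morphspec.replication.replicate_study`, which expects the archive
exported to two CSVs and applies the study's processing settings.

## Numerical choices and limits

- Linear interpolation onto the 1 nm grid; integration as plain sums.
- Pigment templates are peak-normalised then area-normalised; the curve
  maximum can sit 1–2 nm from the nominal λmax after β-band addition.
- Hue ties break toward shorter wavelengths; constant spectra have
  undefined hue and chroma requires positive brightness.
- Zero quantum catch is an error naming the individual and channel (log
  signals would diverge); reflectance can legitimately be zero at some
  wavelengths as long as a channel's band integral stays positive.
- Degenerate PERMANOVA (SS_within = 0) reports an infinite F with a
  permutation p; the dispersion F treats numerically-zero scatter as 0.
- Problem sizes used in tests and the acceptance script are the full
  default design (102 individuals, 6 replicates, B = 1000, 999
  permutations), which completes in seconds on one CPU.
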