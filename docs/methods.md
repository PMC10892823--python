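# Methods

## Design arithmetic

The design enumerates, per protein matrix (whey, beef, pea), all 15
non-empty subsets of the four adulterants at six melamine-equivalent dose
levels (0.5–3 %w/w in 0.5 steps) plus an unadulterated control, in
triplicate: (15 × 6 + 1) × 3 = 273 samples per protein, 819 total.

Dosing follows nitrogen equivalence. The added nitrogen at level ℓ is
`N_tot = 0.5·ℓ × 0.6660` g per 100 g (what pure melamine at that %w/w
carries), split *equally* among the mixture's members:
`massᵢ = (N_tot/|combo|)/wN,i`. Equal splitting is the unique rule that
reproduces all eight per-adulterant concentration endpoints
(melamine 0.125–3, urea 0.179–4.286, glycine 0.446–10.714, taurine
0.744–17.857 g/100 g) simultaneously. The "protein content" response is
defined as 100 − Σ adulterant fractions (g/100 g). Controls (level 0) are
kept in both the LDA grouping (seven classes, levels 0–6) and the PLSR
calibration; excluding them from regression is possible by subsetting but
is not the default, since blanks anchor the zero-analyte end of the
calibration and make the extrapolated leverages well defined.

## Spectra simulator

Spectra are synthesised by Beer–Lambert linear mixing: each component has
a fixed non-negative absorbance profile per unit mass fraction on a
400–2500 nm master grid (0.5 nm step), built as a sum of Gaussian bands,
and a sample's noiseless spectrum is the mass-fraction-weighted profile
sum. Band centers follow the compounds' characteristic NIR features
(melamine 1480 nm; urea 1490, 1530, 1980 nm; taurine 1660/1700/1740 and
1200 nm; glycine broad, weak bands near 1200/1570/2120 nm — deliberately
the least distinct adulterant). Band widths and heights are the package's
own choices, set so that the lowest designed melamine dose (0.125 g/100 g)
contributes only a few times the benchtop noise floor — detection-limit
estimates are then non-trivial rather than vacuous. The three protein
matrices share broad N–H (1400–1600 nm), water (~1940 nm) and combination
(>2000 nm) bands with per-protein coefficients and small center shifts so
the types separate in PCA score space.

Acquisition interpolates the master spectrum onto the instrument grid and
injects, per scan: a multiplicative scatter factor 1 + N(0, 0.02), an
additive baseline `offset + slope·(λ−λmin)/1000`, and i.i.d. N(0, noise_sd)
noise, clamped at zero absorbance. Defaults: noise_sd 0.001 AU for the
benchtops, 0.003 AU for the handheld arms; baseline offset 0.15 AU for
the handheld glass-cuvette arm and 0.04 AU for the plastic-bag arm
(non-contact optics shift the cuvette baseline most — the reason
baseline-correcting pretreatments are always candidates for handheld
data). The five instrument grids are: 400–2498 nm/2 nm (1050 points),
740–1700 nm/2 nm, 4000–12000 cm⁻¹/8 cm⁻¹ (1001 points, stored on the
nm-converted non-uniform grid), and 900–1700 nm/3 nm for the two handheld
arms. Triplicate scans are averaged by default before modeling; the
replicate structure that drives cross-validation is the *preparation*
triplicate, not the scan triplicate.

What the simulator does not emulate: radiative-transfer/particle-size
effects beyond a scalar scatter factor, wavelength-calibration drift,
temperature/moisture effects, band non-linearities at high doses, or
inter-batch matrix variability. Passing tests therefore demonstrate that
the pipeline's algebra and selection logic are correct and that recovery
works under the designed concentration structure — not that any particular
real instrument attains the simulated figures of merit.

## Pretreatments

Operators act row-wise and compose left-to-right in a chain
(`"RANGE(1100,2200)+SG(15,2,0)+SNV"`). Savitzky–Golay uses a 2nd-order
local polynomial with odd windows 5–41; derivatives are scaled by the
grid step. Edges are trimmed, not padded — (window−1)/2 points per side —
so regression vectors never include fabricated boundary values. SNV
standardises each spectrum to mean 0, sample (n−1) SD 1; MSC regresses
each spectrum on the column-mean reference and inverts the fitted affine
transform; detrending subtracts a per-row polynomial (degree 2 default)
in a scaled wavelength basis for conditioning. Range restriction keeps a
closed interval and linearly resamples non-uniform (FT) grids to 2 nm.
The per-arm modeling ranges default to 1100–2200 nm (grating benchtop),
1400–2200 nm (FT) and 950–1650 nm (the 740–1700 nm benchtop and both
handheld arms). The table label "SC", which appears in published
pretreatment lists without a definition, is accepted as an alias for
smoothing-only SG and flagged in the log rather than silently guessed.

## PCA, LDA, PLSR

PCA is mean-centered SVD with a deterministic sign convention (largest
loading element positive). Classification is a pooled-within-class
covariance linear discriminant on the leading PCA scores (15 by default);
the within-class scatter is refused if near-singular (condition > 1e12)
with advice to lower the score count. Cross-validation everywhere is
leave-one-replicate-out: three deterministic folds by preparation index,
so every sample is used for both training and prediction across the
rotation, and all CV numbers are exactly reproducible.

PLSR is single-response NIPALS with deflation (tolerance 1e-10, ≤500
inner iterations per component; with one response the inner loop
converges immediately). The regression vector is b = W(PᵀW)⁻¹q;
R² is defined as 1 − SSE/SST (not a squared correlation), with SST about
the grand response mean for CV and about the test-set mean for test-set
prediction. The test-set split designates one replicate (the third by
default) as an external set. Model optimisation is an exhaustive grid
over pretreatment chains × latent variables (1–10 by default) minimising
RMSECV, with ties broken toward fewer latent variables, then earlier
candidate order; per-fold fits are reused across latent-variable counts
since NIPALS components are nested. Pretreatment chains are applied to
the full sub-dataset before fold splitting; all chain operators except
MSC are row-independent, and MSC's column-mean reference introduces only
a negligible coupling at these sample sizes.

## Detection limits

For a fitted model, SEN = 1/‖b‖₂; var(y_cal) is the (n−1) variance of the
calibration concentrations; h0 leverages come from extrapolating each
calibration score vector to zero analyte concentration by removing its
concentration-correlated component (per-column regression of scores on
the raw concentrations, slope s = Tᵀy/yᵀy), then evaluating the quadratic
form with (TᵀT)⁻¹. The implemented interval is

LOD(h0) = 3.3·[(1+h0)·SEN⁻²·var(x) + h0·var(y_cal)]^½, LOQ = 3·LOD,

evaluated at the extreme leverages. var(x), the instrumental signal
variance, has two estimators: the default uses the mean squared element
of the X-residual after the retained latent variables; the alternative
pools replicate-to-replicate spectral variance within (protein, combo,
level) groups. The residual default is preferred because it is defined
for any calibration (including scan-averaged data where replicate
residuals absorb preparation error, not just instrumental noise). A
rank-deficient score Gram matrix falls back to the pseudo-inverse, which
handles the degenerate case of scores exactly proportional to the
response (all extrapolated scores zero).

## Study orchestration and problem sizes

The default study runs 5 arms × 3 proteins × 5 responses = 75 optimized
PLSR models and 15 LDA models. The default search grid is deliberately
compact — three chain families (SG+SNV, SG+detrend, SG 2nd derivative) ×
10 latent variables — which the synthetic data does not penalise; the
wider 36-chain family spanning window sizes 5–41 is available as
`WIDE_CHAINS`. Test-set prediction is added for the best benchtop and the
handheld plastic-bag arm by default. All randomness flows from a single
config seed through per-arm child seeds, making full runs byte-identical.

## Known limitations

- The simulator's figure-of-merit orderings across arms depend on the
  invented artifact parameters; only the qualitative structure (benchtop
  noise < handheld; cuvette baseline > bag) is designed in.
- PLS1 only; multi-response PLS2 and non-linear models are out of scope.
- MSC uses a dataset-dependent reference, so strict train/test separation
  of the reference is not enforced in CV.
- LDA accuracy is sample-weighted; per-class rates are available from the
  confusion matrices but are not averaged into the headline percentage.
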