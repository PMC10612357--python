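# Methods

This note documents the models, numerical choices and limitations behind
kinstab's analysis stages, and what the synthetic-data generator does and
does not emulate.

## Spectroscopic observables

The intensity-averaged emission wavelength is the intensity-weighted mean
λ̄ = Σ(I_i·λ_i)/Σ(I_i). A variant of this formula sometimes appears in the
literature with the intensities divided by wavelength, Σ(I_i/λ_i)/Σ(I_i);
that form is dimensionally a reciprocal wavelength and cannot yield the
nanometre-scale values the quantity is reported in, so kinstab implements
the conventional weighted mean, which is scale-invariant in the
intensities and bounded by the wavelength range.

Mean residue ellipticity uses [Θ] = θ·MRW/(10·l·c) with θ in millidegrees,
path length l in cm, concentration c in mg/mL and a default mean residue
mass MRW = 110 g/mol (overridable). Concentrations from A280 use
Beer–Lambert with the protein's molar absorptivity and molecular mass
(44,810 M⁻¹cm⁻¹ / 41.477 kDa for MAPK1; 43,320 / 43.222 kDa for MAPK3).

### SVD component counting

A spectral series is decomposed as a wavelength × condition matrix. Two
rank policies are available:

* **threshold** (default): retain components whose singular value exceeds
  5× the median of the trailing half of the singular spectrum. The
  trailing median estimates the noise floor; a relative floor of 1e-8·s₁
  guards the noiseless case where that median underflows.
* **autocorrelation**: retain leading components whose left and right
  singular vectors have successive-pair correlation ≥ 0.8. Signal vectors
  are smooth; noise vectors are not. The correlation is computed on
  mean-centred successive pairs, which is unbiased for the short
  condition-direction vectors.

Denoising is rank truncation; no other smoothing of individual spectra is
applied. Whether denoising precedes transition-curve fitting or SVD is
used only for component counting is left to the caller — both orders are
expressible, since `svd_analyze` returns the denoised series alongside the
rank.

## Equilibrium unfolding

The two-state linear extrapolation model is parameterised as
ΔG([D]) = ΔG_H₂O − m·[D], K = exp(−ΔG/RT), with R = 1.987×10⁻³
kcal·mol⁻¹·K⁻¹ and a default fit temperature of 283.15 K. This sign
convention makes the midpoint identity [D]₀.₅ = ΔG_H₂O/m hold exactly; the
identity is enforced structurally (the midpoint is always computed from the
fitted ΔG and m, never fitted separately). One sometimes sees the
exponent written with +m[D] alongside the same midpoint formula; that
combination is internally inconsistent, and the convention used here is
the one that reproduces the reported midpoints.

Initialisation: baselines from linear fits to the outer 15% of points;
the midpoint from the extremum of a lightly smoothed first derivative; m
started at 1.5 kcal/mol/M with bounds (0, 20]. A fit whose midpoint falls
outside the measured denaturant range is rejected as an unbracketed
transition. Several series can be fitted globally with one shared m (the
usual treatment of replicates of one probe); all other parameters remain
per-series.

The three-state model N ⇌ I ⇌ U evaluates

    F = (F_N + e₁·(F_I + F_U·e₂)) / (1 + e₁·(1 + e₂))

with e₁ = exp(m_IN([D] − D50_IN)/RT), e₂ = exp(m_UI([D] − D50_UI)/RT),
linear N/U baselines and constant F_I. The second midpoint is
parameterised as D50_IN plus a nonnegative increment so the transitions
stay ordered; m values start at 2.0 kcal/mol/M and the two midpoint
guesses come from the two strongest derivative peaks (or a split of the
range when only one is visible). Exponent magnitudes stay below ~285 for
m ≤ 20 and [D] ≤ 8 M, inside double range, so no rescaling is needed.

Model selection compares corrected AIC (6 vs 9 parameters); ΔAICc < 2
prefers the two-state model (parsimony), and an SVD component count ≥ 3
overrides in favour of three states.

**Precision limits.** At the package's default noise (2% of signal span)
and a 30-point 0–8 M series, the Cramér–Rao bound on sd(ΔG_H₂O) at
wild-type-like parameters (ΔG ≈ 2.5, m ≈ 0.9) is ≈ 0.30 kcal/mol for any
unbiased estimator; Monte-Carlo sd of the fit is ≈ 0.29 with negligible
bias, i.e. the estimator is essentially efficient. Published standard
errors of ~0.2 kcal/mol for such data therefore reflect averaged
triplicates and/or lower effective noise; a single 2%-noise series cannot
determine ΔG more tightly than the bound, and the test suite asserts
efficiency against the bound rather than an absolute error. For sharp
transitions (m ≳ 2 kcal/mol/M) the 0.28 M grid spacing under-samples the
transition (width ≈ RT/m) and recovery degrades accordingly.

## Thermal melts

Scans are normalised to their span (making Tm extraction invariant to
affine transformations of the signal), smoothed with a moving polynomial
(Savitzky–Golay, default window 2.5 °C, order 2), differentiated on the
grid, and all derivative peaks with prominence ≥ 10% of the global
derivative maximum and width ≥ half the smoothing window are reported,
ascending, with parabolic interpolation to 0.1 °C. The width criterion
rejects narrow noise spikes whose prominence can pass the threshold at 2%
channel noise; at that noise level minor spurious peaks may still appear,
so `TmResult.principal` (the most prominent peak) is the headline Tm and
is what the pipeline records. For noisy data raise the prominence or
widen the window.

Transitions of these kinases are irreversible on rescan, so only apparent
melting temperatures are reported — no ΔH_vH or two-state thermal
thermodynamics.

## Enzyme kinetics

Initial rates: the fit window is the earliest span with t ≤ 60 s and
product ≤ 10% of substrate (the assay's linear-phase assumption for 5-min
traces); if a quadratic term contributes more than 15% of the signal
change the window shrinks, and a curve with no ≥ 3-point linear window is
rejected. Slopes are converted to µM/s through the instrument calibration
(AU per µM phosphopeptide), which is an explicit input — it is
instrument-specific and must accompany the data.

Michaelis–Menten fits are nonlinear least squares of v = Vmax·S/(Km+S);
kcat = Vmax/[E] (enzyme in µM; the nM → µM factor 10⁻³ is applied once,
here) and kcat/Km are derived identities, exact on every fit object.

Tmax is taken from the measured temperature grid, no interpolation; ties
resolve to the lower temperature and edge maxima are warned about. The
Arrhenius fit k = A·exp(−Ea/RT) is nonlinear on the original rate scale,
initialised from the closed-form log-linear fit (which is retained as a
cross-check); it refuses points above Tmax rather than silently fitting
them, because enzyme inactivation breaks the Arrhenius law there.

## Synthetic data

Generators evaluate the corresponding forward model on realistic
instrument grids (denaturant 0–8 M in 0.25 M steps; melts 20–90 °C every
0.5 °C; 5-min progress curves; substrate 0.069–40 µM at 10 log-spaced
concentrations; assay temperatures 10–45 °C) and add homoscedastic
Gaussian noise, default σ = 2% of the noiseless signal span per channel.
Default truths are the wild-type study conditions: ΔG_H₂O = 2.51 kcal/mol,
m = 0.91 kcal/mol/M (midpoint 2.76 M); Tm = 55 °C; Km = 1.81 µM,
Vmax = 1.10×10⁻² µM/s at 5 nM enzyme; Ea = 9.95 kcal/mol, Tmax = 30 °C.
Every generator returns its truth record, and identical seeds give
byte-identical output.

Progress curves integrate substrate depletion dS/dt = −Vmax·S/(Km+S)
(stiffly-accurate ODE integration at rtol 1e-10). The temperature-activity
profile follows the Arrhenius law exactly up to Tmax and then declines by
a logistic inactivation factor; the super-Tmax branch is a non-physical
fixture whose only purpose is to give the activity curve an interior
maximum for Tmax detection.

What the generators do **not** emulate: heteroscedastic or correlated
instrument noise, baseline drift, photomultiplier saturation, near-UV CD
band shapes, and enzyme inactivation kinetics. Passing round-trip tests
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every instrument artefact.

## Pipeline and reproducibility

The `run` pipeline derives one sub-seed per sample and channel from the
top-level seed, writes all fit records as JSON with sorted keys, CSVs at
full float precision (`%.17g`, so write-then-read is identity), and a run
log capturing package versions, the seed and every configured threshold —
sufficient to re-execute a run byte-identically. Configuration is one
YAML file with per-stage sections; unknown keys are rejected and CLI flags
take precedence over the file.

## Known limitations

* Group classification ships as a data table keyed by (protein,
  substitution); structural inference of CD-site interaction is out of
  scope, as are pathogenicity prediction and any molecular-dynamics
  analysis.
* Tertiary-change and three-state flags in the comparison ledger are
  recorded judgments from upstream analyses, not inferred by the
  reporter.
* No stopped-flow (kinetic) folding analysis, no Gibbs–Helmholtz
  temperature extrapolation of ΔG, and no bi-substrate (ATP-dependence)
  kinetics — ATP is assumed saturating.
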