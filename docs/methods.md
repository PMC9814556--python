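# Methods

## Data model

A full-spectrum chromatogram is an absorbance surface A(t, λ) on a strictly
increasing time axis (minutes) and wavelength axis (nm). The physical model
throughout is Beer–Lambert bilinearity: for k species,

    A = C · Sᵀ + baseline + ε,

where column j of C (time × k) is the species' concentration profile — a
Gaussian centred at its retention time Rtⱼ with width σⱼ, normalised to unit
area and scaled by an injected amount with AU·min semantics, so peak area is
the quantitative readout as in LC practice — and column j of S
(wavelength × k) is its absorption spectrum. ε is iid Gaussian noise;
baseline drift is linear in time and constant across wavelength (the
simplest structure the first-derivative preprocessing must cancel).

Default grids are deliberately coarse — Δλ = 1 nm over 200–450 nm,
Δt = 0.005 min — so every stage runs in seconds on one CPU; the simulation
config accepts full instrument resolution (Δλ = 0.217 nm over 180–890 nm)
when fidelity matters more than speed. All quantitative behaviour exercised
by the tests (cluster counts, recovery r², classification rates) is
grid-coarseness-insensitive because the underlying spectra are smooth on
the 3–20 nm band-width scale.

## Synthetic data: what it emulates and what it does not

`make_synthetic_spectrum` builds species spectra as sums of Gaussian
absorption bands with centres in 200–450 nm (where PAH-like analytes are
active) and widths 3–20 nm, unit-max normalised. Library replicates emulate
reference spectra of the same compound measured on different instruments:
additive noise plus a ≤ 0.5 nm wavelength registration shift.

The canned co-elution scenarios encode specific chromatographic situations:

* **Three-species hidden peak.** A broad middle peak (σ = 0.12 min) exactly
  between two narrow neighbours (σ = 0.06 min) spaced 1.2·σ away. The
  middle species never exceeds a 0.9 fractional contribution at any
  timepoint and produces no apex on the detection channel — it is hidden in
  the strict sense that no pure spectrum of it is ever observable. The
  three species share a spectral backbone (isomer-like family resemblance),
  as co-eluting congeners of equal molecular weight do in practice.
* **Five-species near-coelution.** Three resolved but partially overlapping
  peaks plus a nearly coincident pair (ΔRt = 0.3·σ of the broader member)
  under a single apex: a narrow, locally dominant member riding on a
  broader partner.

These width and similarity structures are not decoration — they are what
makes the species countable. Unit-norm timepoint spectra trace a curve on
the unit sphere; clusters form only where the mixture *composition* is
locally stationary. Equal-width, equal-amount Gaussians at hidden-peak
spacing produce a uniform-density arc with no interior clump, and no
cluster-counting method based on within-cluster variance can report the
hidden species from such data. A broad species between narrow neighbours
produces a composition plateau (a middle density clump); family-correlated
flanker spectra keep the swap of one contaminant for the other from
rotating the spectral direction during that plateau. The scenarios were
validated to give stable counts across 12 noise seeds and independent
K-means seeds.

The generator does **not** model lamp pulse noise, shot noise,
wavelength-correlated detector noise, flow-rate jitter, asymmetric
(tailing) peaks or photodegradation. Passing tests therefore demonstrate
the correctness of the algorithms under the stated statistical structure,
not robustness to every instrument artefact.

## Species counting

Spectra from a congested window are row-filtered (total absorbance ≥ 10% of
the window's largest row total — near-baseline rows have noise-dominated
directions), scaled to unit Euclidean norm so concentration magnitude does
not drive clustering, and embedded by mean-centred PCA. Counting uses 4
components by default: two suffice for visualisation but provably cannot
separate five nearly orthogonal spectral directions. K-means runs for
k = 1…8 (10 restarts, seeded); the count maximises the discrete second
difference wcss(k−1) − 2·wcss(k) + wcss(k+1), ties broken toward smaller k.
If the total direction variance is below 5% of the row count — an order of
magnitude above the measured single-species level at 1% noise, an order of
magnitude below congested-window levels — the window is declared
single-species outright, since second differences of a pure-noise WCSS
curve are meaningless.

## Elution modelling

"Gaussian mixture" fitting here is penalised nonlinear least squares on the
elution curve, not expectation–maximisation on samples: the data are
curves, not draws. Amplitudes are bounded non-negative, σ to
[Δt, window/2], retention times to the window. The shared-Rt fit holds
(Rtⱼ, σⱼ) common across a small set of informative channels (five evenly
spaced in 230–330 nm plus any channel where one component carries > 80% of
the fitted signal) with free per-channel amplitudes, then freezes (Rt, σ)
and refits amplitudes at every wavelength by non-negative least squares —
yielding each component's amplitude spectrum and unit-area concentration
profiles.

The retention-time-consistency diagnostic fits k components independently
per channel: for a true k-species window the Rts agree across wavelengths;
a spread above 0.2·σ̂ flags an under-counted window. The default tolerance
avoids false alarms at 1% noise while firing reliably when k is one short.

Initial retention times for a deconvolution fit come from the visible
apexes; missing components are hypothesised first at the midpoints of the
widest inter-apex gaps (a species buried between neighbours), then stacked
onto apexes with a small stagger (a coincident pair).

## Peak detection

The baseline is the median of the lowest decile of the channel; apex
heights and the 10%-of-apex flank rule use baseline-subtracted absorbance,
making detection invariant to constant offsets. Noise is estimated as
1.4826 × MAD of the successive differences divided by √2 — differencing
removes smooth structure including the peaks themselves, which
median-filter detrending does not (it leaves peak flanks in the residual
and overestimates noise several-fold on peak-dense traces). Candidate
maxima must clear both an apex SNR of 8 and a prominence of 8 × noise; the
prominence gate rejects noise wiggles riding on a real peak's flank, and 8σ
(rather than a conventional 3–5σ) accounts for extreme-value statistics
over several thousand samples plus the low bias of the decile baseline.
Flank times are found by walking outward from the apex with linear
interpolation between samples.

## MCR-AR

Alternating regression is implemented as alternating non-negative least
squares: solve C given S (per time row), then S given C (per wavelength),
tracking lack of fit = 100·√(Σresid²/ΣD²), which is monotone non-increasing
because each half-step is an exact constrained least-squares solve. The
factorisation's scale ambiguity is fixed by unit-max spectra columns
(scale pushed into C); permutation ambiguity by correlation-matched
assignment to the initial estimates (Hungarian algorithm). Convergence is
declared on the relative change of lack of fit (< 1e-8) rather than on
parameters, which the scale fixing would perturb. An optional unimodality
projection (monotone clipping away from the apex) is available for C
columns but off by default — Gaussian elution makes it redundant when the
flank initialisation is sound.

Initial spectra follow the flank rule: the first component's estimate is
the chromatogram row where its fitted profile has risen to 10% of apex, the
last component's the row at its trailing 10% time, and interior (hidden)
components' the rows at their fitted Rt — the timepoints that minimise
neighbour contamination in each case.

## Curve similarity

r² is the squared Pearson correlation of absorbances aligned on the overlap
of the two supports (the first curve's grid points, the second interpolated
onto them; missing-support positions are excluded pairwise, never
zero-filled). The discrete Fréchet distance is computed by the standard
dynamic programme after mapping wavelength to [0, 1] over the common
support and scaling each curve to unit maximum: reported distances are
dimensionless shape distances and their absolute values depend on this
normalisation convention.

## Fingerprint classification

Features: resample to the 200–450 nm common grid (1 nm default) →
Savitzky–Golay (order 5, ±4.5 nm) → first derivative (cancels constant
offsets) → zero-impute outside the spectrum's support only *after*
differentiation (so imputation adds no spurious derivative structure) →
unit-norm (cancels positive scale). Spectra covering under half the window
are rejected.

With at most a handful of spectra per class, per-pixel features vastly
outnumber samples, so features are projected onto at most
(n_samples − n_classes) principal components before a linear discriminant
with Ledoit–Wolf shrinkage of the shared covariance. Shrinkage is not
optional polish: the unshrunk discriminant is frequently *confidently
wrong* on held-out replicates (posterior ≈ 1 for a class whose curve
similarity to the query is near zero), which silently bypasses the
tiebreak. When every class has only one spectrum even shrinkage LDA is
undefined (no within-class scatter); the model then degrades to a nearest-
centroid discriminant whose distance-softmax posteriors are deliberately
diffuse, routing every decision through the tiebreak — the right behaviour
for a one-shot library.

Classification: if the top posterior is below 0.95 or the top-two margin
below 0.25, the top three candidates are compared to the query by r² on
smoothed, *non-derivative* absorbance curves (similarity judgements are
made on the curves a chemist would inspect, not on derivatives) and the
best mean r² wins. The thresholds are set so that clean single-species
queries at 1% noise never tiebreak. Reported leave-one-out accuracy uses
the full classifier including the tiebreak.

## Pipeline

Peaks whose 10%-extent intervals overlap are grouped into regions (this
automates the by-inspection window bounds a chemist would draw). A region
is deconvolved when the clustered species count exceeds its visible apex
count or the Rt-consistency diagnostic flags inconsistency; otherwise each
peak is classified from its apex-timepoint spectrum. Any region whose
analysis fails is emitted as a single "unresolved" row; the run always
completes. All randomness (noise, K-means restarts) flows from one run
seed, so fixed seed + fixed inputs ⇒ identical peak table.

## Numerical choices and degenerate inputs

* Non-finite cells in any loaded object are a hard error, never imputed.
* Chromatogram CSV round-trips are exact to ≤ 1e-9 AU (values printed with
  12 significant digits; wavelength headers with 6).
* The Gaussian-sum optimiser reports non-convergence as a flag on the fit,
  not an exception; per-channel diagnostic fits that fail are excluded and
  listed.
* NNLS subproblems are solved exactly (active set); k above the rank bound
  min(n_t, n_λ) is rejected.
* Ties in the elbow's second difference resolve toward smaller k
  (parsimony); component order everywhere is by retention time except MCR
  output, which follows the initial-estimate order.

## Problem sizes

The test suite and the acceptance script run the scenarios at the default
coarse grids: congested windows of ~300–450 timepoints × 251 wavelengths,
20 replicate deconvolutions for the recovery statistics, 24-class libraries
of 72 spectra. These sizes were chosen as the smallest at which the
quantitative behaviour is stable replicate-to-replicate.

## Known limitations

* Symmetric Gaussian elution only; exponentially modified (tailing) peaks
  are out of scope and would bias flank times and the 10% rule.
* The elbow criterion reports the dominant kink of the WCSS curve; graded
  cluster structures (e.g. a weakly split pair among strongly split
  singles) can under-count, which is precisely why the Rt-consistency
  diagnostic exists as a second, independent trigger.
* Fréchet distances are convention-dependent (see above) and should be
  compared only within one normalisation convention.
* The classifier assumes query spectra cover at least half of the common
  window; heavily truncated spectra are rejected rather than guessed at.
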