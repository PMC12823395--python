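# Methods

This note records the models, conventions and numerical choices behind
`amide1`, and what the synthetic data do and do not establish.

## Spectral model and grid

All analysis happens on the amide I window, 1,600–1,700 cm⁻¹, sampled
uniformly at 2 cm⁻¹ (51 points). Grids are stored ascending regardless of
acquisition order; plots may reverse the axis, but derivatives, integrals
and band windows always use the ascending convention, which removes a
whole class of sign errors. Intensities are kept in their native units
(optoacoustic mV, or unitless after normalization) and are never
converted implicitly; each `Spectrum` carries a `stage` tag
(`raw / smoothed / baselined / normalized / second_derivative`).

A cell spectrum is modeled as a non-negative mixture of five component
spectra:

| component | shape | role |
|---|---|---|
| medium | Gaussian, 1,646 cm⁻¹, FWHM 45 | D₂O cell-medium band, dominant background |
| α-helix | Gaussians 1,650 (FWHM 18) + 0.6 × 1,656 (FWHM 16) | native helical protein |
| turns | Gaussian 1,666, FWHM 18 | turn/loop content |
| intermolecular β-sheet | Gaussian 1,620 (FWHM 14) + 0.35 × 1,682 (FWHM 12) | misfolded-aggregate marker doublet |
| laser profile | smooth cubic polynomial | slowly varying source-power envelope |

Line shapes default to Gaussian (standard amide I practice); Lorentzian
and pseudo-Voigt profiles are available in `BandSpec`. The 1,682:1,620
amplitude ratio of the marker doublet defaults to 0.35 — the high-
frequency partner is known to be the weaker of the pair, and the exact
ratio is a free fixture parameter.

## Synthetic cohorts

`CohortDesign` fixes the study conditions. Defaults: 50 cells per arm,
time points 0/72/78/96 h, responder fraction 0.64, plus 40 pure-medium
measurement points (background positions in the dish — real spectral
datasets of this kind contain them, and they anchor the medium and laser
components during unmixing).

Dynamics:

- **Responders** (a planted `⌊p·n⌋` subset of the treated arm) grow the
  β-sheet doublet linearly at `beta_growth` = 0.0028 amplitude/h on top
  of a basal β amplitude of 0.10.
- **All treated cells** lose α-helix and turn amplitude as
  `exp(−rate·t)` with a shared rate of 0.01/h, corresponding to the
  ~50 % decline of the helical unmixing component observed over 72 h of
  combined treatment in patient cells. The two features share one rate:
  they decline together in measured data, and a single "unfolding/H→D
  exchange" rate is the parsimonious model.
- **Untreated cells are spectrally stationary** apart from noise — in
  measured data untreated cells show no spectral changes over time.
  Consequently the two arms are statistically identical only when the
  decay rates are zero; a refractory (p = 0) treated cohort still shows
  the mild helix decline, which is what drives its response percentage
  to ~0 rather than ~50 % (see below).

Cell-to-cell variability is a mean-one lognormal amplitude jitter per
component (relative sd 0.10). At a cell location the medium contributes
only `cell_medium_frac` = 0.5 of its background amplitude (partial
volume) so cell spectra are protein-dominated, as intracellular spectra
are. Additive i.i.d. Gaussian noise defaults to sd 0.01 of the medium
peak — the instrument resolves ~1 % signal changes. Negative intensities
are clipped at zero (a warning fires if >5 % of points clip).

The generator is strictly reproducible: one root seed spawns a child
stream per cell, so individual records are stable under design changes
that do not touch the cell count.

What the synthetic cohorts do **not** emulate: correlated (pink)
instrument noise, wavenumber calibration drift, scattering baselines,
cell movement between time points, and any true biological heterogeneity
beyond amplitude jitter and the responder/non-responder dichotomy.
Passing tests on this generator show the chain recovers what it assumes
— an identifiable non-negative mixture with the planted dynamics — not
that it is robust to every artifact of real measurements.

## Preprocessing

Default conditioning order: optional buffer division → Savitzky–Golay
(window 19, polyorder 5) → baseline → min–max normalization. Buffer
division runs only when an independently measured reference is supplied;
the cell-medium spectrum is reserved for the medium fit. The baseline is
the straight line through the means of the three lowest- and three
highest-wavenumber points — the minimal assumption on a 100 cm⁻¹ window
(idempotent; maps exactly-linear spectra to zero). Min–max normalization
rejects numerically constant spectra (span ≤ 1e-12 relative).

Second derivatives use Savitzky–Golay window 9 / polyorder 3 with
respect to wavenumber (units per cm⁻²), optionally after ×4 cubic-spline
upsampling; absorption maxima appear as second-derivative minima, and
edge windows use polynomial fits on the truncated window so polynomials
up to the filter order are reproduced exactly everywhere.

The medium fit is scale-only, `c = Σ(s·m)/Σ(m·m)`; offsets belong to the
baseline stage. Its residual is orthogonal to the medium by
construction.

## Response classification

The response score of a cell is the signed trapezoidal AUC of its
differential spectrum over the closed band 1,638–1,615 cm⁻¹ intersected
with the native grid (12 points, 1,616–1,638; no resampling — the score
is resolution-honest). The classification threshold is the mean AUC of
untreated cells at 0 h, computed leave-one-out (each 0 h cell against the
mean of the remaining 0 h cells) so it reflects the null dispersion
rather than a trivial self-difference. A cell is responsive iff its AUC
strictly exceeds the threshold; ties are unresponsive.

Two deliberate choices differ from the obvious alternatives:

1. **Per-cell pairing.** The default differential pairs each cell at
   `t_cmp` with *its own* spectrum at `t_ref` (`reference="self"`), which
   cancels the cell's static amplitude structure (medium path, total
   protein content) exactly. With a cohort-mean reference
   (`reference="mean"`, also available), symmetric cell-to-cell
   amplitude variation alone places ~half of all null cells above a
   near-zero threshold, so a fully refractory cohort would read ~50 %
   response instead of the ~0 % such cohorts actually show.
2. **Scoring on baselined, non-normalized spectra, without the medium
   fit.** Both the per-spectrum 0–1 rescale and the scale-only medium
   fit couple treatment-induced α-helix loss into the β window with
   *positive* sign (the rescale because the spectrum's range shrinks;
   the fit because the fitted scale drops while the broad medium band
   has substantial mass inside 1,638–1,615). Either would inflate null
   AUCs systematically. The medium fit remains implemented and tested
   (`use_medium_fit=True`) for designs where cells cannot be paired and
   the medium contribution varies per measurement.

Under these conventions responders score strongly positive (β growth),
treated null cells slightly negative (helix decline), untreated nulls
symmetric about the threshold — so the estimated percentage response
tracks the planted responder fraction, refractory cohorts read ≈0 %, and
an untreated arm reads ≈50 % at the threshold's own time point, decaying
toward 0 with any negative drift. Statistical inference across patients
(paired t-tests on percentages) is a standard test left to statsmodels/
scipy and is not re-implemented here.

## Regularized NMF

The objective is applied exactly as written — L1 and Frobenius penalties
with weights αρ and ½α(1−ρ) on both factors, **no division by matrix
size** (library dialects differ here; the objective oracle in the test
suite pins this contract). The solver is block coordinate descent
(HALS): each W column and H row is updated by its closed-form
non-negative minimizer, so the recorded objective trace is non-increasing
by construction and matches an independent evaluation of the objective
to 1e-9 relative. Convergence is declared when the relative per-iteration
decrease falls below `tol` (default 10⁻⁵), else the result returns
`converged=False` at `max_iter` (default 2,000).

Initialization is NNDSVD with zeros kept as zeros (no mean filling) —
fully deterministic; a seeded random init is available. The W/H scale
indeterminacy is resolved for reporting by max-normalizing H rows and
rescaling W columns (`NMFResult.normalized()`); labeling is invariant to
this.

Component order after a fit is arbitrary, so all reporting goes through
`label_components`: a component peaking in 1,615–1,625 cm⁻¹ with a
secondary local maximum in 1,672–1,694 cm⁻¹ (≥10 % of its peak) is the
intermolecular β-sheet doublet; near-flat components
(peak/median < 1.5) are background/medium-or-laser; anything else takes
the band-table label(s) of its peak position. A broad medium band
peaking at 1,646 cm⁻¹ falls in the α-helix window and is labeled as
such — spectral shape alone cannot distinguish it from helical protein,
a known ambiguity.

The L-curve procedure fits the NMF over a log-spaced α grid (per ρ),
plots log residual against log penalty, and selects the point of maximum
discrete (Menger) curvature; ρ is swept secondarily. Default grids:
α ∈ 10⁻⁴…10⁰, ρ ∈ 10⁻⁴…10⁻¹. The t-SNE embedding of W (perplexity 30,
seeded, PCA init) is for visualization only.

PCA dimensionality: cumulative explained variance of the mean-centered
matrix; the default k is the smallest number of components reaching
99.97 %. On default-noise synthetic cohorts five components capture
~99.86 % (the rule then asks for more, as noise is white); at the
low-noise end (sd 0.001) five components exceed 99.99 % and the rule
returns ≤5, matching the planted rank.

## Micrograph metrics

CNR = |OA_S − OA_ref| / Noise_PkPk, NOA = |OA − OA_ref| / OA_ref along a
Bresenham line, with OA_ref the lowest-contrast background value. CNR is
invariant to a global intensity offset; NOA is invariant to global
positive scaling (neither is invariant to the other transformation —
both properties are tested). The peak-to-peak noise over a background
ROI (≥25 px) uses the 0.5–99.5 percentile span by default — it tracks
the true peak-to-peak of uniform noise to within a few percent while
resisting outliers; the literal max − min is available
(`robust=False`). Whether peak-to-peak noise is temporal or spatial is a
convention; the spatial-ROI reading is adopted.

## Orchestration and determinism

`run_pipeline` executes simulate → preprocess → unmix → classify with a
single global seed fanned out per stage (stage name CRC-mixed into the
seed, kept below 2³¹), writes every artifact with a SHA-256 manifest,
and is bit-reproducible for a fixed config. The unmixing stage consumes
normalized spectra; the classification stage consumes baselined spectra
(see above). Configs are validated strictly — unknown keys abort before
any compute.

## Problem sizes

Test-suite and acceptance runs use the study-scale defaults: 2 × 50-cell
arms × 4 time points (+40 medium points) for unmixing, 500 treated cells
for responder-fraction recovery, and 250 × 250 px micrographs
(62,500 px, 2 µm pixels). The full suite runs in a few seconds on one
CPU.

## Known limitations

- NMF identifiability is geometric, not guaranteed: with five heavily
  overlapping bands the fitted β-sheet component typically matches the
  planted doublet at cosine ≈ 0.96–0.97, but occasional cohort draws
  dip below 0.95.
- The band-window dictionary overlaps by construction (turns vs α-helix
  and high-β); peak assignment returns all containing labels rather than
  forcing a partition, and cross-cell peak matching by label is only
  meaningful for the narrow windows.
- The albumin-denaturation marker at 1,612 cm⁻¹ lies outside both the
  response band and the default dictionary; it is representable via a
  custom `BandRange`.
- The classifier assumes cells are trackable across time points; for
  unpaired designs the mean-reference mode applies, with the caveats
  above.
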