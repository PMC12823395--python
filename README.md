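# amide1

Analysis pipeline for **live-cell amide I (1,700–1,600 cm⁻¹) mid-infrared
optoacoustic spectroscopy**, built around a single-cell drug-response
readout for proteasome-inhibitor therapy in multiple myeloma.

Proteasome inhibition makes misfolded proteins accumulate in responding
tumour cells. Misfolded aggregates are rich in **intermolecular β-sheets**,
which absorb at ~1,620 cm⁻¹ (with a weaker partner band at ~1,682 cm⁻¹)
inside the amide I window — a label-free spectroscopic biomarker of
drug-induced apoptosis. This package turns per-cell amide I spectra into
that readout:

- **`amide1.io`** — spectra tables (CSV/TSV, long or wide), TIFF
  micrographs with YAML sidecars, JSON results; everything lives on the
  canonical 1,600–1,700 cm⁻¹ grid at 2 cm⁻¹ (51 points).
- **`amide1.synthetic`** — cohort and micrograph generator with full
  ground truth (planted band structure, responder subpopulation,
  treatment dynamics, noise), so the whole chain runs with no instrument.
- **`amide1.preprocess`** — buffer division, Savitzky–Golay smoothing
  (19/5) and second derivatives, linear-endpoint baseline correction,
  0–1 normalization, scale-only least-squares medium fit.
- **`amide1.bands`** — amide I band dictionary (α-helix 1,642–1,660;
  β-sheet 1,615–1,638 and 1,672–1,694; turns 1,653–1,691; the 1,620
  aggregation marker) and second-derivative peak assignment.
- **`amide1.respond`** — differential spectra; the signed trapezoidal
  **AUC over 1,638–1,615 cm⁻¹** per cell; the responsive/unresponsive
  classifier thresholded at the mean AUC of untreated cells at 0 h
  (ties → unresponsive); cohort percentage response.
- **`amide1.decompose`** — regularized NMF `X ≈ WH` solved by
  block-coordinate descent (HALS) under

  ```
  ½‖X − WH‖²_F + αρ(‖W‖₁ + ‖H‖₁) + ½α(1−ρ)(‖W‖²_F + ‖H‖²_F)
  ```

  with deterministic NNDSVD initialization (defaults k=5, α=10⁻²,
  ρ=10⁻³, tol=10⁻⁵, max 2,000 iterations), PCA dimensionality estimate,
  L-curve hyperparameter selection, component labeling, coefficient
  time-evolution statistics, and t-SNE embedding of the coefficients.
- **`amide1.imaging`** — micrograph metrics
  `CNR = |OA_S − OA_ref| / Noise_PkPk` and the normalized contrast
  profile `NOA = |OA − OA_ref| / OA_ref`, with robust background-noise
  estimation.
- **`amide1.pipeline` / `amide1 <subcommand>`** — end-to-end orchestration
  with a single fan-out seed and a checksummed run manifest; CLI
  subcommands `simulate | preprocess | bands | decompose | respond |
  imstats | run`.

## Worked example

Score a synthetic patient-like cohort (50 treated + 50 untreated cells,
64 % planted responders, measured at 0, 48 and 72 h) and unmix it:

```python
from amide1.synthetic import CohortDesign, simulate_cohort
from amide1.preprocess import preprocess_pipeline, PreprocessConfig
from amide1.respond import assess_response
from amide1.decompose import (fit_regularized_nmf, NMFConfig,
                              label_components, component_evolution)

design = CohortDesign(n_cells=50, time_points_h=(0.0, 48.0, 72.0),
                      responder_fraction=0.64, seed=7)
dataset, truth = simulate_cohort(design)

scored = preprocess_pipeline(dataset,
                             PreprocessConfig(stages=("savgol", "baseline")))
calls, summary, threshold = assess_response(scored, t_ref=0.0, t_cmp=72.0)
print(f"{summary.n_responsive}/{len(calls)} cells responsive "
      f"({summary.percent:.1f}%), AUC threshold {threshold:.3f}")

unmix = preprocess_pipeline(dataset)   # adds 0-1 normalization
result = fit_regularized_nmf(unmix.matrix(), NMFConfig(k=5)).normalized()
result.labels = label_components(result.H, unmix.grid)
print("components:", result.labels)
evo = component_evolution(result, unmix)
beta = result.labels.index("intermolecular beta-sheet")
print(f"beta-sheet coefficient change (treated, 0->72 h): "
      f"{evo.percent_change(beta, 'treated', 0.0, 72.0):+.0f}%")
```

This prints:

```
32/50 cells responsive (64.0%), AUC threshold -0.000
components: ['alpha-helix', 'beta-sheet(low)', 'intermolecular beta-sheet', 'turns', 'unassigned']
beta-sheet coefficient change (treated, 0->72 h): +913%
```

Reading: 32 of the 50 treated cells developed the 1,620 cm⁻¹ band above
the untreated-cohort threshold (64 % response — the planted fraction),
the unmixing isolates the intermolecular β-sheet doublet as one of its
five components, and that component's coefficient grows strongly in the
treated arm only.

The same run from a shell:

```sh
amide1 run --seed 7 --out runs/demo     # full chain + manifest.json
```

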