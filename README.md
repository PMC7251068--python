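# tauspread

Network-diffusion modeling of tau pathology spread through brain
connectomes, with mixture-model calibration of tau-PET signal and a fully
synthetic cohort generator with known ground truth.

Tau neurofibrillary tangles accumulate in a stereotyped order across the
brain (entorhinal cortex → limbic cortex → association isocortex → primary
sensory cortex), and a leading hypothesis holds that pathological tau
propagates from neuron to neuron along anatomical connections.  `tauspread`
implements the computational machinery for testing this hypothesis with
regional tau-PET data:

- **Tau-positive probabilities.**  Regional SUVR values mix true tau signal
  with off-target ligand binding.  Per region, one- and two-component
  Gaussian mixtures are fit across the population and compared by AIC;
  where the two-component model wins, each subject's SUVR is mapped to the
  posterior probability of the upper (abnormal) component, evaluated
  out-of-fold under repeated five-fold cross-validation.  Alternatives
  (min–max scaling, reference-bootstrap ECDF) and confound handling
  (per-region residualization or W-scores for age, sex, choroid-plexus
  signal) are included.
- **The epidemic spreading model (ESM).**  Regional tau probability
  `X_i ∈ [0, 1]` evolves on a row-normalized connectome `Ĉ` as

  ```
  dX_i/dt = β (1 − X_i) Σ_j Ĉ_ij X_j − δ X_i
  ```

  seeded at an epicenter (default: bilateral entorhinal cortex, amplitude
  x₀ = 0.1).  β (production) and δ (clearance) are global per-subject rates
  (1/year) and the effective duration t_eff encodes age of onset; the three
  are fit per subject by exhaustive grid search minimizing the sum of
  squared errors between simulated and observed regional probabilities.
  Accuracy is the squared Pearson correlation (r²) between predicted and
  observed patterns, per subject and globally on subject-mean vectors.
- **Evaluation.**  Epicenter search over all 33 homotopic region pairs and
  per-subject best epicenters; significance against 100 degree- and
  strength-preserving null connectomes (one-sided exceedance p, floor
  0.01); regional model residuals versus regional amyloid burden (Welch
  t-test, Pearson correlation, OLS adjusting for regional tau); hemispheric
  asymmetry GLMs with Benjamini–Hochberg FDR; Braak-stage ROI summaries and
  nested threshold maps; greedy nearest-neighbor cohort matching.
- **Synthetic cohorts.**  The atlas (66 cortical / 78 total DKT-derived
  regions), connectomes, and subject cohorts are generated with known
  per-subject β, δ, t_eff and epicenters, so every stage is testable
  without access to restricted imaging data.

## Worked example

```python
import numpy as np
import tauspread as ts

regions = ts.build_region_table("cortical66", coordinate_seed=0)
connectome = ts.simulate_connectome(regions, density=0.10, seed=1)
cohort = ts.simulate_cohort(regions, connectome,
                            ts.recovery_benchmark_spec(n=50), seed=7)

fit = ts.fit_cohort(cohort.ground_truth.probabilities, connectome,
                    ["L_entorhinal", "R_entorhinal"], ts.ParameterGrid.coarse())
print(f"global r2 = {fit.global_r2:.3f}")
print(f"mean within-subject r2 = {np.nanmean(fit.individual_r2):.3f}")

ranking = ts.epicenter_search(cohort.ground_truth.probabilities, connectome,
                              regions=regions, mode="homotopic_pairs")
print(ranking.head(3)[["left", "right", "global_r2"]].to_string(index=False))
```

prints

```
global r2 = 0.998
mean within-subject r2 = 0.811
             left             right  global_r2
     L_entorhinal      R_entorhinal   0.997726
L_parahippocampal R_parahippocampal   0.995814
       L_amygdala        R_amygdala   0.992555
```

The cohort was generated by spreading tau from a bilateral entorhinal seed;
the fit recovers 99.8% of the variance in the population-mean regional
pattern and 81% within subjects on average, and the epicenter search ranks
the true (entorhinal) pair first among all 33 homotopic pairs, ahead of its
medial temporal neighbors.

A command-line interface mirrors the library
(`tauspread simulate / transform / fit / epicenters / nulls / evaluate /
grid`); see `tauspread --help`.

## Limitations

Synthetic cohorts emulate the structure of real tau-PET studies (bimodal
regional SUVR with off-target background, confound effects,
connectome-constrained staged spread, amyloid-coupled tau excess,
lateralized epicenters) but not their full complexity; see
`docs/methods.md` for the generative model, parameter choices, and what
passing benchmarks do and do not establish about real data.
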