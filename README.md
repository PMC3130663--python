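# mrresponse

Early prediction of tumor treatment response from functional MRI biomarkers,
rebuilt as a fully simulated, testable pipeline.

## The problem

In a four-arm preclinical experiment, androgen-sensitive prostate-carcinoma
xenografts receive no treatment, a single 15 Gy radiotherapy dose (RT),
androgen deprivation by castration (ADT), or both. Each animal is imaged at
days 0, 1 and 9 with diffusion-weighted MRI (yielding the apparent diffusion
coefficient, ADC) and dynamic contrast-enhanced MRI (yielding the Tofts
transfer constant K<sup>trans</sup>), alongside caliper tumor volume V and
serum PSA. The question: do early changes in these functional biomarkers,
normalized to each animal's baseline, predict the day-30 tumor volume
(V<sub>30</sub>) — and does *combining* ADC and K<sup>trans</sup> predict it
better than either alone?

Because no such raw animal data are publicly available, this package
simulates the experiment end to end with known ground truth, so every stage
of the analysis chain is testable:

- **`mrresponse.synthetic`** — voxel-level DW signal stacks
  (S = S₀·e<sup>−b·ADC</sup>, b = 0/100 s/mm², 6 directions, Rician noise)
  and DCE concentration curves; an animal-level cohort generator whose
  day-30 group means/SDs are calibrated to +940 ± 91 % (control),
  +60 ± 25 % (RT), −40 ± 9 % (ADT) and −64 ± 5 % (ADT+RT), with a latent
  per-animal response structure linking early biomarker changes to outcome.
- **`mrresponse.dwi`** — voxel-wise isotropic ADC maps
  (ADC = ln(S₀/S)/b averaged over directions) and ROI means.
- **`mrresponse.dce`** — the Tofts model
  C<sub>t</sub>(t) = K<sup>trans</sup>·(C<sub>p</sub> ⊛ e<sup>−k<sub>ep</sub>t</sup>)
  with the biexponential vascular input function
  C<sub>p</sub>(t) = 3.57·e<sup>−0.025t</sup> + 1.45·e<sup>−0.0074t</sup> mM,
  closed-form forward model, convolution oracle, and bounded multi-start
  least-squares voxel fitting.
- **`mrresponse.bpnn`** — a from-scratch back-propagation network
  (6 tanh hidden units, summed-squared error E = ½Σ(y−O)², sequential
  gradient descent with η = 0.4 or scaled conjugate gradient) with
  validation-based early stopping and stratified 50/25/25 splitting.
- **`mrresponse.pipeline`** — baseline-normalized feature assembly, the three
  input-set experiments (ADC+V+PSA, K<sup>trans</sup>+V+PSA, all), Pearson
  evaluation of predicted vs. measured V<sub>30</sub>/V<sub>0</sub>, and a
  one-call study reproduction.

## Worked example

```python
import mrresponse as mr

cohort = mr.simulate_cohort(mr.GeneratorConfig(n_per_group=32, seed=3001))
for input_set in ("adc", "ktrans", "all"):
    res = mr.run_simulation(cohort, mr.SimulationSpec(input_set=input_set,
                                                      n_repeats=25, seed=1))
    print(f"{input_set:>7s}: median r = {res.median_r:.3f} "
          f"(IQR {res.iqr_r[0]:.3f}-{res.iqr_r[1]:.3f})")
```

```
    adc: median r = 0.997 (IQR 0.996-0.998)
 ktrans: median r = 0.998 (IQR 0.996-0.998)
    all: median r = 0.998 (IQR 0.997-0.999)
```

Each `r` is the Pearson correlation between the network's predicted and the
measured day-30 relative tumor volume on held-out test animals (32 of the
128 animals per split). The overall correlations are high because the four
treatment arms separate strongly; the added value of combining both imaging
biomarkers lies in the *within-group* response spread, where ADC and
K<sup>trans</sup> carry complementary latent information — across repeated
fresh cohorts the all-biomarker model beats each single-modality model in
the large majority of paired seeds (tested in the suite).

The same run from a shell:

```bash
mrresponse reproduce --seed 1 --repeats 25 --out run/
mrresponse simulate-cohort --seed 1 --out data/     # cohort.csv + sidecar
```

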