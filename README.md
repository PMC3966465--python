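# amfmtex

Despeckle filtering and multiscale AM-FM texture analysis for B-mode
ultrasound images of the carotid artery intima-media complex (IMC).

Ultrasound speckle is locally correlated multiplicative noise that corrupts
texture measurements of the IMC — the arterial wall band whose thickness and
texture change with age and cardiovascular risk. This package implements the
two halves of a texture pipeline for such images and the machinery to
evaluate them against ground truth:

* **Eight despeckle filters** (`amfmtex.despeckle`): local-statistics
  adaptive filters (`dsf_lsmv`, `dsf_wiener`), homogeneous-mask filters
  (`dsf_kuhawara`, `dsf_lsminsc`), order-statistic filters (`dsf_median`,
  `dsf_hybrid_median`) and anisotropic diffusion (`dsf_srad`, `dsf_nldif`),
  plus a log-domain speckle noise-variance estimator.
* **Multiscale AM-FM demodulation** (`amfmtex.amfm`): the image is modelled
  as a sum of components `a_n(x,y) cos(phi_n(x,y))`; per pixel and per
  frequency scale the instantaneous amplitude `IA = a_n` and instantaneous
  frequency `IF = grad(phi_n)` are estimated via a one-sided (extended
  Hilbert) spectrum, an annular-sector channel filterbank over three dyadic
  scales (low 1.04–2.95, medium 2.08–5.89, high 4.17–11.79 cycles/mm),
  dominant-channel selection, and a variable-spacing arccos phase-derivative
  estimator that is exact on pure cosines.
* **Texture features and statistics** (`amfmtex.features`): 32-bin IA/IF
  histograms, percentile summaries of per-image medians, and pairwise
  Mann-Whitney screening of image groups at P < 0.05.
* **Preprocessing** (`amfmtex.preprocess`): bicubic resampling to a standard
  16.66 pixels/mm, two-point linear intensity normalization against blood
  and adventitia reference levels, and fixed-length (160-px) ROI windows.
* **A synthetic carotid phantom and benchmark harness** (`amfmtex.phantom`,
  `amfmtex.evaluation`): a 1024×1024 chirped-FM phantom with three dark
  background bands and two bright narrow strips, known per-pixel IA/IF
  ground truth, and multiplicative uniform speckle (`g = f + n f`), used to
  score low-scale IF estimation error for every filter.

## Worked example

```python
import numpy as np
from amfmtex import (SpeckleSpec, add_speckle, demodulate, dsf_hybrid_median,
                     generate_phantom, run_synthetic_experiment)

truth = generate_phantom()                      # noise-free phantom + ground truth
noisy = add_speckle(truth, SpeckleSpec(variance=0.07, seed=0))
clean = dsf_hybrid_median(noisy)                # despeckle

res = demodulate(clean, scales=("low",))["low"]
bg = truth.masks["backgrounds"] & res.valid
print(f"median low-scale IFx over backgrounds: {np.median(res.ifx[bg]):.3f} rad/px")
print(f"generating band: [{np.pi/7.5:.3f}, {np.pi/4.5:.3f}] rad/px")

report = run_synthetic_experiment(filters=("lsmv", "hybridmedian", "kuhawara"))
print(report.table.to_string(float_format=lambda x: f"{x:.2e}"))
```

prints

```
median low-scale IFx over backgrounds: 0.557 rad/px
generating band: [0.419, 0.698] rad/px
              lifx_backgrounds  lifx_strips  lifx_combined  lify_backgrounds  lify_strips  lify_combined
noise-free            5.59e-04     1.77e-03       6.59e-04          2.56e-02     2.56e-03       2.37e-02
speckled              6.51e-04     1.83e-03       7.49e-04          2.57e-02     2.59e-03       2.38e-02
lsmv                  8.31e-04     2.88e-03       9.99e-04          2.57e-02     2.80e-03       2.39e-02
hybridmedian          6.43e-04     2.11e-03       7.63e-04          2.57e-02     2.64e-03       2.38e-02
kuhawara              7.05e-04     2.26e-03       8.34e-04          2.57e-02     2.66e-03       2.38e-02
```

Each cell is the mean squared error (rad/px)² of the low-scale IF component
(x or y) against the phantom's generating IF, over the background bands, the
bright strips, or their union — one row for the clean phantom (the estimation
floor), one for the speckled image, and one per despeckle filter applied to
it. The recovered median IFx sits inside the band that generated the texture.

The same pipeline is available from the shell:

```sh
amfmtex phantom --out-dir ph/
amfmtex despeckle --filter hybridmedian ph/phantom_speckled.tif clean.tif
amfmtex amfm clean.tif --out-dir amfm/
amfmtex table1 --filters lsmv,hybridmedian,kuhawara --out table1.csv
```

## Documentation

See `docs/methods.md` for the model, the numerical choices (filterbank
construction, padding conventions, validity masking, tie-breaks) and known
limitations.
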