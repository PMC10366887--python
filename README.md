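# pcctdenoise

Denoising and material decomposition for spectral photon-counting
micro-CT, on synthetic or real multi-energy volumes.

Photon-counting detectors acquire several energy-thresholded images in
one scan, enabling K-edge material decomposition of contrast agents —
but fast filtered-backprojection reconstructions of the photon-starved
energy bins are noisy (tens to hundreds of HU), and that noise is
amplified by the matrix inversion that produces material maps.  This
package implements a supervised denoising pipeline that estimates a
clean, iterative-reconstruction-like volume from the noisy one:

* an **invertible channel transform**: each energy channel is divided
  by its noise variance (estimated from the MAD of intensity gradients),
  the energy dimension is decorrelated by SVD (`A = U S V^T`), each
  left-singular-vector volume is high-pass filtered (37³ Gaussian,
  FWHM 10) and normalized by its absolute 99.95th percentile — and the
  whole map can be inverted exactly per axial slice;
* **2D U-net denoisers** written directly in NumPy (CPU, no deep-learning
  framework): a residual variant trained with MSE on attenuation
  slices, and a transform-domain variant with a Tanhshrink output
  (`x − tanh x`) trained with a four-term loss

  `L = ‖X−X_l‖²/N + λ₁‖U−U_l‖²/N + λ₂‖XM⁻¹−X_lM⁻¹‖²/N + ‖X_b−X_{b,l}‖²/N`

  that penalizes error simultaneously in the reconstruction, transform,
  material-decomposition and blurred-reconstruction domains
  (λ₁ = 15, λ₂ = 0.2, 19×19/FWHM-5 blur, sensitivity rows rescaled by
  calibration vial concentrations);
* image-domain **K-edge material decomposition** `C = X M⁻¹` with
  sensitivity-matrix calibration from vial ROIs and a non-negativity
  projection equal to the exhaustive subset-search optimum;
* a **multi-energy non-local means** baseline (11³ search window, 3³
  patches, h = 1.2, joint weights across energies, 31-slice stacks);
* a **synthetic phantom generator** producing paired clean/noisy
  spectral volumes of vial phantoms with realistic K-edge spectra and
  energy-dependent noise, so the whole pipeline is testable without
  scanner data.

Everything composes as scikit-learn-style estimators (`UTransform`,
`MaterialDecomposer`, `MultiEnergyNLM`, `UnetUDenoiser`,
`UnetWFBPDenoiser` with `fit`/`transform`/`get_params`), with plain
functions underneath. Volumes are `(energy, Z, Y, X)` arrays in 1/cm,
read and written as 4D NIfTI with a JSON sidecar for energy labels.

## Worked example

```python
import numpy as np
from pcctdenoise import (
    NoiseSpec, add_noise, build_sensitivity_matrix, compose_phantom,
    decompose_nonneg, random_phantom_spec, UnetUDenoiser,
)
from pcctdenoise.phantom_sim import generate_paired_volumes
from pcctdenoise.train_eval import material_rmse, rmse

M = build_sensitivity_matrix()           # water/I/Gd/Ca at 25/34/50/60 keV
M.vial_concentrations = {"water": 1.0, "iodine": 10.0,
                         "gadolinium": 10.0, "calcium": 10.0}

pairs = generate_paired_volumes(6, M=M, seed=1)   # (clean, noisy, maps)
clean = [c for c, _, _ in pairs]
noisy = [n for _, n, _ in pairs]

est = UnetUDenoiser(levels=3, base_filters=16, max_epochs=30, seed=1)
est.fit(noisy, clean, sensitivity=M)              # ~4 min on one core
i = est.validation_index_                         # held-out volume
denoised = est.transform(noisy[i])

print(rmse(noisy[i].data, clean[i].data))         # 0.0466  (1/cm)
print(rmse(denoised.data, clean[i].data))         # 0.0738  (1/cm)

ref = decompose_nonneg(clean[i], M)
for tag, vol in [("noisy", noisy[i]), ("denoised", denoised)]:
    print(tag, material_rmse(decompose_nonneg(vol, M), ref))
# noisy    {'water': 0.239, 'iodine': 0.438, 'gadolinium': 0.483, 'calcium': 5.51}
# denoised {'water': 0.163, 'iodine': 0.476, 'gadolinium': 0.607, 'calcium': 1.53}
```

At this deliberately small training budget (~900 optimizer steps) the
transform-domain network already improves the water and calcium maps by
large factors — calcium error drops from 5.5 to 1.5 mg/mL because the
decomposition's noise amplification is tamed — while its raw
reconstruction RMSE still trails the noisy input: a from-scratch
Tanhshrink network needs far more steps to reproduce the
signal-dominant SVD components (see `docs/methods.md` for the
analysis).  The residual MSE variant (`UnetWFBPDenoiser`), which starts
at the identity map, converges much faster at this scale.

The same pipeline is scriptable from the shell:

```bash
pcctdenoise simulate --out data/ --n-volumes 6 --seed 1
pcctdenoise train --data data/ --model unetu.pkl --variant unetu --max-epochs 30
pcctdenoise denoise --model unetu.pkl --in data/vol005_noisy.nii.gz --out d.nii.gz
pcctdenoise decompose --volume d.nii.gz --sensitivity M.json --nonneg --out maps/
pcctdenoise evaluate --in d.nii.gz --reference data/vol005_clean.nii.gz --out report.json
```

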