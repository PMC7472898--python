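# tvdmri

Simulation and analysis of tensor-valued diffusion MRI for separating
white-matter damage from fibre orientation dispersion.

## The problem

Fractional anisotropy (FA) from diffusion tensor imaging is the
workhorse metric for white-matter integrity, but it conflates two
different tissue properties: the *microscopic* anisotropy of axonal
microdomains and the *mesoscopic* dispersion of their orientations.
Since most white-matter voxels contain crossing or fanning fibres, FA
can drop without any damage — or rise when one bundle of a crossing
pair degenerates. Tensor-valued diffusion encoding resolves this at
acquisition time: combining conventional linear tensor encoding (LTE)
with spherical tensor encoding (STE, an isotropic b-tensor) yields a
microscopic fractional anisotropy (μFA) that is unaffected by
orientation dispersion.

This package is aimed at researchers evaluating μFA pipelines for
neuroinflammatory disease (e.g. multiple sclerosis) cohorts. It
provides:

* **encoding** — b-tensor and protocol construction (LTE/STE shells,
  electrostatically repulsed directions, FSL-style `bval`/`bvec` +
  shape sidecar and JSON serialisation);
* **phantom** — voxel environments built from axisymmetric
  microdomains (straight, crossing, Watson-fanning, degenerated,
  lesion), 3-D phantoms with ROI/lesion masks, noiseless signal
  simulation `S = s0 Σ f_i exp(-B:D_i)` and Rician noise;
* **dti** — `DiffusionTensorModel` / `DiffusionTensorResults`:
  weighted log-linear tensor fit on the b=0 + b=1000 shells, FA/MD
  maps;
* **gamma** — `GammaDecayModel` / `GammaDecayResults`: smoothing,
  powder averaging, joint gamma-decay fit to the LTE/STE series
  (`E(b) = s0 (1 + b μ₂/MD)^(−MD²/μ₂)`, shared `s0` and `MD`), and

      μFA = √(3/2) · (1 + (2/5)(MD² + μ₂^STE)/Δμ₂)^(−1/2),
      Δμ₂ = μ₂^LTE − μ₂^STE;

* **cohort** — synthetic subject cohorts (27 HC / 26 RRMS / 14 PPMS by
  default) with a latent damage score coupled to age, lesion load,
  EDSS and SDMT;
* **stats** — mask erosion, ROI means, group histograms, FA-threshold
  analysis, hemisphere × group repeated-measures ANOVA with age/sex
  covariates, Pearson/Spearman/partial correlations, Bonferroni
  correction;
* **io / cli** — NIfTI + sidecar readers/writers, a serialisable run
  configuration, the end-to-end pipeline, and a `tvdmri` command-line
  tool (`simulate-cohort`, `simulate-phantom`, `fit-dti`, `fit-ufa`,
  `roi-stats`, `run-all`).

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from tvdmri import (
    tensor_valued_protocol, multishell_protocol, canonical_environment,
    Phantom, simulate_signal, fit_dti, ufa_map,
)

# one voxel per environment: straight, crossing, fanning
grid = np.empty((3, 1, 1), dtype=object)
for i, lab in enumerate("ABC"):
    grid[i, 0, 0] = canonical_environment(lab, seed=11)
phantom = Phantom(grid)

fa = fit_dti(simulate_signal(phantom, multishell_protocol(seed=7))).fa
ufa, qc = ufa_map(simulate_signal(phantom, tensor_valued_protocol(seed=7)),
                  fwhm_mm=0.0)
for i, lab in enumerate("ABC"):
    print(f"{lab}: FA = {fa[i,0,0]:.3f}   uFA = {ufa.data[i,0,0]:.3f}")
```

```
A: FA = 0.870   uFA = 0.890
B: FA = 0.502   uFA = 0.888
C: FA = 0.567   uFA = 0.889
```

All three voxels are built from identical microdomains (FA of a single
domain: 0.870). Crossing (B) and fanning (C) sharply lower the
conventional FA, while μFA stays put for all three — the dispersion insensitivity that
makes μFA a cleaner damage marker. (μFA reads ≈0.89 rather than 0.870
because the gamma representation of the powder decay carries a small
known bias, measured in the test suite.)

A full synthetic cohort study — simulate subjects, fit both maps per
subject, run the group ANOVA and clinical correlations:

```sh
tvdmri run-all --seed 1 --out results/demo
```

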