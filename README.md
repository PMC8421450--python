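# radfit

Functional 4-D clustering of dynamic PET for characterizing kinetic
intratumor heterogeneity.

Dynamic (4-D) PET captures how a radiotracer distributes in tissue over
time: every voxel carries a time-activity curve (TAC) rather than a
single uptake value. Tumors are rarely kinetically uniform — spatially
contiguous sub-populations with distinct tracer kinetics are a hallmark
of aggressive disease — but conventional ROI metrics (SUV, K1, Ki)
summarise only the hottest part of the tumor. `radfit` is for imaging
scientists who want to segment such functionally distinct, spatially
coherent sub-regions directly from the 4-D data and to quantify and
evaluate the resulting heterogeneity as a prognostic biomarker.

## The method

**Rad-FIT clustering** combines functional data analysis with a Markov
random field segmentation model:

1. **FPCA.** Voxel TACs sampled at frame mid-times are summarised by
   functional principal component analysis under the quadrature inner
   product ⟨f,g⟩ = Σ_t w_t f(t) g(t) with weights w_t equal to frame
   durations. The smallest m components capturing > 85 % of the
   duration-weighted variance are retained; each voxel becomes an
   m-vector of FPC scores.
2. **Hidden-MRF EM.** Voxels are segmented into k classes by
   expectation–maximization for a hidden Markov random field: Gaussian
   emissions N(s_i; μ_k, Σ) in score space (pooled covariance by
   default), a Potts prior β·Σ_{⟨i,j⟩} 1[x_i ≠ x_j] over the 3×3×3
   (26-voxel) neighbourhood, labels updated by iterated-conditional-modes
   sweeps, and K-means initialisation.

**The FTH signature** summarises one tumor's three ranked sub-regions
(ranked by descending mean first-FPC score) with four features: the
compactness ratio BCSS/TSS

    Σ_k (x̄_k − X̄)² / Σ_i (x_i − X̄)²

and the pairwise Bhattacharyya distances φ(1,2), φ(2,3), φ(1,3) between
Gaussians fitted to the sub-region score distributions. Their mean, the
FTH index, increases with kinetic intratumor heterogeneity. The
`prognosis` module evaluates such signatures with three-fold
cross-validated Cox proportional-hazards models (Harrell's C),
risk-score Kaplan–Meier analysis, and unsupervised phenotype discovery
(Ward clustering + consensus clustering + a simplified SigClust test).

Because no real scan data ships with the package, a built-in simulator
provides (a) a dynamic FLT-like sphere phantom (64×69×9 voxels ×
45 frames; low/medium/high-uptake spheres of 10 and 13 mm, a blood-pool
region and background; irreversible two-tissue-compartment kinetics,
activity-scaled noise and an optional resolution blur), and (b) a
synthetic breast-cancer-like cohort whose recurrence hazard is driven by
the generating heterogeneity, so the whole pipeline is testable end to
end. See `docs/methods.md` for the model details and calibration.

## Worked example

Segment the hardest task in the calibrated phantom — the low-uptake
13-mm sphere (signal-to-background ratio 1.78) against its surrounding
background:

```python
import numpy as np
from radfit import (build_phantom, fit_fpca, transform, MRFConfig,
                    radfit_segment, evaluate_segmentation)
from radfit.io import LabelVolume
from radfit.evalseg import two_class_task_mask
from radfit.phantom import calibrated_benchmark_spec

spec = calibrated_benchmark_spec(seed=42)
img, truth = build_phantom(spec)

mask, sphere = two_class_task_mask(spec, truth, sphere_index=0)
tacs = img.tacs(mask)
model = fit_fpca(tacs, img.schedule, var_threshold=0.85)
scores = transform(model, tacs)
print(f"retained {model.m} functional principal components "
      f"({100 * model.cumulative_variance[model.m - 1]:.1f}% of variance)")

result = radfit_segment(scores, mask, MRFConfig(k=2, beta=1.0, seed=42))
task_truth = LabelVolume(labels=(sphere & mask).astype(np.int32))
print(evaluate_segmentation(result.labels, task_truth).round(3)
      .to_string(index=False))
```

prints

```
retained 19 functional principal components (86.1% of variance)
 region  dice  jaccard
      1 0.769    0.624
```

i.e. on this noise replicate the MRF-EM segmenter recovers the
low-contrast sphere with Dice 0.77 — close to the replicate-averaged
operating point (≈ 0.75) the phantom noise model is calibrated to, and
above plain K-means on the same scores (≈ 0.69).

The same operations are available from the shell via the umbrella
command: `radfit simulate phantom`, `radfit fpca`, `radfit segment`,
`radfit cluster-baseline`, `radfit benchmark`, `radfit fth` and
`radfit prognosis {cvcox,km,phenotypes}` (see `radfit --help`).

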