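# cosreg

Multimodal deformable 2D image registration with a **joint co-sparse
analysis model** (JACSM), built for the brain-shift problem: after a
craniotomy the brain deforms and invalidates pre-operative MRI, and an
intra-operative modality — here photoacoustic (PA) imaging, which renders
the vessel meshwork brightly — must be registered to the pre-operative MR
image to track that deformation. The package is aimed at researchers in
image-guided intervention who want a self-contained, ground-truthed
testbed for patch-based multimodal similarity metrics.

## What it implements

* **Co-sparse analysis operators.** A pair `(Ω_PA, Ω_MR)`, each `k×n`
  with unit-norm rows (`k > n`), learned on co-located 7×7 patch pairs so
  that the stacked response is sparse:

      min  (1/N) Σ_i Σ_k log(1 + ν (Ω_PA x_PA,i + Ω_MR x_MR,i)_k²)
           + κ [h(Ω_PA) + h(Ω_MR)] + μ [r(Ω_PA) + r(Ω_MR)]

  where `h` is a log-det full-rank penalty and `r` a pairwise row-coherence
  penalty (both diverge for degenerate operators). Learning uses an ADMM:
  a proximal update for the analyzed coefficients (safeguarded Newton on
  the log-square prox), penalized least squares with unit-row retraction
  for the operators, and a scaled dual ascent.
* **JACSM registration.** A cubic B-spline free-form deformation is
  optimized coarse-to-fine to minimize the same coupled surrogate over
  patch-centre correspondences, with finite-difference gradients, a
  monotone line search, and a bending-energy regularizer.
* **NMI baseline.** The identical scaffold with normalized mutual
  information `(H(A)+H(B))/H(A,B)` as the similarity, so any performance
  difference is attributable to the metric alone.
* **Evaluation.** Target registration error (TRE), displacement-field
  RMSE, and the 95th-percentile Hausdorff distance (HD95) on vessel
  boundaries, all in mm.
* **Phantom simulator.** A brain-mimicking slab (150×40 mm, curved top)
  with tortuous tubular vessels (1.2/1.4 mm), MR/PA/US-like renderings,
  centreline landmarks, and seeded smooth deformation fields with known
  ground truth.

See `docs/methods.md` for the model, solver and simulator details.

## Worked example

Run one end-to-end experiment (simulate a phantom, deform the PA image by
a known smooth field with 8 px peak displacement, learn the operator pair
on the aligned images, register with both methods, score against ground
truth):

```python
from cosreg import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(n_repeats=1, master_seed=3))
print(result.table().to_string(index=False))
```

```
      method RMSE_mm TRE_mm HD95_mm  n_runs  n_targets
       JACSM    2.44   1.26    0.63       1          6
         NMI    2.45   1.91    3.17       1          6
UNREGISTERED    2.54   2.12    3.41       1          6
```

Reading the table: the induced deformation displaced the six vessel
landmarks by 2.12 mm on average (`UNREGISTERED` TRE); JACSM registration
brings them back to within 1.26 mm and aligns the vessel boundaries to
0.63 mm (HD95), while the NMI baseline reaches 1.91 mm TRE on the same
input. RMSE is the field error over the whole interior, including tissue
far from any vessel where the PA image carries no information, so it stays
near the raw deformation magnitude for both methods.

The same pipeline is available from the shell:

```bash
cosreg simulate --seed 1 --out scene/
cosreg learn --pair scene/pa.nii.gz scene/mr.nii.gz --count 2000 --out ops.npz
cosreg register --ref scene/mr.nii.gz --float scene/pa_deformed.nii.gz \
                --operators ops.npz --method jacsm --out reg/
cosreg evaluate --gt-field scene/field.nii.gz \
                --recovered-field reg/recovered_field.nii.gz \
                --landmarks scene/landmarks.csv --out scores.json
cosreg pipeline --seed 0 --out experiment/
```

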