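# neckssm

Statistical shape modelling of the **infrarenal aortic neck** — the aortic
segment between the lowest renal artery (LRA) and the onset of an abdominal
aortic aneurysm, which is the sealing zone for the stent-graft in
endovascular aneurysm repair (EVAR). Classical "hostile neck" measures
(length, diameter, angulation) reduce a complex 3D shape to a handful of
scalars; a statistical shape model (SSM) instead describes each patient's
neck as a mean shape plus a small number of orthogonal variation modes
learned from a corresponded population.

The package is aimed at vascular-imaging researchers who have, per patient,
a triangular surface mesh of the aortic lumen, a center lumen line (CLL)
polyline, and 3D landmarks for the LRA orifice and the distal neck end (as
exported from a vascular workstation), and want a quantitative,
reproducible description of neck morphology.

## Method

1. **Tubular parametrization.** The CLL is truncated between the projection
   of the LRA landmark and the distal neck end — supplied as a landmark or
   detected automatically as the first position where the lumen diameter
   exceeds the LRA baseline diameter by 10%. Ten equidistant stations are
   placed on this segment; at each station 36 rays are cast in the plane
   normal to the local CLL tangent at 10° intervals (0° = patient-anterior)
   and intersected with the mesh (Möller–Trumbore ray–triangle
   intersection), giving a 10 × 36 grid of 360 corresponded contour points.
2. **Correspondence.** Each of the 36 longitudinal columns is re-placed at
   equal spacing along its own polyline (preventing crossing of adjacent
   contour rings), and every grid is translated so the LRA baseline point
   sits at the origin — translation only, so deflection modes keep their
   anatomical orientation.
3. **Shape model.** Grids are flattened to 1080-dimensional shape vectors
   x_i; with mean x̄ and centered data decomposed by SVD, the model is

       x ≈ x̄ + Φ_k b,   Cov(b) = diag(λ_1 … λ_k),

   where the columns of Φ are orthonormal principal components (PCs) and
   λ_i their variances (mm²); n shapes yield at most n − 1 PCs. Mode
   surfaces are rendered at x̄ ± s·√λ_i·φ_i (s up to ±3 SD for normally
   distributed scores, clipped to the empirical score range otherwise).
4. **Evaluation.** Compactness (cumulative explained variance vs number of
   PCs), generalization (leave-one-out reconstruction RMSE in mm), and
   specificity (RMSE from model-sampled shapes to their nearest training
   shape), each with 95% confidence intervals.

Because patient CT data cannot ship with the code, a **synthetic-cohort
generator** produces mesh/CLL/landmark triples from a known five-mode
generative model (neck length, left–right deflection, anterior deflection,
baseline diameter, distal-end deflection, plus vertex noise), with the mode
variances specified directly in shape space so that the SSM's recovered
variance spectrum can be checked against the generative truth. See
`docs/methods.md` for the model's assumptions and calibration details.

## Worked example

Fit the model on a 97-patient synthetic cohort calibrated to a
51:30:12:2:2 variance spectrum with a 5% residual-noise share:

```python
import numpy as np
from neckssm import (CohortSpec, evaluate_all, explained_variance,
                     fit_ssm, generate_cohort, parametrize)
from neckssm.correspond import ShapeCohort, process_grid

spec = CohortSpec(n=97, seed=1)          # 51:30:12:2:2 spectrum, 5% noise
necks, truth = generate_cohort(spec)
rows = [process_grid(parametrize(n.mesh, n.cll, n.landmarks)) for n in necks]
cohort = ShapeCohort([f"S{i:03d}" for i in range(spec.n)], np.vstack(rows))

model = fit_ssm(cohort)
frac, cum = explained_variance(model)
print(f"components: {model.n_components}")
print("variance fractions (%):", np.round(100 * frac[:5], 1))
print(f"cumulative at 5 PCs: {100 * cum[4]:.1f}%")

report = evaluate_all(cohort, k_values=(5, 9), n_samples=200, seed=1)
for k in (5, 9):
    g, s = report.generalization[k], report.specificity[k]
    print(f"k={k}: generalization {g.mean:.2f} mm "
          f"(95% CI {g.ci_low:.2f}-{g.ci_high:.2f}), "
          f"specificity {s.mean:.2f} mm (95% CI {s.ci_low:.2f}-{s.ci_high:.2f})")
```

Output:

```
components: 96
variance fractions (%): [55.4 25.9 10.8  1.7  1.1]
cumulative at 5 PCs: 94.8%
k=5: generalization 0.73 mm (95% CI 0.72-0.75), specificity 1.17 mm (95% CI 1.12-1.22)
k=9: generalization 0.72 mm (95% CI 0.70-0.73), specificity 1.24 mm (95% CI 1.19-1.28)
```

97 shapes give 96 PCs; the leading variance fractions recover the
generative 51/30/12/2/2 proportions up to finite-sample fluctuation (one
cohort of 97 draws; averaging over seeds lands on the targets), with ~95%
of the variance in the first five PCs. Generalization improves as PCs are
added while specificity degrades slightly — random samples that exercise
low-variance modes wander farther from the training set. The absolute
errors (sub-millimetre) reflect this synthetic cohort's 3 mm per-point
shape spread, not clinical imaging data.

The same pipeline is available from the shell:

```bash
neckssm run --synthetic-n 97 --seed 1 --k 5 --k 9 --out results/run1
neckssm synth --n 10 --seed 2 --out data/      # per-patient mesh.ply/cll.csv/landmarks.json
neckssm parametrize --mesh data/S000/mesh.ply --cll data/S000/cll.csv \
    --landmarks data/S000/landmarks.json --out grid.csv
```

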