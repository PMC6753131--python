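# facemorph

Statistical 3D morphable models (3DMMs) of face shape for clinical use:
build a PCA shape model from collections of 3D surface scans, validate it
with the standard shape-model metrics, and run two applications on top of
the model's coefficient space — automated **diagnosis** of orthognathic
(jaw-surgery) face shape with a linear SVM, and **surgery simulation**:
predicting the postoperative face from a preoperative scan with a learnt
regression map.

The intended users are researchers in craniofacial shape analysis and
computer-assisted surgical planning who have collections of triangulated
surface scans (OBJ/PLY) with sparse landmarks, and who want a reproducible,
scriptable pipeline rather than interactive planning software.

## The model

Each scan, once in dense correspondence (one shared triangulation, vertex
`i` anatomically homologous across scans), is a vector `X ∈ R^{3n}`.  The
pipeline is

1. **GPA** — generalised Procrustes analysis removes rotation, translation
   and scale;
2. **NICP** — non-rigid ICP deforms a template mesh onto every scan under a
   decreasing stiffness schedule, producing the shared triangulation;
3. **PCA** — the morphable model: mean `M`, orthonormal basis
   `U = [U₁ … U_d]`, per-component variances.  Any face is synthesised as

   `X* = M + Σᵢ αᵢ Uᵢ = M + Uα`

   and any scan is embedded by the optimal projection

   `α = Uᵀ(X − M)`,  `P(X) = M + UUᵀ(X − M)`.

The coefficient vector `α` is the feature vector for both applications.
Model quality is reported as compactness (variance captured per component
count), generalisation (leave-one-out reconstruction error, mm) and
specificity (distance from synthetic faces to their nearest real face, mm);
errors between corresponded meshes use the average Euclidean distance (AED).

Because clinical face databases are not redistributable, the package ships a
first-class synthetic cohort generator (`facemorph.synthetic_faces`) with a
known low-rank generative model, a localised jaw-dipole patient effect, a
linear "surgical" operator producing paired postoperative shapes, and
similarity/noise corruption — every downstream stage is tested against its
exact ground truth.  See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from facemorph import (GeneratorConfig, sample_cohort, build_correspondence,
                       NicpConfig, generalised_procrustes, fit_pca,
                       SplitSpec, classify_diagnosis, evaluate_regression)
from facemorph.mesh_core import FlatShape
from facemorph.evaluation import compactness

# a synthetic cohort: 40 volunteers + 15 preop/postop patient pairs
cohort = sample_cohort(GeneratorConfig(resolution=16, n_volunteers=40,
                                       n_patients=15, seed=42))

# dense correspondence (template -> every scan), then alignment, then PCA
corr = build_correspondence(cohort.template, cohort.meshes, cohort.landmarks,
                            cohort.template_landmarks, NicpConfig())
aligned = generalised_procrustes(corr.shapes)
X = np.stack([s.x for s in aligned.shapes])
model = fit_pca(X, template_faces=corr.template_faces, id="global")
print(f"global model: {model.n_training} scans, {model.n_components} components")
print(f"compactness at 10 components: {compactness(model)[9]:.1%}")

# diagnosis: linear SVM on shape coefficients, 200 Monte-Carlo splits
ids = cohort.cohort.table.scan_id.tolist()
groups = cohort.cohort.table.set_index("scan_id")["group"]
keep = [i for i in ids if groups[i] in ("volunteer", "preop")]
alphas = np.stack([model.project(FlatShape(X[ids.index(s)]))[0].alpha for s in keep])
rep = classify_diagnosis(cohort.cohort, alphas, keep, SplitSpec(0.8, 200, seed=0))
print(f"diagnosis: accuracy {rep.accuracy:.1%}, sensitivity {rep.sensitivity:.1%}, "
      f"specificity {rep.specificity:.1%}")

# surgery simulation: leave-one-out ridge regression in coefficient space
pairs = cohort.cohort.pairs()
pre = np.stack([X[ids.index(s)] for s in pairs.preop_scan])
post = np.stack([X[ids.index(s)] for s in pairs.postop_scan])
report = evaluate_regression(model, pre, post, pairs.pair_id.tolist(),
                             methods=("RR", "LR"), k_grid=(10,))
s = report.summary().set_index("method")
print(f"simulated postop error (RR, 10 comps): "
      f"{s.loc['RR','mean_mm']:.2f} ± {s.loc['RR','sd_mm']:.2f} mm "
      f"(vs mean-face baseline {s.loc['RR','mean_vs_global_mean_mm']:.2f} mm)")
```

Output:

```
global model: 70 scans, 69 components
compactness at 10 components: 93.8%
diagnosis: accuracy 100.0%, sensitivity 100.0%, specificity 100.0%
simulated postop error (RR, 10 comps): 0.60 ± 0.20 mm (vs mean-face baseline 1.56 mm)
```

Reading the numbers: 10 components already capture 93.8% of the cohort's
shape variance; the 8 mm synthetic jaw effect is far larger than the ~2 mm
identity variation, so the SVM separates patients perfectly; and the
predicted postoperative faces land 0.60 mm from the true postoperative scans
— well below the 1.56 mm a mean-face (non-patient-specific) prediction would
score, confirming the predictions are patient-specific.

## Command-line pipeline

The same stages are available as subcommands over a YAML config:

```bash
facemorph synth    --config run.yaml --out data/
facemorph build    --config run.yaml --data data/ --out models/
facemorph metrics  --config run.yaml --models models/ --out reports/
facemorph embed    --config run.yaml --models models/ --data data/ --out reports/
facemorph diagnose --config run.yaml --models models/ --data data/ --out reports/
facemorph simulate --config run.yaml --models models/ --data data/ --out reports/
```

`build` writes three models (global, bespoke preoperative, bespoke
postoperative — the same model type over different cohort filters), the
aligned shape stack, and signed-error difference maps (mean patient face vs
mean volunteer face) as PLY files with a per-vertex `quality` scalar.  All
commands are deterministic under `--seed`; a run's resolved config is written
beside its outputs.

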