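# Methods

`facemorph` builds statistical 3D morphable models (3DMMs) of face shape and
runs two clinical applications on top of them: automated diagnosis of
orthognathic (jaw-surgery) face shape and simulation of the postoperative face
from a preoperative scan.  This note describes the models, the choices behind
every tunable parameter, what the synthetic cohorts do and do not emulate, and
the known limitations.

## Shape representation

A face scan is a triangle mesh with `n` vertices in millimetres.  Once all
scans share one triangulation with anatomically homologous vertices ("dense
correspondence"), a scan is the vector `X ∈ R^{3n}` of concatenated vertex
coordinates.  Mesh comparison uses the average Euclidean distance
`AED = (1/n) Σᵢ ‖aᵢ − bᵢ‖` (mm) and a signed per-vertex variant whose sign is
positive where the reference has the larger anterior (z) coordinate — so
positive means "reference more protrusive".  The frame is right-handed with
+z anterior; the sign axis is configurable.  Ties in z take the positive
sign, which is immaterial since their magnitude is zero.

## Pipeline

1. **Alignment (GPA).**  Generalised Procrustes analysis removes rotation,
   translation and scale.  Each shape is centred and normalised to unit
   centroid size; shapes are iteratively aligned to the evolving mean until
   the mean moves less than `tol = 1e-6` mm (AED) or 100 iterations.  Both
   defaults are conventional choices; convergence is typically reached in a
   handful of iterations.  Because the model must report millimetre-valued
   errors, the cohort's mean centroid size is restored after convergence
   (`keep_mm_scale=True`); unit-size output is available.  The rotational
   gauge freedom of GPA is fixed by orienting the converged mean to the first
   input shape.

2. **Dense correspondence (non-rigid ICP).**  A template mesh is deformed
   onto every scan with a locally affine model: each template vertex carries a
   3×4 affine transform, solved jointly from a sparse linear least-squares
   system combining (i) distance from deformed vertices to their closest
   *compatible* point on the target surface, (ii) sparse landmark mismatch,
   and (iii) a stiffness penalty on transform differences across template
   edges.  Correspondences farther than `correspondence_cutoff = 10` mm or
   with normal agreement below `cos 60°` receive zero data weight, which makes
   the registration robust to holes.  The outer loop relaxes stiffness through
   `[50, 20, 5, 2, 0.8, 0.5, 0.35, 0.2]` while the landmark weight decays
   from 5 to 0; the inner loop alternates closest-point search with the solve
   until mean vertex motion < 1e-3 mm.  These schedules are this package's
   defaults (the locally-affine formulation is standard; the numbers are not
   canonical) and are fully exposed in `NicpConfig`.  Each scan is first
   brought into template space by a similarity fit of its sparse landmarks
   (scaling enabled), standing in for an upstream automatic landmarking
   stage.  Closest-point queries use a KD-tree over triangle centroids with
   exact point-triangle projection over the 12 nearest candidate triangles.

3. **Model building (PCA).**  The morphable model is the mean shape `M`, an
   orthonormal basis `U` of principal directions, and per-component sample
   variances (divide by m−1), computed by SVD of the centred data matrix —
   never the 3n×3n covariance.  Component signs are fixed (largest-magnitude
   entry positive), making model builds bit-reproducible.  Synthesis is
   `X* = M + Uα`; projection is `α = Uᵀ(X − M)`, `P(X) = M + UUᵀ(X − M)`,
   the least-squares optimal reconstruction.  Random faces are drawn with
   independent Gaussian coefficients at the model variances (optionally
   truncated at ±kσ); Gaussian is the natural choice given PCA's second-order
   description of the cohort.

## Model validation metrics

* **Compactness** — cumulative variance fraction per component count.
* **Generalisation** — leave-one-out: rebuild the model without one face,
  project the held-out face with k components, record the AED.  Note that
  while the *L2 residual* is guaranteed non-increasing in k (nested
  projections), the AED — a mean of per-vertex norms — need not be monotone:
  removing a spatially concentrated component can spread the residual over
  more vertices.  In practice the curves decrease.
* **Specificity** — mean ± sd of the AED from randomly synthesised faces to
  their nearest real face.  The neighbour search is exhaustive and exact;
  cohort sizes here make approximate search unnecessary.

t-SNE embedding of shape coefficients is a seeded wrapper over scikit-learn
with a sweep driver across perplexities and iteration counts.

## Clinical applications

**Diagnosis.**  A linear-kernel SVM (C = 1.0, scikit-learn defaults
otherwise) separates preoperative patients from volunteers in coefficient
space.  Coefficients are used raw — they are already coordinates in an
orthonormal shape basis — with whitening available behind a flag.
Performance is estimated by Monte-Carlo cross-validation: stratified random
splits (per-class training count = round(fraction × class size)) repeated
`n_iterations` times with the confusion matrix averaged, plus per-scan tallies
of how often each scan is misclassified — the tool's way of flagging
atypical patients and possible undiagnosed volunteers.  The binary problem is
solved as a plain binary SVM (identical decision function to one-vs-rest for
two classes).

**Surgery simulation.**  A linear map ("design matrix") from preoperative to
postoperative coefficients is learnt with one of: ordinary least squares
(LR), ridge (alpha = 0.5), LASSO (alpha = 0.1), or least-angle regression
with a budget of one nonzero coefficient *per output component* (LARS).  The
per-output reading of the LARS budget is deliberate: the dominant predictor
of postoperative component i is preoperative component i, so a single-
predictor-per-output map is both well-posed and competitive with ridge,
whereas one nonzero coefficient for the entire map could not be.  Evaluation
is leave-one-out over preop/postop pairs, for each method and component count:
the held-out prediction is compared (AED) against the true postoperative
scan and against two population baselines — the model mean face and the mean
postoperative face — which a genuinely patient-specific prediction must beat.
The component count should stay below the number of training pairs; beyond
that the map is unidentifiable and OLS in particular overfits sharply.

## Synthetic cohorts

Clinical face databases are not redistributable, so all testing and the
acceptance analysis run on generated cohorts with exact ground truth:

* **Template** — a deterministic parametric facial patch (ellipsoidal dome +
  nose + chin) on a regular grid, 120 × 160 mm, with seven named landmarks at
  analytically known vertices (the pronasale is the global z-maximum by
  construction).
* **Identity variation** — a rank-r basis of smooth low-frequency
  normal-direction fields, projected orthogonal to the similarity orbit
  (translation / rotation / scale directions: variation along the orbit is
  removed by alignment and would be unrecoverable ground truth by
  construction), scaled to unit per-vertex RMS.  The default variance
  spectrum (1.6 … 0.05 mm², ~2 mm RMS total) gives inter-face distances of a
  few millimetres, consistent with the sub-millimetre nearest-neighbour
  specificity errors dense face models report.
* **Patients** — an added jaw dipole: maxilla pushed posteriorly, mandible
  anteriorly, peak 8 mm (per-subject amplitude jittered by 15%), a smooth
  stand-in for the class-III malocclusion signature, not anatomy.
* **Surgery** — a known linear operator on the generative coefficients that
  removes 90% of the jaw displacement and adds a small nose residual (25% of
  the jaw amplitude), mirroring the clinical observation that nose shape
  changes persist after maxillary advancement.
* **Corruption** — isotropic Gaussian vertex noise (0.5 mm, a typical surface
  scanner figure) and a per-scan random similarity transform (±10°, ±20 mm,
  scale 0.95–1.05).

Default cohort sizes are 113 paired patients (the emulated study's count) and
500 volunteers (scaled down from several thousand for desk-scale runs; fully
configurable).  All randomness flows from one seed; equal configurations are
bit-identical.

What the generator does **not** emulate: real anatomical covariance
structure, non-linear surgical effects, scanner artefacts (holes appear only
in dedicated fixtures), expression, and texture.  Passing tests therefore
demonstrate the pipeline's correctness and statistical behaviour under a
known low-rank generative model — not clinical performance.

## Numerical choices and degenerate inputs

* Pairwise Procrustes uses the closed-form SVD solution with determinant
  correction; rank < 2 point configurations are rejected.
* The NICP normal equations are solved with a sparse direct solver;
  disconnected templates are rejected up front with the component sizes
  named.  Quad faces are rejected at the I/O boundary rather than silently
  triangulated, protecting correspondence bookkeeping.
* PCA requests beyond m−1 components are clipped with a warning; zero-
  variance directions are dropped.
* Stratified splits reject configurations that leave an empty partition; MC
  iterations with a single-class training partition are skipped and counted.
* Model files are written as `.npy` + JSON, which contain no timestamps, so
  identical runs produce byte-identical artifacts.

## Desk-scale problem sizes

The default analysis scale used by `scripts/acceptance.py` — a 256-vertex
template, 60 volunteers and 28 surgical pairs through full registration,
500 synthetic faces for specificity, 300 Monte-Carlo iterations, 10
regression components — was chosen as the package's standard desk-scale
configuration; every stage scales to larger cohorts through its config
objects.

## Known limitations

* Closest-point registration cannot observe tangential sliding: any
  deformation component tangent to the surface leaves the surface set
  unchanged and is constrained only by landmarks and stiffness.  Recovery
  claims therefore concern normal-direction deformation; tangential accuracy
  degrades gracefully with landmark density.
* The KD-tree candidate search (12 nearest triangle centroids) is exact in
  practice on these meshes but is formally a heuristic; pathological
  triangulations with extreme size contrast could require more candidates.
* GPA quotients out similarity, so any real variation that mimics global
  scaling or rotation is attributed to pose, not shape — an intrinsic
  property of Procrustes shape analysis, not an implementation artefact.
* With very few preop/postop pairs the design matrix is only identifiable
  for component counts below the pair count; reports at higher counts mostly
  measure regularisation behaviour.
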