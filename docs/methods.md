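# Methods

`cardiospare` analyses lung-SBRT treatment plans for cardiac-substructure
(CS) sparing: it evaluates EQD2 dose constraints on five CS, stratifies
patients by whether a cardiac-sparing replan (CSP) is needed and whether it
succeeded, and relates both outcomes to the patient's anatomy through
geometric predictors.  This note records the models, the defaults, and the
choices made where the design was genuinely open.

## Dose–volume metrics and EQD2

All dosimetry runs on binary voxel masks and Gy-per-course dose grids
sharing one lattice (default clinical spacing 1×1×3 mm; x/y axial, z
cranio-caudal).  DVHs are exact voxel lists — every in-structure dose sorted
descending, no histogram binning — because the near-maximum surrogate
D0.1 cm³ is bin-sensitive on noisy Monte-Carlo-like dose.  D-at-volume
interpolates linearly between sorted voxel doses at cumulative volumes
(1·vv, 2·vv, …); a request below one voxel returns the maximum, and an
absolute volume at or beyond the structure volume returns the minimum dose
with an explicit `volume_exceeds_structure` flag rather than an error, so
sub-0.1 cm³ structures on coarse lattices stay evaluable.

Doses are converted to the equivalent dose in 2 Gy fractions under the
linear-quadratic model with the course fraction number n:

    EQD2(D) = D · (D/n + α/β) / (2 + α/β),   α/β = 2 Gy unless specified.

Conversion is applied per voxel before metric extraction.  For quantile-type
metrics (all five CS constraints) the order is immaterial because EQD2 is
strictly increasing in dose at fixed n; the equivalence is asserted as a
property test, exactly at voxel-boundary volumes and bounded by the adjacent
EQD2 gap between them (EQD2 is convex in dose, so the two linear
interpolations can differ by at most that gap).  For the mean metric the
order genuinely matters and per-voxel conversion is the canonical choice.

## Constraints and stratification

The bundled CS table holds the five literature constraints (EQD2 Gy,
optimal with optional mandatory level): base of heart D0.1 cm³ < 13.5,
whole heart D60% < 1.0, left atrium D0.1 cm³ < 4.7 (6.5), right ventricle
D4% < 11 (13.3), left ventricle D0.1 cm³ < 60.  The comparator is a strict
`<`; equality counts as violated.  The base of the heart is the union of
the right atrium and the ascending aorta and is derived on the fly when not
delineated.  Violation (and hence "needs sparing") keys on the optimal
limit; the mandatory status is reported alongside so report layers can
choose.  Missing structures yield per-constraint `unevaluable` results, and
per-patient waiver flags (clinical under-/over-dose exceptions) exclude a
structure from violation accounting without hiding its achieved dose.

A patient *needs sparing* when ≥ 1 CS constraint is violated in the
non-CS-constrained plan.  The CSP is *successful* with zero CS and zero
departmental-OAR violations, *partially successful* when the departmental
table is met but 1–4 of the 5 CS constraints still fail, and *not feasible*
when departmental constraints break (or all CS fail).  No authoritative
departmental table is distributable, so the package ships a clearly-labelled
synthetic placeholder (generic cord/esophagus limits) that users must
override with their own clinic's table.

## Geometric predictors

* **CC distance** — gap between the closed cranio-caudal extent intervals
  of PTV and CS (voxel-center z); 0 when they overlap or touch.
* **3D distance** — minimum center-to-center Euclidean distance, computed
  via an exact anisotropic distance transform of the PTV and verified
  against the O(N·M) pairwise definition in tests.
* **iOVH** — in-field overlap volume histogram: only CS voxels whose z lies
  within a slab extending 6.4 mm (the lung penumbra scale) beyond the PTV's
  CC extent count; each such voxel's in-plane distance to the PTV's *axial
  projection* (Δz ignored) is thresholded at radii 0, 1, 2, … mm and the
  curve reports the covered fraction of the total CS volume.  The
  projection reading is the default because a strictly per-slice expansion
  can never overlap anything on slices beyond the PTV, which would make the
  slab extension meaningless; the per-slice variant is available behind
  `IOVHParams(per_slice=True)` for sensitivity analysis.  Slab membership is
  voxel-center based and boundary-inclusive — a visible choice on 3 mm
  slices, hence documented.  Radii are physical mm, honoring anisotropy.

All distances are between voxel centers: surface-based definitions depend
on meshing choices, while center-based ones are reproducible and admit
exhaustive brute-force oracles.

## Cohort statistics

AUC is computed from midranks, making the tie-adjusted identity
AUC = U/(n₁·n₂) exact by construction (cross-checked against an independent
ROC implementation in tests).  Classifier cutoffs are reported at a true
positive rate of 1 — the clinically conservative threshold that never
misses a sparing candidate — with the false-positive count as its cost, and
only when AUC ≥ 0.8 and the Mann–Whitney p ≤ 0.05.  Thresholds sit at
observed predictor values; no interpolation.

Mann–Whitney uses the exact null when the samples are tie-free and the
arrangement count is enumerable (≤ 10⁷), else the tie-corrected normal
approximation; the method used is always recorded.  The paired Wilcoxon
signed-rank test discards zero differences (classical zero handling; the
alternative Pratt treatment is noted in output metadata), uses the exact
null for ≤ 25 informative pairs and the continuity-corrected approximation
above, and its p-values are Holm step-down adjusted across the metric
family at α = 0.05.

## The phantom cohort

The generator emulates the study conditions so every downstream stage is
testable without clinical data: 34 patients on the 1×1×3 mm lattice
(150×140×72 voxels), 60 Gy prescribed as 8×7.5 Gy (central, probability
16/34) or 12×5 Gy (ultra-central), PTV volumes inside the reported
1.8–221.5 cm³ range with median near 28 cm³, and a scenario mix of 18
far / 10 near-spareable / 6 near-unspareable patients planting 16/34 (47%)
needing sparing and 10/16 successful CSPs.  The anatomy is an ellipsoidal
heart with five disjoint chamber ellipsoids (disjointness enforced by
carving priority), two OAR cylinders (cord, esophagus), a k-nearest-voxel
ball PTV (realised volume within half a voxel of target), and a GTV eroded
4 mm from the PTV.

Dose is an analytic surrogate, not a beam model:
D(v) = Rx · erfc(d_eff/(√2 σ)) with d_eff the anisotropic distance from the
PTV surface and σ ≈ 6.22 mm fixed by requiring the 80%→20% falloff to span
6.4 mm.  The CSP multiplies d_eff by 1 + a·max(0, cos θ) toward the heart
center (a = 5), so dose is untouched on the PTV (coverage exactly preserved)
and monotonically reduced on the cardiac side — emulating a replan without
optimisation, which suffices to exercise the paired statistics.  The
functional form is smooth, monotone in effective distance, and analytically
invertible, so scenario geometry (surface gaps of 3.5–6.5 mm for spareable,
−10…−4 mm overlap for unspareable patients) forces the planted labels:
an overlapping PTV puts > 0.1 cm³ of the left atrium at full prescription
(EQD2 142.5 Gy) in any plan, while a 3.5 mm gap amplified six-fold by
steering drops the atrium dose far below the 4.7 Gy limit.

Planted truth is computed inside the generator by an independent ~10-line
numpy implementation of the same D-at-volume/EQD2 definitions, so exact
recovery by the production DVH/constraint path is a dual-route check, not a
tautology.

What the phantoms do *not* contain: realistic anatomy, heterogeneity and
lateral scatter, respiratory motion, MR magnetic-field dose effects, or
optimiser trade-offs.  Passing tests therefore demonstrate the *analysis
machinery* — metric arithmetic, stratification logic, predictor geometry,
statistics — is correct, not that clinical cohorts will reproduce any
particular rate.  The cohort-level numbers the pipeline prints on phantoms
(47% needing sparing, 62.5% spareable, AUC 1.0 for left-atrium CC distance)
are consequences of the planted construction.

## Numerical choices and limitations

* Problem sizes: default full-lattice phantoms (~1.5 M voxels) take well
  under a second per patient for dose synthesis and evaluation; oracle
  tests run on ≤ 20×20×12 lattices where exhaustive pairwise computation is
  exact and fast.
* Masks arriving on a finer lattice than the dose grid are resampled
  nearest-neighbour onto the dose lattice (the dose grid is authoritative);
  dose itself is never interpolated, which would perturb DVH metrics.
* The erfc tail underflows to exactly 0 in double precision at large
  amplified distances, so "strictly decreasing" holds only where dose > 0;
  invariants are asserted as non-increasing.
* Ball-mask ties in voxel-center distance break on flat index,
  deterministically.
* DICOM RT-STRUCT/RT-DOSE parsing is out of scope (NIfTI + JSON sidecar is
  the interface; a DICOM adapter would be a separate concern), as are plan
  optimisation, delivery-time/complexity metrics, and motion management.
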