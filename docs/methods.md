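# Methods

## Data model

A brain is a regular voxel lattice (default spacing 100 μm; voxel centre at
`(index + 0.5) × spacing`) carrying an integer annotation volume bound to a
hierarchical structure graph (Allen structure-graph JSON dialect: `id`,
`acronym`, `parent_structure_id`). *Leafs* are annotated structures with no
annotated descendant; they partition the annotated voxels. Sources are the
leafs of one designated hemisphere (the half-space below the midline plane of
the last lattice axis; voxels exactly on the midline count as ipsilateral, so
a leaf wholly on the midline has no contralateral counterpart). Targets are
the ipsilateral leafs followed by the mirrored contralateral leafs, so the
contralateral target count is the total target count minus the source count.
Each leaf's *major structure* is its depth-1 ancestor.

An experiment carries a cell-class label, an injection centroid (the
signal-weighted mean of injection voxel centres; an unweighted variant is
available by binarizing the field first) and the regionalized projection
y_T (projection signal summed per target). Index sets I_l, I_m, I_v (leaf,
major, class) are recomputed deterministically from centroids and labels;
experiments whose centroid falls in an unannotated voxel are excluded with a
logged warning. Because the environment provides no NRRD reader, volumes are
handled as in-memory arrays and exchanged on disk as compressed `.npz`; the
tabular interfaces (manifest TSV + experiments × target-leaf TSV) are the
primary exchange format.

## Normalization and detection limit

Default normalization is `total_projection` (y_T rescaled to sum to one),
which makes classes with different tracer efficiencies comparable;
`injection_volume` (divide by injection voxel count) and `none` are
selectable. The lower limit of detection defaults to the 5th percentile of
positive normalized entries of the training data (a fixed value can be
configured); entries below it are zeroed, idempotently. During
cross-validation the limit is refit inside each fold when enabled.

## Estimators and selection

Gaussian kernels are used for both the spatial and the class kernel — the
standard smooth choice for Nadaraya-Watson regression. Kernel weights are
computed with the largest exponent shifted to zero, which cancels in the
weight ratio and keeps tiny bandwidths finite; coincident centroids are used
as given, with no jitter. Class distance is 1 − cosine similarity of the
classes' mean normalized projection vectors (Euclidean selectable); it is
exactly zero for a class against itself.

EL's fallback chain for the class-leaf mean m(v, l) when the class has no
experiment in the leaf is: global class mean, then all-class leaf mean — so a
prediction exists wherever the leaf holds any experiment. During LOOCV a
missing prediction (e.g. Cre-NW with an empty held-out support) falls back to
the same class-mean chain, and to a zero vector only when the training set
offers nothing; points are never silently dropped, because dropping would
favor models with narrower coverage.

Hyperparameters are selected by leave-one-out cross-validation of the
weighted l2-loss, restricted to (leaf, class) cells with at least two
experiments; everything data-dependent (class space, class means, NNLS fits)
is refit on each leave-one-out training set. σₓ (and σ_c for EL) are chosen
per major structure, ties breaking toward larger (smoother) bandwidths; α is
chosen per (major, class) on a grid over [0, 1], ties toward larger α. The
default grids used throughout the synthetic studies (σₓ ∈ {100, 300, 800} μm,
σ_c ∈ {0.1, 1}, α ∈ {0, 0.5, 1}) are matched to the synthetic leaf geometry
(300 μm blocks); for atlas-scale data wider log-spaced grids (10²–10⁴ μm)
are appropriate and configurable.

EL is evaluated at the structure level by default — one prediction per leaf,
the voxel-average of the blended estimate, multiplied by |s| when assembling
connectivity — with a per-voxel mode available; the NW family always predicts
per voxel. NNLS is fit per major structure using only that major's source
columns; an all-zero injection column yields a zero row with a warning.
Connectivity rows for (class, source) pairs without an injection centroid are
stored as missing (NaN; empty fields in CSV, an explicit flag in long TSV),
never as zero — "not estimated for lack of data" and "no projection" are
different statements. A log10 display transform exists only in the writers.

## Masked sparse NMF

Distal connectivity (pairs at least 1,500 μm apart by default; the metric —
nearest-voxel or centroid distance — is selectable, nearest-voxel being the
default because short-range artifacts arise at region borders) is factored by
minimizing ½‖M ⊙ (C − WH)‖² + λ(‖H‖₁ + ‖W‖₁), λ = 0.002. The mask is applied
to the *residual*: masking C alone would drive WH toward zero on proximal
pairs instead of ignoring them. The solver uses mask-aware multiplicative
updates with the L1 term folded into the update denominators — the standard
majorize-minimize step, which keeps the objective non-increasing at every
iteration (asserted in the tests with 1e-10 slack); a subtractive L1 update
with clipping was considered and rejected because it loses that guarantee.
Denominators carry an ε = 1e-12 floor; default max_iter = 2000 and stopping
at relative objective change < 1e-6. H rows are stored unit-L2-normalized
with scale absorbed into W.

Rank selection hides a random 20% of unmasked entries (10 repeats), fits each
candidate rank with the hidden entries masked, and scores held-out squared
error; ties go to the smaller rank. Stability analysis pools unit-normalized
H rows across replicate restarts (seeds base+1…base+R, default R = 30 at
atlas scale, smaller in the bundled studies), clusters them by average-linkage
cosine distance cut at 0.3, keeps at most one member per replicate per
cluster (the one nearest the cluster mean), ranks clusters by the number of
distinct replicates represented, and reports element-wise median archetypes
(top 15 by default). Recovery checks compare factors only up to permutation
and scale, via Hungarian matching of unit-normalized rows.

## Synthetic generator

The generator embodies the smoothness/discontinuity assumptions the
estimators rely on. Brains are axis-aligned block parcellations (two-level
ontology, mirrored hemispheres). Each (class, leaf) pattern is a sparse
Dirichlet-like draw: Bernoulli(1 − sparsity) support, Gamma(2, 1) weights,
normalized; class v perturbs the leaf's base pattern multiplicatively by
exp(class_effect · z), z ~ N(0, 1), so class_effect = 0 makes classes
identical and larger values drive them apart. Within-leaf spatial modulation
is the scalar field exp(sin(⟨pos, u⟩/scale + φ)) per leaf (random direction u
and phase φ); an infinite scale makes it constant. Experiments sample a blob
centre uniformly over leaf voxels, truncate a Gaussian injection blob
(sd 1.5 voxels) to the leaf and normalize it to unit mass — the blob
amplitude is otherwise arbitrary, and unit mass makes the noiseless readout
equal the ground truth at the centroid exactly — then apply entrywise
multiplicative log-normal noise (default sd 0.2, emulating
fluorescence-intensity variability).

What the generator does *not* emulate: imaging artifacts, traveling fibers,
segmentation errors, and within-leaf changes of the *pattern shape* (the
spatial modulation is a scalar per position). The last point has a practical
consequence: under total-projection normalization a scalar modulation cancels
exactly, so the spatial-gradient study conditions use unnormalized vectors,
where the gradient appears as a magnitude trend. Passing tests therefore
demonstrate correct bookkeeping and the expected regime behavior of the
estimators, not robustness to real imaging artifacts.

## Study conditions for the built-in validations

All validation studies run on 2 majors × 2 leafs × (3, 3, 3)-voxel blocks
(4 sources, 8 targets), 3 classes, chosen so the full LOOCV grid search over
three estimators and 10 seeded replicates completes in seconds:

- *Class-dominated regime*: class_effect = 2, smoothness scale 10⁶ μm,
  3 experiments per (class, leaf), noise sd 0.2, total-projection
  normalization. Expected: Cre-NW and EL beat NW.
- *Spatially dominated regime*: class_effect = 0, smoothness scale 300 μm,
  2 experiments per cell (sparse class subsets), noise sd 0.2, no
  normalization. Expected: pooled NW at least matches Cre-NW.
- *Ground-truth recovery*: noiseless, 4 experiments per cell, smoothness
  10⁶ μm, class-restricted kernel estimator at σₓ = 200 μm, structure-level
  assembly, compared entrywise to the generator's true strength matrix.
- *NMF*: planted sparse rank-3 factors on a 20 × 30 matrix with additive
  noise sd 0.01; rank grid 1–6, 10 held-out repeats; 10 stability replicates.

## Known limitations

- The EL blend (α-mix of class-leaf mean and product-kernel term) is this
  package's explicit parameterization of expected-loss weighting; other
  weightings (e.g. loss-derived closed forms, leaf-conditional class
  distances) are plausible and would slot behind the same interface.
- Real atlas ingestion (NRRD volumes, the full CCF ontology) is out of scope
  here; the readers accept the same JSON dialect and tabular formats, but no
  registration or segmentation is provided.
- LOOCV refits everything per held-out point; at atlas scale (~1,700
  experiments) the NNLS baseline in particular would need caching or
  incremental updates.
- Multiplicative NMF updates converge slowly near fixed points; archetype
  stability clustering, not single-run convergence, is the intended source of
  reliability.
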