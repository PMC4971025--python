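# Methods

This note documents the algorithms, the tunable parameters and their
defaults, the synthetic phantom's scope, and the numerical and design
choices made where behavior was genuinely open.

## The correction model

A label atlas is a 3D integer grid in which each voxel names one
anatomical structure, accompanied by one or more co-registered intensity
volumes (typically T1-weighted and T2-weighted MRI). Two defect classes
dominate after manual or multi-atlas segmentation:

1. **Suspicious voxels**: a catch-all ID (999 by convention) marking
   voxels the segmentation could not assign, concentrated at structure
   borders where partial-volume averaging yields intermediate intensities.
2. **Dust**: small connected components of an otherwise valid label,
   disconnected from the label's main body — usually tracing errors,
   since one label is assumed to represent a single densely packed
   structure.

Both are corrected by reassigning a small region to the most plausible
*bordering* label, where plausibility is mean-intensity similarity.

### Similarity metric

For target region T and a border label B, with per-modality means
Tᵢ and Bᵢ, the distance is the Euclidean norm d = √Σᵢ(Tᵢ−Bᵢ)². The
candidate with smallest d wins; ties break by ascending label ID for
determinism. Because √ is monotone, ranking is identical whether or not
the radical is applied; the property suite asserts this invariance.

Border means are computed, by default, over the border label's voxels in
the island's one-voxel 26-shell (`scope="shell"`). The alternative
`scope="component"` averages over the entire connected component(s) of
the border label touching the shell. Shell scope is the default because
local means are robust to intensity inhomogeneity across large
structures; both are exposed since either convention is defensible.

### Dust cleanup sweep

Labels are processed in ascending ID order (a review list restricts the
set; an exclude list removes from it — excluded labels may still
*receive* voxels). Within a label, island sizes s = 1…S are processed in
increasing order, and the label's mask is recomputed from the current,
partially edited volume at every (l, s) pass, so edits are immediately
visible and no voxel is processed twice. Islands whose (masked) size is
exactly s are processed at pass s; larger ones wait for their size or are
never touched if above S.

Isolation gating: with dilation enabled and s > 1, the label mask is
dilated by a discrete ball of radius r(s) = ⌈(3s/4π)^⅓⌉ — the radius of a
sphere of volume s — before component labeling, and the component map is
then masked back by the original mask. Dust within ~r(s) of another body
of the same label merges with it in the dilated mask, so its masked size
exceeds s and it is skipped: only spatially isolated islands are
reassigned. Dilation is never applied at s = 1, so all isolated single
voxels are removable. The ball is {(i,j,k): i²+j²+k² ≤ r²} in voxel
units; with anisotropic voxel spacing it is physically anisotropic
(documented limitation — all geometry here is index-space).

If the island's own label ranks first, the island is left (logged as a
self-skip) unless `force_relabel` is set, in which case the best *other*
border label is used. The degenerate case where the only border label is
the island's own (possible across a diagonal under face-built islands) is
left unchanged and logged as unresolvable. The sweep is fully
deterministic — no randomness anywhere — and every decision is logged;
replaying the log against the input reproduces the output bit-exactly.

Termination: with force on, no dilation, and full (26) connectivity,
one sweep leaves zero islands of size ≤ S for every reviewed label.
Reassigned voxels are 26-adjacent to a shell voxel of the receiving
label, so they join an existing component; once a label's pass has
removed all of its small islands, later gifts only grow components, never
create small ones. The acceptance suite asserts this on 50 seeded
phantoms. With face connectivity or dilation the guarantee intentionally
does not hold (skips are the point of isolation gating).

### Label merge

The combined source∪target mask is component-labeled (default: full
connectivity; the original convention is not documented, so it is a
parameter). Eligible components are either the single largest (ties go to
the component holding the lexicographically smallest coordinate) or every
component containing at least one target voxel. The literal "all
components" reading — which would relabel even pure-source components far
from any target, i.e. unconditional relabeling — is available behind
`all_components_literal` but is not the default, since it defeats the
"where the two are connected" purpose. Source voxels in eligible
components become the target unless a posterior volume assigns them a
value below `min_threshold`; gated voxels keep the source label, and the
changed set is monotone non-increasing in the threshold. Intensity-window
masks (closed intervals per modality, ANDed) provide binary posteriors
for merges such as sending venous-blood voxels to background.

### Two-stage automated protocol

`run-protocol` executes the shipped `data/protocol.yaml`:

* **Stage 2** (suspicious dust): S = 6, face connectivity, no dilation,
  force on, review = {suspicious}. Face adjacency splits border dust into
  small groups; no dilation lets islands near other dust still be
  cleaned; force guarantees every island ≤ 6 voxels is resolved.
* **Stage 4** (isolated dust in ordinary labels): S = 5, full
  connectivity, dilation on, force on, review all minus user-supplied
  labels whose disconnected bodies are anatomically viable (e.g. CSF).

The numbering leaves room for the manual stages (region addition, large
island repair) that precede and separate the automated ones in a full
atlas-editing workflow; those are out of scope here.

## Synthetic phantom

The phantom is the package's test substrate: a 64³ grid (unit spacing) of
concentric spheres — background 0, CSF shell 24 (radius fraction 0.45 of
the half-extent), gray shell 17 (0.34), white core 5 (0.22) — with
Gaussian intensities per label in two modalities. Defaults: noise SD 4.0
per modality; label means follow brain-MRI contrast (CSF 60/240,
gray 140/120, white 220/70, background 10/10 in T1w/T2w units), so every
label pair is ≥ 5 SD apart in at least one modality, the regime in which
similarity ranking should essentially always recover the generating
label.

Defects:

* **Border dust** (default fraction 0.20): sampled from the single voxel
  layer on the outer side of each label interface, relabeled suspicious,
  intensity set to the exact average of the two adjoining labels' means —
  the worst case for the similarity metric, by design. Sampling one
  layer at 0.20 keeps the dust subcritical: face-connected clusters are
  predominantly of size ≤ 6 and hence within Stage 2's reach, matching
  the intended pathology of scattered partial-volume voxels rather than
  contiguous mislabeled sheets. At 64³ this yields on the order of 800
  suspicious voxels, a density comparable to (slightly above) real
  256³ atlases with ~16k suspicious voxels.
* **Planted islands** (`(true, host, size, count)` tuples): randomized
  face-connected blobs carved inside the host label, relabeled
  suspicious, with intensities drawn from the *true* label's
  distribution; when true ≠ host the blob is seeded 26-adjacent to the
  true label's region so the true label is always a border candidate.
  Defects keep Chebyshev distance ≥ 2 from each other, exactly enough
  that each island is a separate component whose border shell contains no
  other defect. Placement retries are bounded (200 per island) and
  exhaustion is an error, not a silent shortfall.

The posterior volume is a Gaussian-smoothed (σ = 1.5), max-normalized
indicator of one designated label (CSF by default).

One `numpy` generator seeded from `spec.seed` drives everything;
identical spec + seed is bit-identical.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: anatomical shape (spheres, not gyri), bias
fields and Rician noise, within-label intensity gradients, scanner
effects, and suspicious regions large enough to need voxel-wise
splitting. Results on phantoms demonstrate algorithmic correctness
(the right island found, the right neighbor chosen, exact accounting),
not clinical segmentation accuracy.

## Numerical choices and edge cases

* Geometry: co-registration tolerance 1e-5 (shape exact; spacing, origin,
  direction within tolerance); direction matrices orthonormal within
  1e-6. Label maps stored as uint32 (atlas IDs like 15000 exceed 8 bits);
  float-stored label files are accepted only if integral within 1e-6.
* Quartiles: linear interpolation between order statistics (numpy
  default), fixed and documented since box-plot conventions vary.
* Island ordering: lexicographic scan order of each island's minimum
  coordinate; makes logs and outputs reproducible across runs.
* `percent_reduction` requires a positive baseline; stage reports emit
  null reductions when a reference count is zero.
* Degenerate inputs: an island filling the whole grid has no border
  (error); a merge whose source label is absent is a logged no-op;
  empty regions cannot be profiled.

## Problem sizes in the shipped checks

The test and acceptance workloads use 4³ grids (1000 seeded, for exact
oracle comparison against brute-force flood fill and shell enumeration),
64³ phantoms (50 seeds for the eradication property; single seeds
elsewhere), and 100 planted islands for the recovery rate. These sizes
were chosen so the full suite completes in about a minute while every
code path — both connectivity regimes, dilation gating, forced and
unforced ranking, posterior gating — is exercised.
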