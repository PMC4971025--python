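# atlasdust

Headless correction engines for 3D label atlases (brain MRI
parcellations and similar dense anatomical label maps).

Manually or automatically produced label atlases accumulate small,
disconnected clumps of mislabeled voxels — *dust* — and catch-all
"suspicious" voxels (commonly ID 999) at structure borders where partial
volume effects make assignment ambiguous. `atlasdust` provides the
automatic pieces of a cleanup pipeline as a library and CLI, with no GUI
dependency:

* **Automatic dust cleanup** — for each reviewed label *l* and island size
  *s* = 1…*S*, find connected components (face/6 or full/26 adjacency) of
  *l*, optionally testing spatial isolation by dilating the label mask
  with a ball of radius *r* = ⌈(3*s*/4π)^⅓⌉ (the radius of a sphere of
  volume *s*) and masking component labels back onto the original mask.
  Each isolated island of size *s* is merged into the bordering label with
  the most similar mean intensity.
* **Similarity ranking** (label suggestion) — candidates for a
  questionable region are ordered by the distance between mean-intensity
  vectors across the supplied modalities,
  *d* = √Σᵢ(*T*ᵢ − *B*ᵢ)², where *T*ᵢ is the target region's mean in
  modality *i* and *B*ᵢ a border label's mean.
* **Posterior-gated label merge** — reassign a source label's voxels to a
  target label where the two are connected, vetoing voxels whose posterior
  probability (e.g. a CSF probability map, or an intensity-window mask)
  falls below a minimum threshold.
* **Synthetic phantoms** — seeded 64³ multi-label phantoms with Gaussian
  per-label intensities in two modalities, partial-volume border dust, and
  planted islands of known true label, so every engine is testable with
  planted ground truth and no data downloads.
* **Stage accounting** — per-stage censuses of suspicious voxels, percent
  reductions, and five-number summaries.

All volumes are NIfTI-1 (`.nii`/`.nii.gz`) or NRRD (`.nrrd`/`.nhdr`),
read and written through SimpleITK; intensity volumes must be
co-registered with the label map (checked, tolerance 1e-5).

## Worked example

Generate a 48³ phantom with partial-volume border dust and five planted
2-voxel islands, then eradicate the suspicious label's dust
(*S* = 6, face connectivity, no dilation, forced reassignment):

```sh
$ atlasdust phantom --shape 48 48 48 --seed 11 --plant 5 17 2 5 --out-dir ph_demo
{"out_dir": "ph_demo", "n_planted": 5, "n_border_dust": 477}

$ atlasdust clean-dust --label-map ph_demo/label.nii.gz \
    --intensity T1w ph_demo/t1w.nii.gz --intensity T2w ph_demo/t2w.nii.gz \
    --out ph_demo/cleaned.nii.gz --max-island-size 6 \
    --review-labels 999 --no-dilate --connectivity face --force
{"islands_moved": 363, "islands_skipped": 0, "voxels_moved": 487}

$ atlasdust report --stage base ph_demo/label.nii.gz --stage cleaned ph_demo/cleaned.nii.gz
[
  {"stage": "base",    "undefined_count": 487, "reduction_from_base_percent": 0.0, ...},
  {"stage": "cleaned", "undefined_count": 0,   "reduction_from_base_percent": 100.0, ...}
]
```

The phantom contained 487 suspicious voxels (477 border-dust voxels plus
five planted 2-voxel islands); they formed 363 face-connected islands, all
of size ≤ 6, so a single cleanup pass reassigned every one to its most
intensity-similar neighbor and the suspicious count dropped to zero.
Each run also writes a `manifest.json` (parameters, input checksums,
version) and, with `--log-json`, a replayable audit log of every
reassignment.

Other subcommands: `suggest` (ranked candidate labels for one region),
`merge` / `make-mask` (posterior-gated merging and intensity-window
masks), `islands` (component census), `run-protocol` (the shipped
two-stage automated protocol; see `src/atlasdust/data/protocol.yaml`).

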