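"""Seeded synthetic phantoms with planted, ground-truthed label defects.

The phantom emulates the pathology a correction tool must fix in a real
multi-modal label atlas, on a geometry simple enough to generate in well
under a second: concentric spherical structures (by default a CSF shell,
a gray-matter shell, and a white-matter core over background) with
per-label Gaussian intensities in two MRI-like modalities, plus two kinds
of planted defect:

* **Partial-volume border dust** — a fraction of inter-label boundary
  voxels is relabeled to the catch-all suspicious ID and given exactly the
  average of the two adjoining labels' mean intensities. The averaged mean
  is the worst case for intensity-similarity ranking and deliberately
  stresses the metric.
* **Isolated dust islands** — face-connected blobs of known size carved
  inside a host label, relabeled to the suspicious ID, with intensities
  drawn from the *true* (generating) label's distribution. When the true
  label differs from the host, the blob is seeded 26-adjacent to the true
  label's region so the true label is always a border candidate. Each
  planted island is recorded in the ground truth, and islands are kept at
  Chebyshev distance >= 2 from every other defect, which is exactly enough
  to keep each island a separate component whose border shell contains no
  other defect — its size and border context are as planted.

A posterior volume (smoothed, max-normalized indicator of one designated
label, CSF by default) accompanies the phantom for testing posterior-gated
merges. Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import PlacementError
from .volumes import IntensityVolume, LabelVolume, PosteriorVolume, VolumeGeometry

__all__ = ["PhantomSpec", "PlantedIsland", "GroundTruth", "generate_phantom"]

_FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

#: Default structures: (label, radius as fraction of the half-extent),
#: outermost first. 24 = CSF shell, 17 = gray shell, 5 = white core.
_DEFAULT_STRUCTURES = ((24, 0.45), (17, 0.34), (5, 0.22))

#: Default per-label modality means. Contrast follows brain MRI: CSF dark
#: on T1w / bright on T2w, white matter the reverse, gray in between; all
#: pairs of labels are separated by >= 5 noise SDs in at least one modality.
_DEFAULT_MEANS = {
    0: {"T1w": 10.0, "T2w": 10.0},
    24: {"T1w": 60.0, "T2w": 240.0},
    17: {"T1w": 140.0, "T2w": 120.0},
    5: {"T1w": 220.0, "T2w": 70.0},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom; identical spec + seed is bit-reproducible."""

    shape: tuple[int, int, int] = (64, 64, 64)
    structure_labels: tuple[tuple[int, float], ...] = _DEFAULT_STRUCTURES
    modality_means: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_MEANS
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"T1w": 4.0, "T2w": 4.0}
    )
    suspicious_label_id: int = 999
    border_dust_fraction: float = 0.2
    planted_islands: tuple[tuple[int, int, int, int], ...] = ()
    posterior_label: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [f for _, f in self.structure_labels]
        if any(b >= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("structure radius fractions must be strictly decreasing")
        if not 0.0 <= self.border_dust_fraction <= 1.0:
            raise ValueError("border_dust_fraction must lie in [0, 1]")
        for true_label, host, size, count in self.planted_islands:
            if size < 1 or count < 1:
                raise ValueError("planted island size and count must be >= 1")
        for lab, means in self.modality_means.items():
            if any(not np.isfinite(m) for m in means.values()):
                raise ValueError(f"non-finite mean for label {lab}")

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.noise_sd)


@dataclass(frozen=True)
class PlantedIsland:
    coords: frozenset[tuple[int, int, int]]
    true_label: int
    host_label: int


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: defect islands and relabeled border voxels."""

    planted: tuple[PlantedIsland, ...]
    border_suspicious_coords: dict[tuple[int, int, int], int]


def _grow_blob(
    rng: np.random.Generator,
    seed_coord: tuple[int, int, int],
    allowed: np.ndarray,
    size: int,
) -> set[tuple[int, int, int]] | None:
    """Randomized face-connected growth from a seed inside ``allowed``."""
    blob = {seed_coord}
    frontier = [seed_coord]
    shape = allowed.shape
    while len(blob) < size:
        if not frontier:
            return None
        i = int(rng.integers(len(frontier)))
        x, y, z = frontier[i]
        options = []
        for dx, dy, dz in _FACE_OFFSETS:
            n = (x + dx, y + dy, z + dz)
            if (0 <= n[0] < shape[0] and 0 <= n[1] < shape[1]
                    and 0 <= n[2] < shape[2] and allowed[n] and n not in blob):
                options.append(n)
        if not options:
            frontier.pop(i)
            continue
        chosen = options[int(rng.integers(len(options)))]
        blob.add(chosen)
        frontier.append(chosen)
    return blob


def _mark_zone(zone: np.ndarray, coords, radius: int = 2) -> None:
    """Mark the Chebyshev-radius neighborhood of coords as occupied."""
    shape = zone.shape
    for (x, y, z) in coords:
        zone[max(0, x - radius):x + radius + 1,
             max(0, y - radius):y + radius + 1,
             max(0, z - radius):z + radius + 1] = True


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[LabelVolume, list[IntensityVolume], PosteriorVolume, GroundTruth]:
    """Generate label + intensity (+ posterior) volumes and ground truth."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    geom = VolumeGeometry(shape=shape)

    # 1. concentric structures, outermost first so inner spheres overwrite
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    half_extent = min(shape) / 2.0
    grids = np.indices(shape, dtype=float)
    dist = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    clean = np.zeros(shape, dtype=np.uint32)
    for lab, frac in spec.structure_labels:
        clean[dist <= frac * half_extent] = np.uint32(lab)

    # 2. per-modality intensities: label mean + Gaussian noise
    labels = clean.copy()
    mean_of = {int(l): dict(m) for l, m in spec.modality_means.items()}
    intensity_arrays: dict[str, np.ndarray] = {}
    for mod in spec.modalities:
        arr = np.zeros(shape, dtype=np.float64)
        for lab in np.unique(clean):
            arr[clean == lab] = mean_of[int(lab)][mod]
        arr += rng.normal(0.0, spec.noise_sd[mod], size=shape)
        intensity_arrays[mod] = arr

    defect_zone = np.zeros(shape, dtype=bool)  # keep-out ring around defects
    border_records: dict[tuple[int, int, int], int] = {}

    # 3. partial-volume dust on inter-label boundaries: the single voxel
    # layer on the outer side of each interface, so sampled dust stays in
    # the subcritical small-cluster regime the defect emulates
    if spec.border_dust_fraction > 0:
        boundary = np.zeros(shape, dtype=bool)
        neighbor_label = np.full(shape, -1, dtype=np.int64)
        for dx, dy, dz in _FACE_OFFSETS:
            shifted = np.roll(clean, shift=(dx, dy, dz), axis=(0, 1, 2))
            shifted_dist = np.roll(dist, shift=(dx, dy, dz), axis=(0, 1, 2))
            # roll wraps around; mask out the wrapped border slab
            valid = np.ones(shape, dtype=bool)
            for ax, d in enumerate((dx, dy, dz)):
                if d == 1:
                    valid[tuple(slice(None) if a != ax else slice(0, 1)
                                for a in range(3))] = False
                elif d == -1:
                    valid[tuple(slice(None) if a != ax else slice(-1, None)
                                for a in range(3))] = False
            differs = valid & (shifted != clean) & (dist > shifted_dist)
            newly = differs & ~boundary
            boundary |= differs
            neighbor_label[newly] = shifted[newly]
        cand = np.argwhere(boundary)
        n_dust = int(round(spec.border_dust_fraction * len(cand)))
        if n_dust > 0:
            picked = cand[rng.choice(len(cand), size=n_dust, replace=False)]
            for x, y, z in picked:
                own = int(clean[x, y, z])
                other = int(neighbor_label[x, y, z])
                labels[x, y, z] = np.uint32(spec.suspicious_label_id)
                for mod in spec.modalities:
                    intensity_arrays[mod][x, y, z] = 0.5 * (
                        mean_of[own][mod] + mean_of[other][mod]
                    )
                border_records[(int(x), int(y), int(z))] = own
            _mark_zone(defect_zone, map(tuple, picked.tolist()), radius=1)

    # 4. planted isolated islands with known generating label
    planted: list[PlantedIsland] = []
    for true_label, host_label, size, count in spec.planted_islands:
        host_mask = labels == np.uint32(host_label)
        if true_label == host_label:
            # interior seeds: every 26-neighbor is also host
            eroded = ndimage.binary_erosion(
                host_mask, structure=np.ones((3, 3, 3), bool))
            seed_mask = eroded
        else:
            true_mask = clean == np.uint32(true_label)
            near_true = ndimage.binary_dilation(
                true_mask, structure=np.ones((3, 3, 3), bool))
            seed_mask = host_mask & near_true & ~true_mask
        for _ in range(count):
            placed = False
            for _attempt in range(200):
                free_seed = seed_mask & ~defect_zone
                cand = np.argwhere(free_seed)
                if len(cand) == 0:
                    break
                sx, sy, sz = cand[int(rng.integers(len(cand)))]
                allowed = host_mask & ~defect_zone
                blob = _grow_blob(rng, (int(sx), int(sy), int(sz)), allowed, size)
                if blob is None:
                    continue
                for c in blob:
                    labels[c] = np.uint32(spec.suspicious_label_id)
                    for mod in spec.modalities:
                        intensity_arrays[mod][c] = rng.normal(
                            mean_of[true_label][mod], spec.noise_sd[mod])
                _mark_zone(defect_zone, blob, radius=1)
                host_mask = host_mask & (labels != np.uint32(spec.suspicious_label_id))
                planted.append(PlantedIsland(
                    coords=frozenset(blob), true_label=int(true_label),
                    host_label=int(host_label)))
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place a size-{size} island of true label "
                    f"{true_label} inside host {host_label} after bounded retries")

    # 5. posterior: smoothed, max-normalized indicator of one label
    indicator = (clean == np.uint32(spec.posterior_label)).astype(np.float64)
    smoothed = ndimage.gaussian_filter(indicator, sigma=1.5)
    if smoothed.max() > 0:
        smoothed /= smoothed.max()
    smoothed = np.clip(smoothed, 0.0, 1.0)

    label_volume = LabelVolume(labels, geometry=geom)
    intensity_volumes = [
        IntensityVolume(intensity_arrays[mod], modality_name=mod, geometry=geom)
        for mod in spec.modalities
    ]
    posterior = PosteriorVolume(smoothed, geometry=geom)
    truth = GroundTruth(planted=tuple(planted),
                        border_suspicious_coords=border_records)
    return label_volume, intensity_volumes, posterior, truth
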