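"""Automatic dust cleanup: isolation-aware reassignment of small islands.

Small disconnected components ("dust") of a label are usually segmentation
errors: a voxel clump stranded away from the label's main body. The cleanup
sweep visits each reviewed label l in ascending ID order and, within it,
island sizes s = 1..S (the maximum island voxel count). At each (l, s) pass
the mask of l is recomputed from the *current*, partially edited volume, so
earlier edits are visible to later passes and voxels are never processed
twice.

Isolation awareness: a label may legitimately consist of several densely
packed bodies. When dilation is enabled and s > 1, the binary mask of l is
dilated by a ball whose radius is that of a sphere of volume s,

    r = ceil( (3 s / (4 pi))^(1/3) ),

components are built from the dilated mask, and the component map is then
masked back by the original (non-dilated) mask. Islands that sit within ~r
voxels of another body of l merge with it under dilation, so their masked
size exceeds s and they are skipped — only spatially isolated islands of
size s are reassigned. Dilation is never applied at s = 1 so that all
isolated single voxels are removed. With dilation disabled, components come
from the raw mask, which maximizes the number of islands cleaned (useful
when the goal is to eradicate a catch-all "suspicious" label).

Each candidate island is merged into the bordering label with the most
similar mean intensity (see :mod:`atlasdust.similarity`). If the island's
own label ranks first it is left alone unless ``force_relabel`` is set, in
which case the best *other* border label wins. Every decision — moves,
self-skips, and degenerate unresolvable islands — is appended to a
ChangeLog that can be replayed to reproduce the output bit-exactly.

The algorithm is fully deterministic: no randomness anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .islands import (
    Connectivity,
    IslandRecord,
    ball_element,
    border_context,
)
from .similarity import SimilarityRanking, rank_border_labels
from .volumes import IntensityVolume, LabelVolume, assert_coregistered

__all__ = [
    "CleanupConfig",
    "ChangeRecord",
    "ChangeLog",
    "dilation_radius",
    "cleanup_dust",
    "summarize_changes",
    "replay_changes",
]


@dataclass(frozen=True)
class CleanupConfig:
    """Parameters of one dust-cleanup run.

    max_island_voxel_count
        S, the largest island size to correct (voxels).
    labels_to_review / labels_to_exclude
        Optional label lists; all labels are reviewed when the review list
        is omitted, minus any excluded ones. The lists must be disjoint.
    use_dilation
        Whether to test isolation by dilating the label mask (see module
        docstring). Never applied at s = 1.
    connectivity
        How islands are built (face or full adjacency).
    force_relabel
        Reassign an island even when it is most similar to its own label.
    border_profile_scope
        "shell" (border means over the one-voxel ring) or "component".
    shell_connectivity
        Adjacency used to collect border candidates (default full).
    """

    max_island_voxel_count: int
    labels_to_review: tuple[int, ...] | None = None
    labels_to_exclude: tuple[int, ...] | None = None
    use_dilation: bool = True
    connectivity: Connectivity = Connectivity.FULL
    force_relabel: bool = False
    border_profile_scope: str = "shell"
    shell_connectivity: Connectivity = Connectivity.FULL

    def __post_init__(self) -> None:
        if self.max_island_voxel_count < 1:
            raise ValueError("max_island_voxel_count must be >= 1")
        if self.labels_to_review is not None:
            object.__setattr__(self, "labels_to_review", tuple(int(x) for x in self.labels_to_review))
        if self.labels_to_exclude is not None:
            object.__setattr__(self, "labels_to_exclude", tuple(int(x) for x in self.labels_to_exclude))
        if self.labels_to_review and self.labels_to_exclude:
            overlap = set(self.labels_to_review) & set(self.labels_to_exclude)
            if overlap:
                raise ValueError(f"review and exclude lists overlap: {sorted(overlap)}")
        if isinstance(self.connectivity, str):
            object.__setattr__(self, "connectivity", Connectivity(self.connectivity))
        if isinstance(self.shell_connectivity, str):
            object.__setattr__(self, "shell_connectivity", Connectivity(self.shell_connectivity))


@dataclass(frozen=True)
class ChangeRecord:
    """One island decision: a move, a self-skip, or an unresolvable island.

    ``new_label == old_label`` marks a no-op (self-skip or unresolvable).
    """

    island: IslandRecord
    old_label: int
    new_label: int
    distance: float
    pass_size: int
    ranking_snapshot: SimilarityRanking | None
    note: str = "moved"

    @property
    def moved(self) -> bool:
        return self.new_label != self.old_label


@dataclass
class ChangeLog:
    """Audit trail of a label-editing run.

    Replaying ``records`` in order against the input volume reproduces the
    output volume exactly; per-label voxel counts reconcile as
    output = input - lost + gained.
    """

    records: list[ChangeRecord] = field(default_factory=list)
    config: object | None = None
    input_counts: dict[int, int] = field(default_factory=dict)
    output_counts: dict[int, int] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def voxels_moved(self) -> dict[tuple[int, int], int]:
        """Voxel counts per (old_label, new_label) pair, moves only."""
        out: dict[tuple[int, int], int] = {}
        for r in self.records:
            if r.moved:
                key = (r.old_label, r.new_label)
                out[key] = out.get(key, 0) + r.island.size
        return out

    def to_json_dict(self) -> dict:
        """JSON-serializable form (coordinates as lists)."""
        cfg = self.config
        if hasattr(cfg, "__dataclass_fields__"):
            cfg = {
                k: (v.value if isinstance(v, Connectivity) else v)
                for k, v in vars(cfg).items()
            }
        return {
            "config": cfg,
            "input_counts": {str(k): v for k, v in sorted(self.input_counts.items())},
            "output_counts": {str(k): v for k, v in sorted(self.output_counts.items())},
            "meta": self.meta,
            "records": [
                {
                    "old_label": r.old_label,
                    "new_label": r.new_label,
                    "distance": None if math.isnan(r.distance) else r.distance,
                    "pass_size": r.pass_size,
                    "note": r.note,
                    "size": r.island.size,
                    "voxels": sorted(map(list, r.island.voxel_coords)),
                }
                for r in self.records
            ],
        }


def dilation_radius(s: int) -> int:
    """Ceiling of the radius of a sphere of volume ``s`` voxels.

    Defined for s >= 2; islands of a single voxel are never dilated.
    Monotonically non-decreasing in s.
    """
    if s < 2:
        raise ValueError("dilation radius is defined for island sizes >= 2")
    return math.ceil((3.0 * s / (4.0 * math.pi)) ** (1.0 / 3.0))


def _count_labels(arr: np.ndarray) -> dict[int, int]:
    ids, counts = np.unique(arr, return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts)}


def _candidate_islands(
    vox: np.ndarray, label_id: int, s: int, config: CleanupConfig
) -> list[IslandRecord]:
    """Islands of masked size exactly s at pass s, per the dilation regime."""
    mask = vox == np.uint32(label_id)
    if not mask.any():
        return []
    structure = config.connectivity.structure()
    if config.use_dilation and s > 1:
        dil = ndimage.binary_dilation(mask, structure=ball_element(dilation_radius(s)))
        comp_map, n = ndimage.label(dil, structure=structure)
        comp_map = np.where(mask, comp_map, 0)  # mask back by the non-dilated mask
    else:
        comp_map, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return []
    sizes = np.bincount(comp_map.ravel(), minlength=n + 1)
    islands = []
    for cid in np.nonzero(sizes[1:] == s)[0] + 1:
        coords = frozenset(map(tuple, np.argwhere(comp_map == cid).tolist()))
        arr = np.array(sorted(coords))
        bbox = (tuple(arr.min(axis=0).tolist()), tuple(arr.max(axis=0).tolist()))
        islands.append((min(coords), coords, bbox))
    islands.sort(key=lambda t: t[0])
    return [
        IslandRecord(label_id=int(label_id), island_index=i, size=s,
                     voxel_coords=coords, bounding_box=bbox)
        for i, (_, coords, bbox) in enumerate(islands, start=1)
    ]


def cleanup_dust(
    v: LabelVolume,
    intensities: Sequence[IntensityVolume],
    config: CleanupConfig,
) -> tuple[LabelVolume, ChangeLog]:
    """Run the dust-cleanup sweep; returns the edited volume and its log.

    Edits are sequential and in-place: each island is reassigned before the
    next is ranked, and the label mask is recomputed at every (l, s) pass.
    Excluded labels are never reviewed but may still receive voxels.
    """
    if not intensities:
        raise ValueError("at least one intensity volume is required")
    assert_coregistered([v, *intensities])
    out = v.copy()
    vox = out.voxels
    log = ChangeLog(config=config, input_counts=_count_labels(v.voxels))

    if config.labels_to_review is not None:
        labels = sorted(set(config.labels_to_review))
    else:
        labels = v.label_ids
    if config.labels_to_exclude:
        labels = [l for l in labels if l not in set(config.labels_to_exclude)]

    for label_id in labels:
        for s in range(1, config.max_island_voxel_count + 1):
            for island in _candidate_islands(vox, label_id, s, config):
                ctx = border_context(out, island, config.shell_connectivity)
                if not ctx.border_labels:
                    log.records.append(ChangeRecord(
                        island=island, old_label=label_id, new_label=label_id,
                        distance=float("nan"), pass_size=s, ranking_snapshot=None,
                        note="unresolvable-no-border"))
                    continue
                ranking = rank_border_labels(
                    out, island, intensities,
                    border_profile_scope=config.border_profile_scope,
                    context=ctx)
                best = ranking.best_label
                if best == label_id and not config.force_relabel:
                    log.records.append(ChangeRecord(
                        island=island, old_label=label_id, new_label=label_id,
                        distance=ranking.candidates[0][1], pass_size=s,
                        ranking_snapshot=ranking, note="self-skip"))
                    continue
                if best == label_id and config.force_relabel:
                    forced = ranking.best_label_excluding(label_id)
                    if forced is None:
                        # island of l ringed entirely by another body of l
                        log.records.append(ChangeRecord(
                            island=island, old_label=label_id, new_label=label_id,
                            distance=float("nan"), pass_size=s,
                            ranking_snapshot=ranking, note="unresolvable-self-only"))
                        continue
                    best = forced
                dist = next(d for lab, d, _ in ranking.candidates if lab == best)
                for c in island.voxel_coords:
                    vox[c] = np.uint32(best)
                log.records.append(ChangeRecord(
                    island=island, old_label=label_id, new_label=best,
                    distance=dist, pass_size=s, ranking_snapshot=ranking))

    log.output_counts = _count_labels(vox)
    return out, log


def summarize_changes(log: ChangeLog) -> dict:
    """Per-label accounting of a ChangeLog.

    Returns islands moved/skipped per source label, voxel counts per
    (old -> new) pair, and a histogram of processed island sizes.
    """
    islands_moved: dict[int, int] = {}
    islands_skipped: dict[int, int] = {}
    size_histogram: dict[int, int] = {}
    for r in log.records:
        size_histogram[r.island.size] = size_histogram.get(r.island.size, 0) + 1
        bucket = islands_moved if r.moved else islands_skipped
        bucket[r.old_label] = bucket.get(r.old_label, 0) + 1
    return {
        "islands_moved": islands_moved,
        "islands_skipped": islands_skipped,
        "voxels_moved": log.voxels_moved(),
        "size_histogram": size_histogram,
        "total_voxels_moved": sum(log.voxels_moved().values()),
    }


def replay_changes(v_input: LabelVolume, log: ChangeLog) -> LabelVolume:
    """Reapply a ChangeLog to the input volume; reproduces the output exactly."""
    out = v_input.copy()
    for r in log.records:
        if r.moved:
            for c in r.island.voxel_coords:
                out.voxels[c] = np.uint32(r.new_label)
    return out
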