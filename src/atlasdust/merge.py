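"""Label merge: posterior-gated reassignment of a source label to a target.

The merge operation reassigns voxels of a *source* ("suspicious") label to
a *target* label where the two are connected: a combined binary mask of
source ∪ target is built, its connected components are found, and source
voxels inside eligible components become the target label. Eligibility is
either the single largest combined component, or every component that
contains at least one target voxel (so pure-source components far from the
target stay untouched). A literal mode that relabels source voxels in
*every* component — reducing the merge to unconditional relabeling — is
available via ``all_components_literal``.

An optional posterior-probability (or binary-mask) volume vetoes the merge
voxel-by-voxel: a source voxel whose posterior falls below the minimum
threshold keeps its source label. Raising the threshold can only shrink
the changed set.

Also provides the multi-modal intensity-range mask builder used to carve,
e.g., a venous-blood mask from T1w/T2w windows for merging into background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .cleanup import ChangeLog, ChangeRecord, _count_labels
from .islands import Connectivity, IslandRecord
from .volumes import (
    IntensityVolume,
    LabelVolume,
    PosteriorVolume,
    assert_coregistered,
)

__all__ = [
    "MergeConfig",
    "IntensityRangeSpec",
    "merge_labels",
    "intensity_range_mask",
]


@dataclass(frozen=True)
class MergeConfig:
    """Parameters of one merge run.

    ``min_threshold`` may be given only together with ``posterior``;
    defaults to 0.0 when a posterior is supplied without a threshold.
    """

    target_label: int
    source_label: int
    largest_island_only: bool = True
    posterior: PosteriorVolume | None = None
    min_threshold: float | None = None
    connectivity: Connectivity = Connectivity.FULL
    all_components_literal: bool = False

    def __post_init__(self) -> None:
        if self.target_label == self.source_label:
            raise ValueError("target and source labels must differ")
        if self.min_threshold is not None:
            if self.posterior is None:
                raise ValueError("min_threshold requires a posterior volume")
            if not 0.0 <= self.min_threshold <= 1.0:
                raise ValueError("min_threshold must lie in [0, 1]")
        if isinstance(self.connectivity, str):
            object.__setattr__(self, "connectivity", Connectivity(self.connectivity))


@dataclass(frozen=True)
class IntensityRangeSpec:
    """Closed per-modality intensity intervals, ANDed across modalities."""

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("at least one modality interval is required")
        for name, (low, high) in self.ranges.items():
            if low > high:
                raise ValueError(f"interval for {name!r} has low > high")


def _record_for(coords: np.ndarray, old: int, new: int, index: int) -> ChangeRecord:
    cset = frozenset(map(tuple, coords.tolist()))
    bbox = (tuple(coords.min(axis=0).tolist()), tuple(coords.max(axis=0).tolist()))
    island = IslandRecord(label_id=old, island_index=index, size=len(cset),
                          voxel_coords=cset, bounding_box=bbox)
    return ChangeRecord(island=island, old_label=old, new_label=new,
                        distance=float("nan"), pass_size=len(cset),
                        ranking_snapshot=None, note="merge")


def merge_labels(v: LabelVolume, config: MergeConfig) -> tuple[LabelVolume, ChangeLog]:
    """Reassign source-label voxels to the target label where connected.

    Source absent from the volume is a no-op with an empty log. Only source
    voxels can change, and any change sets them to the target label.
    """
    if config.posterior is not None:
        assert_coregistered([v, config.posterior])
    out = v.copy()
    log = ChangeLog(config=config, input_counts=_count_labels(v.voxels))
    src = np.uint32(config.source_label)
    tgt = np.uint32(config.target_label)
    source_mask = v.voxels == src
    target_mask = v.voxels == tgt
    if not source_mask.any():
        log.output_counts = dict(log.input_counts)
        log.meta["no_op"] = "source label absent"
        return out, log

    combined = source_mask | target_mask
    comp_map, n = ndimage.label(combined, structure=config.connectivity.structure())
    if config.largest_island_only:
        sizes = np.bincount(comp_map.ravel(), minlength=n + 1)
        sizes[0] = 0
        biggest = sizes.max()
        tied = np.nonzero(sizes == biggest)[0]
        if len(tied) > 1:
            # tie → the component containing the lexicographically smallest coord
            order = np.argwhere(np.isin(comp_map, tied))
            first = min(map(tuple, order.tolist()))
            eligible = {int(comp_map[first])}
        else:
            eligible = {int(tied[0])}
    elif config.all_components_literal:
        eligible = set(range(1, n + 1))
    else:
        eligible = {int(c) for c in np.unique(comp_map[target_mask])} - {0}

    threshold = config.min_threshold
    if config.posterior is not None and threshold is None:
        threshold = 0.0

    gated = 0
    for index, cid in enumerate(sorted(eligible), start=1):
        sel = source_mask & (comp_map == cid)
        if config.posterior is not None:
            vetoed = sel & (config.posterior.voxels < threshold)
            gated += int(vetoed.sum())
            sel &= ~vetoed
        if not sel.any():
            continue
        coords = np.argwhere(sel)
        out.voxels[sel] = tgt
        log.records.append(_record_for(coords, config.source_label,
                                       config.target_label, index))

    log.meta["voxels_gated_by_posterior"] = gated
    log.output_counts = _count_labels(out.voxels)
    return out, log


def intensity_range_mask(
    intensities: Sequence[IntensityVolume], spec: IntensityRangeSpec
) -> PosteriorVolume:
    """Binary mask: 1 iff every specified modality lies in its closed interval.

    The spec may constrain a subset of the supplied modalities; constrained
    modalities are ANDed. Unknown modality names in the spec are an error.
    """
    if len(intensities) >= 2:
        assert_coregistered(list(intensities))
    by_name = {iv.modality_name: iv for iv in intensities}
    missing = set(spec.ranges) - set(by_name)
    if missing:
        raise ValueError(f"spec names modalities not supplied: {sorted(missing)}")
    mask = np.ones(intensities[0].voxels.shape, dtype=bool)
    for name, (low, high) in spec.ranges.items():
        vals = by_name[name].voxels
        mask &= (vals >= low) & (vals <= high)
    return PosteriorVolume(mask.astype(np.float64), geometry=intensities[0].geometry)
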