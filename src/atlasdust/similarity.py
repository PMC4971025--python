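"""Mean-intensity similarity metric and border-label ranking.

For a questionable region (an island of voxels) the candidate list of
neighboring labels is ordered by the Euclidean distance between mean
intensity vectors,

    d = sqrt( sum_i (T_i - B_i)^2 )

where T_i is the mean intensity of the target region in modality i and B_i
the mean intensity of a border label's region in modality i. The border
label with the smallest d has the closest average intensity to the target
and is the top relabeling suggestion. The ordering is invariant to whether
the radical is applied, since sqrt is monotone.

B_i can be computed over the border label's voxels in the island's shell
only (``scope="shell"``, the default — robust to intensity inhomogeneity
across large structures) or over the full connected component(s) of that
label touching the shell (``scope="component"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import NoBorderError
from .islands import BorderContext, Connectivity, IslandRecord, border_context
from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "RegionIntensityProfile",
    "SimilarityRanking",
    "region_profile",
    "similarity_distance",
    "rank_border_labels",
]


@dataclass(frozen=True)
class RegionIntensityProfile:
    """Per-modality mean intensity over a set of voxel coordinates."""

    region_coords: frozenset[tuple[int, int, int]]
    means: dict[str, float]
    n_voxels: int


@dataclass(frozen=True)
class SimilarityRanking:
    """Candidates ordered by ascending distance d, ties by ascending label."""

    target: RegionIntensityProfile
    candidates: tuple[tuple[int, float, RegionIntensityProfile], ...]

    @property
    def best_label(self) -> int:
        return self.candidates[0][0]

    def best_label_excluding(self, label_id: int) -> int | None:
        """Top-ranked candidate that is not ``label_id``, or None."""
        for lab, _, _ in self.candidates:
            if lab != label_id:
                return lab
        return None


def region_profile(
    coords: Iterable[tuple[int, int, int]],
    intensities: Sequence[IntensityVolume],
) -> RegionIntensityProfile:
    """Arithmetic mean of each modality over ``coords``."""
    coords = frozenset(coords)
    if not coords:
        raise ValueError("cannot profile an empty region")
    idx = tuple(np.asarray(a) for a in zip(*coords))
    means = {iv.modality_name: float(iv.voxels[idx].mean()) for iv in intensities}
    return RegionIntensityProfile(region_coords=coords, means=means, n_voxels=len(coords))


def similarity_distance(
    target: RegionIntensityProfile, border: RegionIntensityProfile
) -> float:
    """Euclidean distance between the two mean-intensity vectors."""
    if set(target.means) != set(border.means):
        raise ValueError(
            f"modality sets differ: {sorted(target.means)} vs {sorted(border.means)}"
        )
    return math.sqrt(
        sum((target.means[m] - border.means[m]) ** 2 for m in target.means)
    )


def _component_scope_coords(
    v: LabelVolume, label_id: int, shell_coords_of_label: frozenset
) -> frozenset:
    """All voxels of the 26-connected components of label_id touching the shell."""
    mask = v.voxels == np.uint32(label_id)
    comp_map, _ = ndimage.label(mask, structure=Connectivity.FULL.structure())
    wanted = {int(comp_map[c]) for c in shell_coords_of_label}
    wanted.discard(0)
    sel = np.isin(comp_map, sorted(wanted))
    return frozenset(map(tuple, np.argwhere(sel).tolist()))


def rank_border_labels(
    v: LabelVolume,
    island: IslandRecord,
    intensities: Sequence[IntensityVolume],
    border_profile_scope: str = "shell",
    shell_connectivity: Connectivity = Connectivity.FULL,
    context: BorderContext | None = None,
) -> SimilarityRanking:
    """Rank every label bordering an island by intensity similarity.

    One candidate per distinct border label; sorted by ascending d, ties
    broken by ascending label ID. ``context`` may supply a precomputed
    BorderContext to avoid recomputation.
    """
    if border_profile_scope not in ("shell", "component"):
        raise ValueError(f"unknown border_profile_scope {border_profile_scope!r}")
    if not intensities:
        raise ValueError("at least one intensity volume is required")
    ctx = context if context is not None else border_context(v, island, shell_connectivity)
    if not ctx.border_labels:
        raise NoBorderError(
            f"island {island.island_index} of label {island.label_id} has no border"
        )
    target = region_profile(island.voxel_coords, intensities)
    candidates = []
    for lab, shell_coords in ctx.border_labels.items():
        if border_profile_scope == "component":
            coords = _component_scope_coords(v, lab, shell_coords)
        else:
            coords = shell_coords
        prof = region_profile(coords, intensities)
        candidates.append((lab, similarity_distance(target, prof), prof))
    candidates.sort(key=lambda c: (c[1], c[0]))
    return SimilarityRanking(target=target, candidates=tuple(candidates))
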