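"""Shared fixtures and brute-force oracles.

The oracles here are deliberately independent of the package internals:
flood fill with explicit neighbor offsets, shell enumeration with
recomputed means, and naive relabeling — so agreement with the package is
a two-route check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

import atlasdust as ad

FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
FULL_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def offsets_for(conn: ad.Connectivity):
    return FACE_OFFSETS if conn is ad.Connectivity.FACE else FULL_OFFSETS


def flood_fill_components(mask: np.ndarray, offsets) -> list[frozenset]:
    """BFS connected components of a boolean grid; independent oracle."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            c = stack.pop()
            comp.add(c)
            for off in offsets:
                n = tuple(c[i] + off[i] for i in range(3))
                if all(0 <= n[i] < mask.shape[i] for i in range(3)):
                    if mask[n] and not seen[n]:
                        seen[n] = True
                        stack.append(n)
        comps.append(frozenset(comp))
    return comps


def oracle_rank(v: ad.LabelVolume, island_coords, intensity_volumes):
    """Rank border labels by enumerating the 26-shell and recomputing means."""
    island = set(island_coords)
    shell = set()
    for c in island:
        for off in FULL_OFFSETS:
            n = tuple(c[i] + off[i] for i in range(3))
            if all(0 <= n[i] < v.voxels.shape[i] for i in range(3)) and n not in island:
                shell.add(n)
    by_label: dict[int, list] = {}
    for c in shell:
        by_label.setdefault(int(v.voxels[c]), []).append(c)

    def mean_vec(coords):
        return [sum(float(iv.voxels[c]) for c in coords) / len(coords)
                for iv in intensity_volumes]

    t = mean_vec(island)
    ranked = []
    for lab, coords in by_label.items():
        b = mean_vec(coords)
        d = sum((ti - bi) ** 2 for ti, bi in zip(t, b)) ** 0.5
        ranked.append((d, lab))
    ranked.sort()
    return [(lab, d) for d, lab in ranked]


def random_label_grid(rng: np.random.Generator, shape=(4, 4, 4), n_labels=4):
    arr = rng.integers(0, n_labels, size=shape).astype(np.uint32)
    return ad.LabelVolume(arr)


def random_intensities(rng: np.random.Generator, shape=(4, 4, 4), modalities=("T1w", "T2w")):
    return [
        ad.IntensityVolume(rng.normal(100.0, 30.0, size=shape), modality_name=m)
        for m in modalities
    ]


@pytest.fixture(scope="session")
def defect_phantom():
    """One 64³ phantom with border dust and planted islands of known truth."""
    spec = ad.PhantomSpec(
        seed=7,
        planted_islands=((5, 17, 1, 8), (24, 17, 2, 8), (17, 17, 3, 4)),
    )
    return spec, ad.generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    spec = ad.PhantomSpec(seed=3, border_dust_fraction=0.0)
    return spec, ad.generate_phantom(spec)
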