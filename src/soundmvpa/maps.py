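"""Discriminative, category-selective and conjunction brain maps.

A discriminative map accumulates, per voxel, how many fits (subject x
repetition) retained the voxel in their selected subset.  A category-selective
map contrasts 7-class (all categories) fits with 6-class fits that omit one
category: voxels selected for the full problem but not for the reduced one
are attributed to the omitted category, kept only if they survive in more
than one repetition and more than one subject.  Conjunction maps intersect
the voxel sets of two analyses.  Clusters are connected components of a
voxel set under face (6-), edge (18-) or corner (26-) connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid

__all__ = [
    "DiscriminativeMap",
    "SelectiveMap",
    "Cluster",
    "discriminative_map",
    "category_selective_map",
    "conjunction_map",
    "find_clusters",
]


@dataclass(eq=False)
class DiscriminativeMap:
    """Per-voxel survival counts over a family of fits."""

    grid: VoxelGrid
    survival_count: np.ndarray  # length p
    provenance: str = ""

    def voxels(self, min_count: int = 1) -> np.ndarray:
        """Sorted voxel indices with survival count >= ``min_count``."""
        return np.flatnonzero(self.survival_count >= min_count)


@dataclass(eq=False)
class SelectiveMap:
    """Voxels attributed to one category by the 7-vs-6-class comparison."""

    category: object
    voxel_set: np.ndarray  # sorted voxel indices
    survival_count: np.ndarray  # length p, nonzero only on voxel_set
    grid: VoxelGrid = None

    def voxels(self, min_count: int = 1) -> np.ndarray:
        return self.voxel_set


@dataclass(eq=False)
class Cluster:
    """One connected component of a voxel set."""

    voxel_indices: np.ndarray
    size: int
    center_mm: np.ndarray


def _selected(fit) -> np.ndarray:
    return np.asarray(fit.selected_voxels, dtype=int)


def discriminative_map(fits, grid: VoxelGrid, provenance: str = "") -> DiscriminativeMap:
    """Accumulate selected voxels over fits into survival counts."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    counts = np.zeros(grid.p, dtype=int)
    for fit in fits:
        if getattr(fit, "n_features", grid.p) != grid.p:
            raise ValueError("fit was trained on a different grid")
        counts[_selected(fit)] += 1
    return DiscriminativeMap(grid=grid, survival_count=counts, provenance=provenance)


def category_selective_map(
    fits_all7: dict,
    fits_without_c: dict,
    category,
    min_reps: int = 2,
    min_subjects: int = 2,
    grid: VoxelGrid = None,
) -> SelectiveMap:
    """Contrast all-category fits with fits lacking one category.

    Both inputs map ``(subject, repetition)`` keys to fits; keys must match
    pairwise.  Per key the candidate voxels are the set difference
    ``selected(all classes) - selected(without category)``; a voxel enters
    the map if it is a candidate in at least ``min_reps`` distinct
    repetitions and ``min_subjects`` distinct subjects ("more than one"
    survival rule with the default thresholds of 2).
    """
    if set(fits_all7) != set(fits_without_c):
        raise ValueError("7-class and 6-class fits must share (subject, rep) keys")
    if not fits_all7:
        raise ValueError("no fits supplied")
    p = None
    for key, f7 in fits_all7.items():
        f6 = fits_without_c[key]
        c7 = list(f7.final_model.class_labels)
        c6 = list(f6.final_model.class_labels)
        if category not in c7:
            raise ValueError(f"category {category!r} missing from 7-class fit {key}")
        if category in c6 or set(c6) != set(c7) - {category}:
            raise ValueError(
                f"6-class fit {key} must exclude exactly {category!r}"
            )
        p = f7.n_features if p is None else p
        if f7.n_features != p or f6.n_features != p:
            raise ValueError("fits trained on mismatched grids")
    counts = np.zeros(p, dtype=int)
    vox_subjects = [set() for _ in range(p)]
    vox_reps = [set() for _ in range(p)]
    for (subject, rep), f7 in fits_all7.items():
        diff = np.setdiff1d(_selected(f7), _selected(fits_without_c[(subject, rep)]))
        counts[diff] += 1
        for v in diff:
            vox_subjects[v].add(subject)
            vox_reps[v].add(rep)
    kept = np.array(
        [
            v
            for v in np.flatnonzero(counts)
            if len(vox_reps[v]) >= min_reps and len(vox_subjects[v]) >= min_subjects
        ],
        dtype=int,
    )
    survival = np.zeros(p, dtype=int)
    survival[kept] = counts[kept]
    return SelectiveMap(
        category=category, voxel_set=kept, survival_count=survival, grid=grid
    )


def _as_voxel_set(m, min_count):
    if isinstance(m, (DiscriminativeMap, SelectiveMap)):
        return np.asarray(m.voxels(min_count), dtype=int), getattr(m, "grid", None)
    return np.unique(np.asarray(list(m), dtype=int)), None


def conjunction_map(mapA, mapB, min_count: int = 1) -> np.ndarray:
    """Intersection of two maps' (survival-thresholded) voxel sets."""
    va, ga = _as_voxel_set(mapA, min_count)
    vb, gb = _as_voxel_set(mapB, min_count)
    if ga is not None and gb is not None and ga is not gb:
        if ga.dims != gb.dims or not np.allclose(ga.affine, gb.affine):
            raise ValueError("conjunction of maps on mismatched grids")
    return np.intersect1d(va, vb)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def find_clusters(voxel_set, grid: VoxelGrid, connectivity: int = 6) -> list:
    """Connected components of a voxel set, largest first.

    Components are found under the requested 3-D connectivity (6 = faces,
    18 = +edges, 26 = +corners), sorted by size descending with ties broken
    by the lowest member voxel index; centers of mass are reported in mm
    through the grid affine.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    voxel_set = np.asarray(sorted(set(int(v) for v in np.asarray(voxel_set).ravel())))
    if voxel_set.size == 0:
        return []
    if voxel_set.min() < 0 or voxel_set.max() >= grid.p:
        raise ValueError("voxel indices outside the mask linearization")
    vol = grid.to_volume(np.isin(np.arange(grid.p), voxel_set).astype(np.int8))
    labeled, n = ndimage.label(vol, structure=_STRUCTURES[connectivity])
    lab_vec = grid.from_volume(labeled)
    clusters = []
    for lab in range(1, n + 1):
        members = np.flatnonzero(lab_vec == lab)
        coords = grid.coords()[members]
        center = grid.voxel_to_mm(coords.mean(axis=0))[0]
        clusters.append(
            Cluster(voxel_indices=members, size=len(members), center_mm=center)
        )
    clusters.sort(key=lambda c: (-c.size, int(c.voxel_indices.min())))
    return clusters
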