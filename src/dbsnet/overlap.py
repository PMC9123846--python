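"""Multi-target overlap mapping and network-node extraction.

The binarised per-target connectivity maps are intersected voxelwise to
outline the territory every target is significantly connected to; discrete
node regions are then carved out of that territory by 3-D connected-component
analysis, and combined with the anatomical seed regions into one disjoint
node atlas for the graph stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
from skimage import measure

from .seedmap import SeedMask, StatMap, _check_grid

__all__ = [
    "NodeAtlas",
    "intersect_maps",
    "extract_components",
    "assemble_network_nodes",
    "dice",
]


@dataclass
class NodeAtlas:
    """Named, pairwise-disjoint 3-D regions on a shared grid.

    ``provenance`` records per region whether it is an anatomical seed or an
    overlap-derived component.
    """

    labels: List[str]
    masks: Dict[str, np.ndarray]
    affine: np.ndarray
    provenance: Dict[str, str] = field(default_factory=dict)
    flags: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(self.labels) != sorted(self.masks):
            raise ValueError("labels and masks disagree")
        claimed = None
        for name in self.labels:
            m = np.asarray(self.masks[name]).astype(bool)
            self.masks[name] = m
            if not m.any():
                raise ValueError(f"region {name!r} is empty")
            if claimed is None:
                claimed = np.zeros(m.shape, dtype=bool)
            if (claimed & m).any():
                raise ValueError(f"region {name!r} overlaps another region")
            claimed |= m

    def __len__(self) -> int:
        return len(self.labels)

    def label_image(self) -> np.ndarray:
        """Integer-coded label volume: 0 background, i+1 for labels[i]."""
        out = np.zeros(self.masks[self.labels[0]].shape, dtype=np.int32)
        for i, name in enumerate(self.labels):
            out[self.masks[name]] = i + 1
        return out


def intersect_maps(maps: List[StatMap]) -> StatMap:
    """Voxelwise logical AND of two or more binary maps on a shared grid."""
    if len(maps) < 2:
        raise ValueError("intersect_maps needs at least 2 maps")
    first = maps[0]
    out = np.ones(first.grid_shape, dtype=bool)
    for m in maps:
        if m.kind != "binary":
            raise ValueError("intersect_maps expects binary maps")
        _check_grid(first.grid_shape, first.affine, m.grid_shape, m.affine)
        out &= m.data.astype(bool)
    return StatMap(
        kind="binary",
        data=out.astype(np.float64),
        affine=first.affine,
        source_seed="+".join(m.source_seed for m in maps if m.source_seed),
        qc={"overlap_voxels": int(out.sum())},
    )


def extract_components(
    binary_map: StatMap, connectivity: int = 26, min_voxels: int = 5,
    name_prefix: str = "overlap",
) -> NodeAtlas:
    """Connected components of a binary map as labelled node regions.

    ``connectivity`` is the 3-D neighbourhood (6 = faces only, 26 = faces,
    edges and corners); components smaller than ``min_voxels`` are dropped.
    Labelling is deterministic: components sorted by descending voxel count,
    ties broken by lexicographically smallest voxel index. An empty input
    yields an empty atlas with a flag rather than an error.
    """
    if binary_map.kind != "binary":
        raise ValueError("extract_components expects a binary map")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    skimage_conn = 1 if connectivity == 6 else 3
    data = binary_map.data.astype(bool)
    if not data.any():
        return NodeAtlas(labels=[], masks={}, affine=binary_map.affine,
                         flags={"empty_input": 1})
    labelled = measure.label(data, connectivity=skimage_conn)
    comps = []
    for lab in range(1, labelled.max() + 1):
        mask = labelled == lab
        size = int(mask.sum())
        if size < min_voxels:
            continue
        first_voxel = tuple(int(c) for c in np.argwhere(mask)[0])
        comps.append((size, first_voxel, mask))
    comps.sort(key=lambda c: (-c[0], c[1]))
    labels, masks, prov = [], {}, {}
    for i, (_, _, mask) in enumerate(comps):
        name = f"{name_prefix}_{i + 1:02d}"
        labels.append(name)
        masks[name] = mask
        prov[name] = "overlap_component"
    flags = {"components_discarded": int(labelled.max()) - len(comps)}
    return NodeAtlas(labels=labels, masks=masks, affine=binary_map.affine,
                     provenance=prov, flags=flags)


def assemble_network_nodes(
    seeds: List[SeedMask], overlap_atlas: NodeAtlas
) -> NodeAtlas:
    """Union atlas of seed regions and overlap components, seeds first.

    Voxels claimed by both a seed and an overlap component go to the seed
    (seeds are the anchored anatomy); components left empty after that are
    dropped. Region names must be unique across the union.
    """
    if not seeds:
        raise ValueError("at least one seed is required")
    affine = seeds[0].affine
    names = [s.name for s in seeds] + list(overlap_atlas.labels)
    if len(set(names)) != len(names):
        raise ValueError("duplicate region names between seeds and overlap atlas")
    seed_union = np.zeros(seeds[0].mask.shape, dtype=bool)
    labels, masks, prov = [], {}, {}
    for s in seeds:
        _check_grid(seeds[0].mask.shape, affine, s.mask.shape, s.affine)
        if (seed_union & s.mask).any():
            raise ValueError(f"seed {s.name!r} overlaps another seed")
        labels.append(s.name)
        masks[s.name] = s.mask.copy()
        prov[s.name] = "seed"
        seed_union |= s.mask
    absorbed = 0
    for name in overlap_atlas.labels:
        _check_grid(seeds[0].mask.shape, affine,
                    overlap_atlas.masks[name].shape, overlap_atlas.affine)
        trimmed = overlap_atlas.masks[name] & ~seed_union
        if not trimmed.any():
            absorbed += 1
            continue
        labels.append(name)
        masks[name] = trimmed
        prov[name] = overlap_atlas.provenance.get(name, "overlap_component")
    return NodeAtlas(labels=labels, masks=masks, affine=affine,
                     provenance=prov, flags={"components_absorbed": absorbed})


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
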