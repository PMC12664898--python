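"""Custom atlas annotations and region bookkeeping.

Three annotations mirror the customizations used for region-resolved
proliferation mapping:

* **ventricular-wall (SVZ) layer** — the one-voxel-thick layer of a parent
  region (caudoputamen) facing an adjacent region (lateral ventricle) is
  relabelled with a reserved custom ID (default 5);
* **consensus marker mask** — voxels positive for a marker (e.g. a nestin
  reporter) in at least ``min_votes`` of N registered brains get the custom ID;
* **hemispheres** — left-hemisphere voxels get ``base ID + 1,000,000,000`` so
  left/right statistics can be separated; right IDs stay unedited.

All annotations are pure relabelings: voxel positions never change.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .core import HEMISPHERE_OFFSET, OUTSIDE_ID, LabelAtlas, NucleusSet

logger = logging.getLogger(__name__)

__all__ = [
    "lookup_regions",
    "region_volumes",
    "annotate_svz",
    "annotate_consensus",
    "annotate_hemispheres",
]


def lookup_regions(points: NucleusSet, atlas: LabelAtlas, level: str = "leaf") -> np.ndarray:
    """Region ID under each point (half-open voxel binning); 0 when outside.

    ``level="top"`` replaces each leaf ID by its depth-1 ancestor in the
    ontology; hemisphere-offset IDs keep their offset through aggregation.
    """
    if points.space != "atlas":
        raise ValueError(f"points must be tagged 'atlas', got {points.space!r}")
    if level not in ("leaf", "top"):
        raise ValueError("level must be 'leaf' or 'top'")
    idx = atlas.point_to_index(points.coords())
    ids = np.zeros(len(idx), dtype=np.int64)
    inside = idx[:, 0] >= 0
    ids[inside] = atlas.labels[tuple(idx[inside].T)]
    if level == "top":
        offset = atlas.hemisphere_offset
        out = np.zeros_like(ids)
        for rid in np.unique(ids):
            if rid == OUTSIDE_ID:
                continue
            base = int(rid % offset) if rid >= offset else int(rid)
            if base not in atlas.ontology:
                raise ValueError(f"label {rid} absent from ontology")
            top = atlas.ontology.top_level_ancestor(base)
            out[ids == rid] = top + (offset if rid >= offset else 0)
        ids = out
    else:
        present = set(np.unique(ids).tolist()) - {OUTSIDE_ID}
        offset = atlas.hemisphere_offset
        for rid in present:
            base = int(rid % offset) if rid >= offset else int(rid)
            if base not in atlas.ontology:
                raise ValueError(f"label {rid} absent from ontology")
    return ids


def region_volumes(atlas: LabelAtlas, level: str = "leaf") -> dict[int, float]:
    """Region volumes in mm^3 (voxel count x voxel volume)."""
    if level not in ("leaf", "top"):
        raise ValueError("level must be 'leaf' or 'top'")
    ids, counts = np.unique(atlas.labels, return_counts=True)
    vv = atlas.voxel_volume_mm3
    out: dict[int, float] = {}
    offset = atlas.hemisphere_offset
    for rid, cnt in zip(ids.tolist(), counts.tolist()):
        if rid == OUTSIDE_ID:
            continue
        key = rid
        if level == "top":
            base = rid % offset if rid >= offset else rid
            key = atlas.ontology.top_level_ancestor(int(base)) \
                + (offset if rid >= offset else 0)
        out[key] = out.get(key, 0.0) + cnt * vv
    return out


def annotate_svz(atlas: LabelAtlas, parent_id: int, adjacent_id: int,
                 new_id: int | None = None, exclude_from_parent: bool = True,
                 connectivity: int = 6) -> LabelAtlas:
    """Relabel the parent-region voxels facing the adjacent region.

    With face (6-)connectivity the relabelled set is exactly a one-voxel
    layer on the interface — the automated counterpart of hand-painting a
    layer of single pixels on the ventricular wall.  The new record enters
    the ontology under the parent; ``exclude_from_parent=False`` keeps the
    layer additionally reported as part of the parent (both bookkeeping
    conventions are in use).
    """
    new_id = atlas.custom_id if new_id is None else new_id
    if new_id in atlas.ontology:
        raise ValueError(f"custom ID {new_id} already present in the ontology; refusing")
    for rid, nm in ((parent_id, "parent"), (adjacent_id, "adjacent")):
        if not (atlas.labels == rid).any():
            raise ValueError(f"{nm} region {rid} has no voxels")
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    adj = ndimage.binary_dilation(atlas.labels == adjacent_id, structure=structure)
    layer = adj & (atlas.labels == parent_id)
    if not layer.any():
        raise ValueError(f"regions {parent_id} and {adjacent_id} share no interface")
    out = atlas.copy()
    out.labels[layer] = new_id
    out.ontology.add(new_id, "SVZ", "subventricular zone (custom)", int(parent_id))
    if not exclude_from_parent:
        out.ontology.nodes[new_id]["count_with_parent"] = True
    logger.info("annotate_svz: relabelled %d interface voxels as ID %d",
                int(layer.sum()), new_id)
    return out


def annotate_consensus(atlas: LabelAtlas, sample_masks: list[np.ndarray],
                       min_votes: int = 4, new_id: int | None = None,
                       exclude_from_regions: bool = True) -> LabelAtlas:
    """Relabel voxels positive in at least ``min_votes`` of the sample masks.

    Default 4-of-7 encodes the consensus rule for reporter-positive voxels
    across registered brains.  ``exclude_from_regions=True`` removes the
    consensus voxels from their original regions (they belong solely to the
    custom region afterwards).
    """
    if not sample_masks:
        raise ValueError("need at least one sample mask")
    if not (1 <= min_votes <= len(sample_masks)):
        raise ValueError("min_votes must lie in [1, number of masks]")
    votes = np.zeros(atlas.shape, dtype=np.int32)
    for m in sample_masks:
        m = np.asarray(m)
        if m.shape != atlas.shape:
            raise ValueError("sample mask geometry does not match the atlas")
        votes += m.astype(bool)
    consensus = (votes >= min_votes) & atlas.brain_mask()
    new_id = atlas.custom_id if new_id is None else new_id
    if new_id in atlas.ontology:
        raise ValueError(f"custom ID {new_id} already present in the ontology; refusing")
    out = atlas.copy()
    out.labels[consensus] = new_id
    out.ontology.add(new_id, "MARK", "marker-consensus region (custom)",
                     out.ontology.root_id)
    if not exclude_from_regions:
        out.ontology.nodes[new_id]["count_with_parent"] = True
    logger.info("annotate_consensus: %d voxels met the %d-vote threshold",
                int(consensus.sum()), min_votes)
    return out


def annotate_hemispheres(atlas: LabelAtlas, midline_axis: int = 2,
                         offset: int = HEMISPHERE_OFFSET) -> LabelAtlas:
    """Split every region into left/right by adding ``offset`` to left-side IDs.

    The midline is the half-way plane of ``midline_axis``; for an odd axis
    length the exact midplane voxel column stays on the right side (logged).
    The ontology is duplicated with "left "/"right " name prefixes.
    """
    max_id = int(atlas.labels.max())
    if offset <= max_id:
        raise ValueError(f"offset {offset} must exceed the largest base ID {max_id}")
    n = atlas.shape[midline_axis]
    half = n // 2
    if n % 2:
        logger.info("odd axis length %d: midplane voxel column assigned to the right side", n)
    out = atlas.copy()
    left = [slice(None)] * 3
    left[midline_axis] = slice(0, half)
    left_sl = tuple(left)
    region = out.labels[left_sl]
    region[region != OUTSIDE_ID] += offset
    out.labels[left_sl] = region
    onto = out.ontology
    for rid in list(onto.nodes):
        node = onto.nodes[rid]
        pid = node["parent_structure_id"]
        onto.nodes[rid] = {**node, "name": "right " + node["name"]}
        new_parent = None if pid is None else pid + offset
        onto.nodes[rid + offset] = {
            "id": rid + offset,
            "acronym": "L-" + node["acronym"],
            "name": "left " + node["name"],
            "parent_structure_id": new_parent,
        }
    out.hemisphere_offset = offset
    return out
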