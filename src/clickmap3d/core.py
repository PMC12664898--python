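"""Core containers shared across the pipeline.

Physical-coordinate convention
------------------------------
A grid with per-axis spacing ``s`` places voxel ``i`` over the half-open
interval ``[i*s, (i+1)*s)`` along each axis, with the origin at the most
left-anterior-superior voxel, i.e. ``point_um = origin + index * spacing``
addresses the *lower corner* of a voxel and ``floor((point - origin) /
spacing)`` recovers the index.  Axes are abstract (axis0, axis1, axis2);
the hemisphere midline axis is configurable and defaults to axis2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "Ontology",
    "LabelAtlas",
    "NucleusSet",
    "OUTSIDE_ID",
    "DEFAULT_CUSTOM_ID",
    "HEMISPHERE_OFFSET",
]

#: label value of voxels outside the brain mask
OUTSIDE_ID = 0
#: reserved region ID used by the custom annotations (SVZ / marker consensus)
DEFAULT_CUSTOM_ID = 5
#: added to base region IDs on the left hemisphere
HEMISPHERE_OFFSET = 1_000_000_000


def _as_triple(x, name: str) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class Volume:
    """A 3D scalar intensity grid with physical voxel spacing in micrometres."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {data.shape}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _as_triple(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _as_triple(self.origin, "origin"))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
            raise ValueError("Volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)

    def point_to_index(self, points_um: np.ndarray) -> np.ndarray:
        """Map physical points (n, 3) to voxel indices under the half-open rule.

        Out-of-grid points get index -1 on every axis (the "outside" sentinel).
        """
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        idx = np.floor((pts - np.asarray(self.origin)) / np.asarray(self.spacing)).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)
        idx[~inside] = -1
        return idx

    def index_to_point(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinate of each voxel's lower corner."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class Ontology:
    """Allen-style structure graph: a tree of (id, acronym, name, parent_id).

    Node records are flat dictionaries; the nested JSON representation used
    by the reference-atlas ecosystem is produced/consumed in :mod:`clickmap3d.io`.
    """

    nodes: dict[int, dict] = field(default_factory=dict)
    root_id: int | None = None

    def __post_init__(self):
        self._validate()

    def _validate(self):
        roots = [i for i, n in self.nodes.items() if n.get("parent_structure_id") is None]
        for i, n in self.nodes.items():
            pid = n.get("parent_structure_id")
            if pid is not None and pid not in self.nodes:
                raise ValueError(f"orphan parent link: node {i} references missing parent {pid}")
        if self.nodes:
            if not roots:
                raise ValueError("ontology has no root")
            # more than one root is legitimate after a hemisphere split
            # (right tree + offset left tree); root_id names the base tree
            self.root_id = min(roots)

    def add(self, id: int, acronym: str, name: str, parent_structure_id: int | None):
        if id in self.nodes:
            raise ValueError(f"duplicate ontology ID {id}")
        if parent_structure_id is not None and parent_structure_id not in self.nodes:
            raise ValueError(f"parent {parent_structure_id} not in ontology")
        self.nodes[id] = {
            "id": int(id),
            "acronym": acronym,
            "name": name,
            "parent_structure_id": None if parent_structure_id is None else int(parent_structure_id),
        }
        if parent_structure_id is None:
            if self.root_id is not None and self.root_id != id and self.nodes:
                raise ValueError("ontology already has a root; use an explicit parent")
            self.root_id = id

    def __contains__(self, id: int) -> bool:
        return int(id) in self.nodes

    def parent(self, id: int) -> int | None:
        return self.nodes[int(id)]["parent_structure_id"]

    def children(self, id: int) -> list[int]:
        return [i for i, n in self.nodes.items() if n["parent_structure_id"] == int(id)]

    def ancestors(self, id: int) -> list[int]:
        """Path from *id* up to (and including) the root."""
        path = [int(id)]
        while (p := self.parent(path[-1])) is not None:
            path.append(p)
        return path

    def depth(self, id: int) -> int:
        return len(self.ancestors(id)) - 1

    def top_level_ancestor(self, id: int) -> int:
        """The depth-1 ancestor of *id* (or *id* itself if it is the root)."""
        path = self.ancestors(id)
        if len(path) == 1:
            return path[0]
        return path[-2]

    def top_level_ids(self) -> list[int]:
        return sorted(self.children(self.root_id))

    def descendants(self, id: int) -> list[int]:
        out, stack = [], [int(id)]
        while stack:
            cur = stack.pop()
            kids = self.children(cur)
            out.extend(kids)
            stack.extend(kids)
        return out

    def copy(self) -> "Ontology":
        return Ontology(nodes={i: dict(n) for i, n in self.nodes.items()})


@dataclass
class LabelAtlas:
    """Integer region-ID grid plus its ontology. 0 marks outside-brain voxels."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    ontology: Ontology
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    custom_id: int = DEFAULT_CUSTOM_ID
    hemisphere_offset: int = HEMISPHERE_OFFSET

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        present = set(np.unique(self.labels).tolist()) - {OUTSIDE_ID}
        missing = {p for p in present if p not in self.ontology}
        if missing:
            raise ValueError(f"grid labels absent from ontology: {sorted(missing)[:5]}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing)) * 1e-9

    def as_volume(self) -> Volume:
        return Volume(self.labels.astype(np.float64), self.spacing, self.origin)

    def brain_mask(self) -> np.ndarray:
        return self.labels != OUTSIDE_ID

    def copy(self) -> "LabelAtlas":
        return LabelAtlas(
            labels=self.labels.copy(),
            spacing=self.spacing,
            ontology=self.ontology.copy(),
            origin=self.origin,
            custom_id=self.custom_id,
            hemisphere_offset=self.hemisphere_offset,
        )

    def point_to_index(self, points_um: np.ndarray) -> np.ndarray:
        return self.as_volume().point_to_index(points_um)


@dataclass
class NucleusSet:
    """Point list of nuclear centres in physical micrometres.

    ``space`` tags which coordinate frame the points live in ("sample" for
    raw microscope coordinates, "atlas" after normalization).  Extra columns
    (component_size, outside flag, ...) travel in the backing DataFrame.
    """

    points: pd.DataFrame
    space: str
    channel: str = "edu"

    COLUMNS = ("x_um", "y_um", "z_um")

    def __post_init__(self):
        if self.space not in ("sample", "atlas"):
            raise ValueError(f"space must be 'sample' or 'atlas', got {self.space!r}")
        if not isinstance(self.points, pd.DataFrame):
            self.points = pd.DataFrame(np.atleast_2d(self.points), columns=list(self.COLUMNS))
        missing = [c for c in self.COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"missing coordinate columns {missing}")
        if len(self.points) and not np.all(np.isfinite(self.coords())):
            raise ValueError("non-finite nucleus coordinates")

    @classmethod
    def from_array(
        cls,
        coords_um: np.ndarray,
        space: str,
        channel: str = "edu",
        component_size: np.ndarray | None = None,
        **extra,
    ) -> "NucleusSet":
        coords_um = np.asarray(coords_um, dtype=float).reshape(-1, 3)
        df = pd.DataFrame(coords_um, columns=list(cls.COLUMNS))
        if component_size is not None:
            df["component_size"] = np.asarray(component_size, dtype=int)
        for k, v in extra.items():
            df[k] = v
        return cls(df, space=space, channel=channel)

    def coords(self) -> np.ndarray:
        return self.points[list(self.COLUMNS)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.points)

    def with_coords(self, coords_um: np.ndarray, space: str) -> "NucleusSet":
        df = self.points.copy()
        df[list(self.COLUMNS)] = np.asarray(coords_um, dtype=float)
        return NucleusSet(df, space=space, channel=self.channel)

    def to_csv(self, path) -> None:
        df = self.points.copy()
        df["channel"] = self.channel
        df["space"] = self.space
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "NucleusSet":
        df = pd.read_csv(path)
        space = str(df["space"].iloc[0]) if "space" in df and len(df) else "sample"
        channel = str(df["channel"].iloc[0]) if "channel" in df and len(df) else "edu"
        df = df.drop(columns=[c for c in ("space", "channel") if c in df])
        return cls(df, space=space, channel=channel)
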