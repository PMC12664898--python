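"""File-format boundary: NRRD, TIFF, NIfTI, structure-graph JSON, CSV, affine text.

NRRD support is a small self-contained codec covering the subset this package
reads and writes: 3D scalar grids, ``raw`` or ``gzip`` encodings, little-endian,
payload in Fortran order with ``sizes`` equal to the array shape (the layout
the pynrrd ecosystem produces by default).  TIFF goes through :mod:`tifffile`
and NIfTI (deformation fields) through :mod:`nibabel`.
"""

from __future__ import annotations

import gzip
import json
import zlib
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .core import LabelAtlas, Ontology, Volume

__all__ = [
    "read_nrrd",
    "write_nrrd",
    "read_volume",
    "write_volume",
    "read_ontology_json",
    "write_ontology_json",
    "read_label_atlas",
    "write_label_atlas",
    "read_affine_text",
    "write_affine_text",
    "read_deformation_nifti",
    "write_deformation_nifti",
]

_NRRD_TYPES = {
    "uint8": np.uint8, "int8": np.int8,
    "uint16": np.uint16, "int16": np.int16, "short": np.int16,
    "uint32": np.uint32, "int32": np.int32, "int": np.int32,
    "uint64": np.uint64, "int64": np.int64,
    "float": np.float32, "double": np.float64,
}
_NRRD_NAMES = {np.dtype(v): k for k, v in _NRRD_TYPES.items()
               if k not in ("short", "int")}


def write_nrrd(path, data: np.ndarray, spacing=None, origin=None, encoding: str = "gzip") -> None:
    data = np.ascontiguousarray(np.asarray(data))
    if encoding not in ("raw", "gzip"):
        raise ValueError(f"unsupported NRRD encoding {encoding!r}")
    dtype = data.dtype
    if dtype not in _NRRD_NAMES:
        raise ValueError(f"unsupported NRRD dtype {dtype}")
    lines = [
        "NRRD0004",
        "# generated by clickmap3d",
        f"type: {_NRRD_NAMES[dtype]}",
        f"dimension: {data.ndim}",
        f"sizes: {' '.join(str(s) for s in data.shape)}",
        f"encoding: {encoding}",
        "endian: little",
    ]
    if spacing is not None:
        sp = np.broadcast_to(np.asarray(spacing, dtype=float), (data.ndim,))
        lines.append("spacings: " + " ".join(f"{s:.17g}" for s in sp))
    if origin is not None:
        og = np.broadcast_to(np.asarray(origin, dtype=float), (data.ndim,))
        lines.append("space origin: (" + ",".join(f"{s:.17g}" for s in og) + ")")
    payload = np.asfortranarray(data).tobytes(order="F")
    if encoding == "gzip":
        payload = gzip.compress(payload)
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n\n").encode("ascii"))
        fh.write(payload)


def read_nrrd(path) -> tuple[np.ndarray, dict]:
    with open(path, "rb") as fh:
        raw = fh.read()
    head_end = raw.find(b"\n\n")
    if head_end < 0:
        raise ValueError(f"{path}: not an NRRD file (no header terminator)")
    header_lines = raw[:head_end].decode("ascii", errors="replace").splitlines()
    if not header_lines or not header_lines[0].startswith("NRRD"):
        raise ValueError(f"{path}: missing NRRD magic")
    fields: dict[str, str] = {}
    for line in header_lines[1:]:
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        fields[key.strip().lower()] = value.strip()
    try:
        dtype = np.dtype(_NRRD_TYPES[fields["type"]])
        sizes = tuple(int(s) for s in fields["sizes"].split())
        encoding = fields.get("encoding", "raw")
    except KeyError as exc:
        raise ValueError(f"{path}: missing NRRD header field {exc}") from exc
    if fields.get("endian", "little") != "little":
        raise ValueError(f"{path}: only little-endian NRRD supported")
    payload = raw[head_end + 2:]
    if encoding == "gzip":
        payload = zlib.decompress(payload, zlib.MAX_WBITS | 32)
    elif encoding != "raw":
        raise ValueError(f"{path}: unsupported encoding {encoding!r}")
    data = np.frombuffer(payload, dtype=dtype, count=int(np.prod(sizes)))
    data = data.reshape(sizes, order="F").copy()
    meta: dict = {}
    if "spacings" in fields:
        meta["spacing"] = tuple(float(x) for x in fields["spacings"].split())
    if "space origin" in fields:
        meta["origin"] = tuple(
            float(x) for x in fields["space origin"].strip("()").split(","))
    return data, meta


def write_volume(path, volume: Volume) -> None:
    """Write a Volume as NRRD (.nrrd) or multi-page TIFF (.tif/.tiff)."""
    path = Path(path)
    if path.suffix == ".nrrd":
        write_nrrd(path, volume.data, spacing=volume.spacing, origin=volume.origin)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path, np.asarray(volume.data),
            metadata={"spacing_um": list(volume.spacing), "origin_um": list(volume.origin)},
        )
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")


def read_volume(path, spacing=None, origin=(0.0, 0.0, 0.0)) -> Volume:
    path = Path(path)
    if path.suffix == ".nrrd":
        data, meta = read_nrrd(path)
        return Volume(data, meta.get("spacing", spacing if spacing is not None else 1.0),
                      meta.get("origin", origin))
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = {}
            if tf.shaped_metadata:
                meta = tf.shaped_metadata[0]
            elif tf.imagej_metadata:
                meta = tf.imagej_metadata
        sp = meta.get("spacing_um", spacing if spacing is not None else 1.0)
        og = meta.get("origin_um", origin)
        return Volume(data, sp, og)
    raise ValueError(f"unsupported volume format {path.suffix!r}")


# ---------------------------------------------------------------------------
# structure-graph (ontology) JSON

def _nest(ontology: Ontology, node_id: int) -> dict:
    rec = dict(ontology.nodes[node_id])
    rec["children"] = [_nest(ontology, c) for c in sorted(ontology.children(node_id))]
    return rec


def write_ontology_json(path, ontology: Ontology) -> None:
    """Write the Allen-style nested structure graph: {"msg": [<root records>]}.

    A hemisphere-annotated ontology is a forest (base tree + offset left
    tree); every root is emitted.
    """
    roots = sorted(i for i, n in ontology.nodes.items()
                   if n.get("parent_structure_id") is None)
    doc = {"msg": [_nest(ontology, r) for r in roots]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_ontology_json(path) -> Ontology:
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, dict) and "msg" in doc:
        roots = doc["msg"]
    elif isinstance(doc, list):
        roots = doc
    else:
        roots = [doc]
    nodes: dict[int, dict] = {}
    def _walk(rec: dict, parent_id: int | None):
        rid = int(rec["id"])
        if rid in nodes:
            raise ValueError(f"duplicate ontology ID {rid}")
        declared = rec.get("parent_structure_id")
        if declared is not None and parent_id is not None and int(declared) != int(parent_id):
            raise ValueError(f"node {rid}: parent link {declared} contradicts nesting under {parent_id}")
        nodes[rid] = {"id": rid, "acronym": rec.get("acronym", str(rid)),
                      "name": rec.get("name", str(rid)),
                      "parent_structure_id": parent_id}
        for child in rec.get("children", []) or []:
            _walk(child, rid)
    for root in roots:
        _walk(root, None)
    return Ontology(nodes=nodes)


def write_label_atlas(path_nrrd, atlas: LabelAtlas, path_json=None) -> None:
    write_nrrd(path_nrrd, atlas.labels.astype(np.int64), spacing=atlas.spacing,
               origin=atlas.origin)
    if path_json is not None:
        write_ontology_json(path_json, atlas.ontology)


def read_label_atlas(path_nrrd, path_json, **kwargs) -> LabelAtlas:
    labels, meta = read_nrrd(path_nrrd)
    ontology = read_ontology_json(path_json)
    return LabelAtlas(labels, meta.get("spacing", 1.0), ontology,
                      origin=meta.get("origin", (0.0, 0.0, 0.0)), **kwargs)


# ---------------------------------------------------------------------------
# affine as 12-number plain text with a direction header

def write_affine_text(path, affine) -> None:
    with open(path, "w") as fh:
        fh.write("# clickmap3d affine v1\n")
        fh.write(f"direction: {affine.direction}\n")
        for row, t in zip(affine.linear, affine.translation):
            fh.write(" ".join(f"{v:.17g}" for v in row) + f" {t:.17g}\n")


def read_affine_text(path):
    from .normalization import AffineTransform
    direction = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("direction:"):
                direction = line.split(":", 1)[1].strip()
                continue
            rows.append([float(v) for v in line.split()])
    if direction is None:
        raise ValueError(f"{path}: missing direction header")
    mat = np.asarray(rows, dtype=float)
    if mat.shape != (3, 4):
        raise ValueError(f"{path}: expected 3 rows of 4 numbers, got {mat.shape}")
    return AffineTransform(linear=mat[:, :3], translation=mat[:, 3], direction=direction)


# ---------------------------------------------------------------------------
# deformation field as 4-D NIfTI (3 displacement components, micrometres)

def write_deformation_nifti(path, field) -> None:
    disp = np.asarray(field.displacements_um, dtype=np.float32)  # (nx, ny, nz, 3)
    aff = np.diag(list(field.spacing) + [1.0])
    aff[:3, 3] = field.origin
    img = nib.Nifti1Image(disp, aff)
    img.header.set_zooms(tuple(field.spacing) + (1.0,))
    nib.save(img, str(path))


def read_deformation_nifti(path):
    from .normalization import DeformationField
    img = nib.load(str(path))
    disp = np.asarray(img.dataobj, dtype=np.float64)
    if disp.ndim == 5:  # ANTs-style (nx, ny, nz, 1, 3)
        disp = disp[:, :, :, 0, :]
    if disp.ndim != 4 or disp.shape[-1] != 3:
        raise ValueError(f"{path}: expected a (nx,ny,nz,3) displacement grid, got {disp.shape}")
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return DeformationField(displacements_um=disp, spacing=spacing, origin=origin)
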