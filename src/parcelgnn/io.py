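"""Readers/writers for surfaces, label maps, and per-vertex metrics.

GIFTI (`.surf.gii`, `.label.gii`, `.func.gii`) is the interchange standard,
handled through nibabel. Plain-text fallbacks keep the toolkit usable
without neuroimaging tooling: surfaces as a two-table text file (vertex xyz
rows, then 0-based face triples), labels as an integer vector, metrics as
TSV with an optional column-name header. Vertex indexing is 0-based
everywhere internally.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from parcelgnn.features import FeatureMatrix
from parcelgnn.labels import LabelMap
from parcelgnn.surface import SurfaceGraph, build_graph

__all__ = [
    "read_surface",
    "write_surface",
    "read_labels",
    "write_labels",
    "read_metric",
    "write_metric",
]


def _is_gifti(path: Path) -> bool:
    return path.name.endswith(".gii")


# -- surfaces ---------------------------------------------------------------

def write_surface(g: SurfaceGraph, path: str | Path) -> None:
    path = Path(path)
    if _is_gifti(path):
        img = nib.gifti.GiftiImage()
        img.add_gifti_data_array(
            nib.gifti.GiftiDataArray(
                g.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            )
        )
        img.add_gifti_data_array(
            nib.gifti.GiftiDataArray(
                g.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            )
        )
        nib.save(img, path)
    else:
        with open(path, "w") as fh:
            fh.write(f"vertices {g.num_vertices}\n")
            for x, y, z in g.vertices:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
            fh.write(f"faces {g.faces.shape[0]}\n")
            for a, b, c in g.faces:
                fh.write(f"{a} {b} {c}\n")


def read_surface(path: str | Path) -> SurfaceGraph:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_gifti(path):
        img = nib.load(path)
        verts = faces = None
        for arr in img.darrays:
            if arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                verts = np.asarray(arr.data, dtype=np.float64)
            elif arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = np.asarray(arr.data, dtype=np.int64)
        if verts is None or faces is None:
            raise ValueError(f"{path}: GIFTI surface lacks pointset/triangle arrays")
        return build_graph(verts, faces)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty surface file")
    try:
        tag, n = lines[0].split()
        if tag != "vertices":
            raise ValueError
        n = int(n)
        verts = np.array(
            [[float(v) for v in ln.split()] for ln in lines[1 : 1 + n]]
        )
        tag, m = lines[1 + n].split()
        if tag != "faces":
            raise ValueError
        m = int(m)
        faces = np.array(
            [[int(v) for v in ln.split()] for ln in lines[2 + n : 2 + n + m]],
            dtype=np.int64,
        )
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed surface text file") from exc
    return build_graph(verts, faces)


# -- labels -----------------------------------------------------------------

def write_labels(labels: LabelMap, path: str | Path) -> None:
    path = Path(path)
    if _is_gifti(path):
        img = nib.gifti.GiftiImage()
        table = nib.gifti.GiftiLabelTable()
        rng = np.random.default_rng(0)
        for code in [labels.unlabeled_code] + list(range(1, labels.num_classes + 1)):
            lab = nib.gifti.GiftiLabel(int(code), *(float(v) for v in rng.uniform(0, 1, 4)))
            lab.label = "???" if code == labels.unlabeled_code else f"parcel_{code}"
            table.labels.append(lab)
        img.labeltable = table
        img.add_gifti_data_array(
            nib.gifti.GiftiDataArray(
                labels.labels.astype(np.int32), intent="NIFTI_INTENT_LABEL"
            )
        )
        nib.save(img, path)
    else:
        with open(path, "w") as fh:
            fh.write(f"# unlabeled={labels.unlabeled_code} classes={labels.num_classes}\n")
            fh.write("\n".join(str(int(v)) for v in labels.labels))
            fh.write("\n")


def read_labels(path: str | Path) -> LabelMap:
    path = Path(path)
    if _is_gifti(path):
        img = nib.load(path)
        vec = np.asarray(img.darrays[0].data, dtype=np.int64)
        return LabelMap(labels=vec)
    with open(path) as fh:
        first = fh.readline()
        unlabeled, classes = 0, 0
        body_start = first
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                if k == "unlabeled":
                    unlabeled = int(v)
                elif k == "classes":
                    classes = int(v)
            body_start = ""
        text = body_start + fh.read()
    try:
        vec = np.array([int(tok) for tok in text.split()], dtype=np.int64)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer label content") from exc
    return LabelMap(labels=vec, unlabeled_code=unlabeled, num_classes=classes)


# -- metrics ----------------------------------------------------------------

def write_metric(values, path: str | Path, column_names=None) -> None:
    """Write per-vertex vectors/matrices; FeatureMatrix keeps its column names."""
    path = Path(path)
    if isinstance(values, FeatureMatrix):
        column_names = list(values.column_names)
        values = values.values
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    if _is_gifti(path):
        img = nib.gifti.GiftiImage()
        for j in range(arr.shape[1]):
            da = nib.gifti.GiftiDataArray(
                arr[:, j].astype(np.float32), intent="NIFTI_INTENT_NONE"
            )
            if column_names is not None:
                da.meta["Name"] = column_names[j]
            img.add_gifti_data_array(da)
        nib.save(img, path)
    else:
        with open(path, "w") as fh:
            if column_names is not None:
                fh.write("\t".join(column_names) + "\n")
            for row in arr:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_metric(path: str | Path, expect_vertices: int | None = None):
    """Read a metric file; returns (array, column_names-or-None).

    A single-column metric is returned as a 1-D vector.
    """
    path = Path(path)
    if _is_gifti(path):
        img = nib.load(path)
        cols = [np.asarray(d.data, dtype=np.float64) for d in img.darrays]
        names = [d.meta.get("Name") for d in img.darrays]
        arr = np.column_stack(cols)
        names = names if all(n is not None for n in names) else None
    else:
        with open(path) as fh:
            first = fh.readline()
            names = None
            rows = []
            try:
                rows.append([float(v) for v in first.split("\t")])
            except ValueError:
                names = first.rstrip("\n").split("\t")
            for ln in fh:
                if not ln.strip():
                    continue
                vals = [float(v) for v in ln.split("\t")]
                if rows and len(vals) != len(rows[0]):
                    raise ValueError(f"{path}: ragged rows")
                rows.append(vals)
        arr = np.array(rows)
    if expect_vertices is not None and arr.shape[0] != expect_vertices:
        raise ValueError(
            f"{path}: metric has {arr.shape[0]} vertices, mesh has {expect_vertices}"
        )
    if arr.ndim == 2 and arr.shape[1] == 1:
        return arr[:, 0], names
    return arr, names
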