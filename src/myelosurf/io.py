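"""GIFTI / NIfTI / TSV serialization.

Surfaces are written as GIFTI surface files (POINTSET + TRIANGLE arrays),
per-vertex maps as GIFTI metric (shape) files, parcellations as GIFTI
label files with a label table, and volumes as NIfTI-1 with an RAS affine.
The long-format parcel metrics table round-trips through TSV with a
versioned comment header, and ground-truth/config sidecars through JSON.
Readers validate topology and reject mismatched surface pairs loudly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import MetricMap, SurfacePair, TriangleMesh, TopologyError
from .myelin import VolumeImage
from .parcellation import ParcelLabelMap

__all__ = [
    "save_surface", "load_surface", "load_surface_pair",
    "save_metric", "load_metric",
    "save_labels", "load_labels",
    "save_volume", "load_volume",
    "save_metrics_table", "load_metrics_table",
    "save_json", "load_json",
]

TABLE_FORMAT_VERSION = "1"


def save_surface(mesh: TriangleMesh, path: str | Path) -> None:
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
        )
    )
    nib.save(img, str(path))


def load_surface(path: str | Path) -> TriangleMesh:
    img = nib.load(str(path))
    pts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")
    tri = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")
    if not pts or not tri:
        raise TopologyError(f"{path}: not a GIFTI surface (missing arrays)")
    mesh = TriangleMesh(pts[0].data.astype(np.float64), tri[0].data.astype(np.int64))
    mesh.validate()
    return mesh


def load_surface_pair(white_path: str | Path, pial_path: str | Path) -> SurfacePair:
    """Load and pair white/pial surfaces; topology mismatches raise."""
    return SurfacePair(load_surface(white_path), load_surface(pial_path))


def save_metric(metric: MetricMap, path: str | Path) -> None:
    img = nib.gifti.GiftiImage()
    da = nib.gifti.GiftiDataArray(
        metric.values.astype(np.float32), intent="NIFTI_INTENT_SHAPE"
    )
    da.meta["units"] = metric.units
    img.add_gifti_data_array(da)
    nib.save(img, str(path))


def load_metric(path: str | Path, n_vertices: int | None = None) -> MetricMap:
    img = nib.load(str(path))
    arrays = img.darrays
    if not arrays:
        raise TopologyError(f"{path}: empty GIFTI metric file")
    values = arrays[0].data.astype(np.float64)
    if n_vertices is not None and len(values) != n_vertices:
        raise TopologyError(
            f"{path}: {len(values)} values for a {n_vertices}-vertex mesh"
        )
    return MetricMap(values, units=arrays[0].meta.get("units", ""))


def save_labels(labels: ParcelLabelMap, path: str | Path) -> None:
    img = nib.gifti.GiftiImage()
    table = nib.gifti.GiftiLabelTable()
    unassigned = nib.gifti.GiftiLabel(key=0, red=0, green=0, blue=0, alpha=0)
    unassigned.label = "???"
    table.labels.append(unassigned)
    rng = np.random.default_rng(0)
    for key in sorted(labels.names):
        r, g, b = rng.uniform(0.2, 0.9, size=3)
        gl = nib.gifti.GiftiLabel(key=int(key), red=r, green=g, blue=b, alpha=1.0)
        gl.label = labels.names[key]
        table.labels.append(gl)
    img.labeltable = table
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            labels.labels.astype(np.int32), intent="NIFTI_INTENT_LABEL"
        )
    )
    nib.save(img, str(path))


def load_labels(path: str | Path, n_vertices: int | None = None) -> ParcelLabelMap:
    img = nib.load(str(path))
    data = img.darrays[0].data.astype(np.int64)
    if n_vertices is not None and len(data) != n_vertices:
        raise TopologyError(f"{path}: {len(data)} labels for a {n_vertices}-vertex mesh")
    names = {
        int(gl.key): gl.label
        for gl in img.labeltable.labels
        if gl.key != 0 and gl.label
    }
    return ParcelLabelMap(data, names)


def save_volume(vol: VolumeImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def load_volume(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    return VolumeImage(np.asarray(img.dataobj, dtype=np.float64), img.affine)


def save_metrics_table(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# myelosurf metrics table v{TABLE_FORMAT_VERSION}\n")
        # %.17g guarantees exact float64 round-trip through text
        table.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.17g")


def load_metrics_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# myelosurf metrics table"):
            raise ValueError(f"{path}: missing versioned header")
        return pd.read_csv(fh, sep="\t", float_precision="round_trip")


def save_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def load_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
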