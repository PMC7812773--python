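"""Readers and writers.

Surfaces travel as GIFTI (.surf.gii); time courses use either GIFTI
functional files or a compact NPZ container with the run metadata stored
inside (the internal interchange format — GIFTI round trips are slow for
many runs). Distance matrices are NPZ plus a JSON sidecar; tabular results
are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import GeodesicDistanceMatrix, TriangleMesh
from .preprocess import TimecourseMatrix

_HEMI_TO_GIFTI = {"L": "CortexLeft", "R": "CortexRight"}
_GIFTI_TO_HEMI = {v: k for k, v in _HEMI_TO_GIFTI.items()}


def write_surface(mesh: TriangleMesh, path) -> Path:
    """Write a mesh as a GIFTI surface file.

    Coordinates are stored as float32, the only type the GIFTI standard
    allows for pointsets; round trips are exact whenever the coordinates
    are float32-representable (true for regular millimeter grids).
    """
    path = Path(path)
    meta = nib.gifti.GiftiMetaData(
        AnatomicalStructurePrimary=_HEMI_TO_GIFTI[mesh.hemisphere]
    )
    pts = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32),
        intent="NIFTI_INTENT_POINTSET",
        datatype="NIFTI_TYPE_FLOAT32",
        meta=meta,
    )
    tris = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32),
        intent="NIFTI_INTENT_TRIANGLE",
        datatype="NIFTI_TYPE_INT32",
    )
    darrays = [pts, tris]
    for name, idx in mesh.region_labels.items():
        lab = np.zeros(mesh.n_vertices, dtype=np.int32)
        lab[np.asarray(idx, dtype=np.int64)] = 1
        darrays.append(
            nib.gifti.GiftiDataArray(
                lab,
                intent="NIFTI_INTENT_LABEL",
                datatype="NIFTI_TYPE_INT32",
                meta=nib.gifti.GiftiMetaData(Name=name),
            )
        )
    nib.save(nib.gifti.GiftiImage(darrays=darrays), path)
    return path


def read_surface(path) -> TriangleMesh:
    """Read a GIFTI surface; hemisphere tag and region labels round-trip."""
    img = nib.load(str(path))
    pts = [d for d in img.darrays if d.intent == nib.nifti1.intent_codes["pointset"]]
    tris = [d for d in img.darrays if d.intent == nib.nifti1.intent_codes["triangle"]]
    if not pts or not tris:
        raise ValueError(f"{path}: missing pointset or triangle array")
    verts = np.asarray(pts[0].data, dtype=float)
    faces = np.asarray(tris[0].data, dtype=np.int64)
    if faces.size and (faces.min() < 0 or faces.max() >= len(verts)):
        raise ValueError(f"{path}: face indices out of range for {len(verts)} vertices")
    anat = pts[0].meta.get("AnatomicalStructurePrimary", "")
    hemi = _GIFTI_TO_HEMI.get(anat, "L")
    labels = {}
    for d in img.darrays:
        if d.intent == nib.nifti1.intent_codes["label"]:
            name = d.meta.get("Name", "region")
            labels[name] = np.flatnonzero(np.asarray(d.data) > 0).astype(np.int64)
    return TriangleMesh(verts, faces, hemisphere=hemi, region_labels=labels)


def write_timecourses(tc: TimecourseMatrix, path) -> Path:
    """Write a run to the NPZ container (bit-exact round trip)."""
    path = Path(path)
    np.savez(
        path,
        data=tc.data,
        vertex_ids=tc.vertex_ids,
        sampling_rate=np.array([tc.sampling_rate]),
        run_id=np.array([tc.run_id]),
        condition=np.array([tc.condition]),
        hemisphere=np.array([tc.hemisphere if tc.hemisphere else ""]),
    )
    return path


def read_timecourses(path, allow_nan: bool = False) -> TimecourseMatrix:
    """Read a run from NPZ or a GIFTI functional file.

    GIFTI time-series darrays are stacked along time; NPZ restores the full
    metadata. NaN-containing data are rejected unless ``allow_nan``.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            hemi = str(z["hemisphere"][0]) or None
            tc = TimecourseMatrix(
                data=z["data"],
                vertex_ids=z["vertex_ids"],
                sampling_rate=float(z["sampling_rate"][0]),
                run_id=str(z["run_id"][0]),
                condition=str(z["condition"][0]),
                hemisphere=hemi,
            )
    else:
        img = nib.load(str(path))
        data = np.column_stack([np.asarray(d.data, dtype=float) for d in img.darrays])
        tc = TimecourseMatrix(data=data, vertex_ids=np.arange(data.shape[0]))
    if not allow_nan and not np.all(np.isfinite(tc.data)):
        raise ValueError(f"{path}: non-finite values present (pass allow_nan=True to accept)")
    return tc


def write_distance_matrix(gd: GeodesicDistanceMatrix, path, tolerance: float | None = None) -> Path:
    """NPZ distance matrix with a JSON sidecar (vertex list, hemisphere)."""
    path = Path(path)
    np.savez(path, dists=gd.dists, vertex_ids=gd.vertex_ids)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "hemisphere": gd.hemisphere,
                "n_vertices": int(gd.n),
                "vertex_ids": gd.vertex_ids.tolist(),
                "units": "mm",
                "symmetrized": True,
                "tolerance": tolerance,
            },
            indent=2,
        )
    )
    return path


def read_distance_matrix(path) -> GeodesicDistanceMatrix:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    with np.load(path) as z:
        return GeodesicDistanceMatrix(
            dists=z["dists"],
            vertex_ids=z["vertex_ids"],
            hemisphere=meta.get("hemisphere", "L"),
        )


def write_tsv(df: pd.DataFrame, path, provenance: str | None = None) -> Path:
    """Write a result table; ``provenance`` becomes a leading '#' comment."""
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
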