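"""Directory-bundle serialization for synthetic participants.

A participant bundle is a documented plain-text directory:

* ``mesh.off`` — the triangle mesh in OFF format;
* ``maps.csv`` — long-format quantitative maps (contrast, vertex, depth, value);
* ``bold.csv`` — optional long-format time series (vertex, volume, value);
* ``meta.json`` — units, axis frame, vertex spacing and the ground truth.

The loader round-trips bit exactly (values are written with full ``repr``
precision).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BoldTimeSeries, CorticalPatchMesh, FingerTopography
from .synthdata import GroundTruthSpec, Participant, Septum

UNITS = {"qT1": "ms", "nQSM": "ppm", "pQSM": "ppm", "aQSM": "ppm"}


def write_off(mesh: CorticalPatchMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.triangles)} 0\n")
        for v in mesh.vertex_coords:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_off(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if lines[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf, _ = (int(x) for x in lines[1].split())
    verts = np.array([[float(x) for x in ln.split()] for ln in lines[2:2 + nv]])
    tris = np.array([[int(x) for x in ln.split()[1:4]]
                     for ln in lines[2 + nv:2 + nv + nf]])
    return verts, tris


def save_participant(p: Participant, out_dir: str | Path,
                     bold: BoldTimeSeries | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_off(p.mesh, out / "mesh.off")
    rows = []
    for contrast, m in p.maps.items():
        v_idx, d_idx = np.indices(m.shape)
        rows.append(pd.DataFrame({
            "contrast": contrast, "vertex": v_idx.ravel(),
            "depth": d_idx.ravel() + 1,
            "value": [repr(float(x)) for x in m.ravel()]}))
    pd.concat(rows, ignore_index=True).to_csv(out / "maps.csv", index=False)
    if bold is not None:
        v_idx, t_idx = np.indices(bold.values.shape)
        pd.DataFrame({"vertex": v_idx.ravel(), "volume": t_idx.ravel(),
                      "value": [repr(float(x)) for x in bold.values.ravel()]}
                     ).to_csv(out / "bold.csv", index=False)
    truth = asdict(p.truth)
    truth["finger_band_centers"] = [repr(float(x)) for x in p.truth.finger_band_centers]
    meta = {
        "label": p.label,
        "units": UNITS,
        "vertex_spacing_mm": p.mesh.vertex_spacing,
        "axis_frame": p.mesh.axis_frame.tolist(),
        "rows": p.mesh.rows, "cols": p.mesh.cols,
        "surface_coords_generated": True,
        "bold_TR_s": None if bold is None else bold.TR,
        "ground_truth": truth,
        "topography": {
            "prf_center": [repr(float(x)) for x in p.topography.prf_center],
            "prf_width": [repr(float(x)) for x in p.topography.prf_width],
            "finger_label": p.topography.finger_label.tolist(),
        },
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1, default=str))
    return out


def load_participant(in_dir: str | Path) -> tuple[Participant, BoldTimeSeries | None]:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    verts, tris = read_off(src / "mesh.off")
    spacing = meta["vertex_spacing_mm"]
    rows, cols = meta["rows"], meta["cols"]
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    surface = np.column_stack([jj.ravel() * spacing, ii.ravel() * spacing])
    mesh = CorticalPatchMesh(
        vertex_coords=verts, triangles=tris, vertex_spacing=spacing,
        axis_frame=np.asarray(meta["axis_frame"], float),
        surface_coords=surface, rows=rows, cols=cols)
    maps_df = pd.read_csv(src / "maps.csv", float_precision="round_trip")
    maps = {}
    for contrast, grp in maps_df.groupby("contrast"):
        nv = int(grp.vertex.max()) + 1
        nd = int(grp.depth.max())
        m = np.empty((nv, nd))
        m[grp.vertex.to_numpy(), grp.depth.to_numpy() - 1] = \
            grp.value.map(float).to_numpy()
        maps[contrast] = m
    tr = meta["ground_truth"]
    tr["finger_band_centers"] = np.array([float(x)
                                          for x in tr["finger_band_centers"]])
    tr["septa"] = [Septum(**s) for s in tr["septa"]]
    truth = GroundTruthSpec(**tr)
    topo_meta = meta["topography"]
    label_idx = np.asarray(topo_meta["finger_label"], int)
    topo = FingerTopography(
        prf_center=np.array([float(x) for x in topo_meta["prf_center"]]),
        prf_width=np.array([float(x) for x in topo_meta["prf_width"]]),
        explained_variance=np.where(label_idx >= 0, 1.0, 0.0),
        model_confidence=np.where(label_idx >= 0, 1.0, 0.0),
        finger_label=label_idx)
    p = Participant(mesh=mesh, maps=maps, topography=topo, truth=truth,
                    label=meta["label"])
    bold = None
    if (src / "bold.csv").exists():
        bdf = pd.read_csv(src / "bold.csv", float_precision="round_trip")
        nv = int(bdf.vertex.max()) + 1
        nt = int(bdf.volume.max()) + 1
        vals = np.empty((nv, nt))
        vals[bdf.vertex.to_numpy(), bdf.volume.to_numpy()] = \
            bdf.value.map(float).to_numpy()
        bold = BoldTimeSeries(values=vals, TR=meta["bold_TR_s"])
    return p, bold
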