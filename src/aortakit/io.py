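"""File formats: cohort CSV dialects, shape-model JSON, VTP polylines.

The on-disk cohort layout is plain CSV/JSON so that runs are diffable and
reproducible:

* ``centrelines/<id>.csv`` — columns ``index, x_mm, y_mm, z_mm, radius_mm``
  plus an optional ``landmark`` column naming anatomical stations;
* ``waveforms/<id>.csv`` — columns ``t_s, flow_ml_s, area_cm2`` over one
  cycle (a trailing duplicate sample at ``t = period`` is accepted if it
  matches the first sample, and rejected as non-periodic otherwise);
* ``subjects.csv`` — per-subject scalars;
* ``truth.json`` — generator ground truth, when the cohort is synthetic.

Centrelines exported by vascular modelling tools as VTK XML polylines
(``.vtp``, ASCII) can be read directly if they carry the usual
``MaximumInscribedSphereRadius`` point-data array.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Centreline, Waveform
from .shape import ShapeModel
from .synthetic import SubjectRecord

__all__ = [
    "write_centreline_csv", "read_centreline_csv",
    "write_waveforms_csv", "read_waveforms_csv",
    "write_cohort", "read_cohort",
    "save_shape_model", "load_shape_model",
    "read_vtp_centreline",
]


# ---------------------------------------------------------------------------
# centrelines


def write_centreline_csv(cl: Centreline, path: str | Path) -> None:
    idx_to_name = {v: k for k, v in cl.landmarks.items()}
    df = pd.DataFrame({
        "index": np.arange(cl.n_points),
        "x_mm": cl.points[:, 0],
        "y_mm": cl.points[:, 1],
        "z_mm": cl.points[:, 2],
        "radius_mm": cl.radius,
        "landmark": [idx_to_name.get(i, "") for i in range(cl.n_points)],
    })
    df.to_csv(path, index=False, float_format="%.9g")


def read_centreline_csv(path: str | Path, subject_id: str = "") -> Centreline:
    df = pd.read_csv(path)
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    rad = df["radius_mm"].to_numpy(dtype=float)
    landmarks: dict[str, int] = {}
    if "landmark" in df.columns:
        for i, name in enumerate(df["landmark"].fillna("")):
            if str(name):
                landmarks[str(name)] = i
    sid = subject_id or Path(path).stem
    return Centreline(pts, rad, landmarks, sid)


# ---------------------------------------------------------------------------
# waveforms


def write_waveforms_csv(flow: Waveform, area: Waveform, path: str | Path) -> None:
    if flow.n != area.n or flow.dt != area.dt:
        raise ValueError("flow and area must share the same grid")
    pd.DataFrame({"t_s": flow.t, "flow_ml_s": flow.values,
                  "area_cm2": area.values}).to_csv(path, index=False,
                                                   float_format="%.9g")


def read_waveforms_csv(path: str | Path, closed: bool = False,
                       rtol: float = 1e-3) -> tuple[Waveform, Waveform]:
    """Read a flow/area cycle.

    Waveforms live on a circular grid over ``[0, period)``.  With
    ``closed=True`` the file is expected to end with an explicit sample at
    ``t = period`` closing the cycle: it must duplicate the first sample
    within ``rtol`` (otherwise the cycle is non-periodic and rejected) and
    is dropped.
    """
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(dtype=float)
    q = df["flow_ml_s"].to_numpy(dtype=float)
    a = df["area_cm2"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t)))
    if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform sampling grid")
    if closed:
        scale_q = max(1.0, float(np.abs(q).max()))
        scale_a = max(1e-12, float(np.abs(a).max()))
        if abs(q[-1] - q[0]) > rtol * scale_q or \
                abs(a[-1] - a[0]) > rtol * scale_a:
            raise ValueError(f"{path}: cycle endpoints mismatch beyond "
                             "tolerance (non-periodic waveform)")
        q, a = q[:-1], a[:-1]
    return Waveform(q, dt, "ml/s"), Waveform(a, dt, "cm2")


# ---------------------------------------------------------------------------
# cohort


def write_cohort(records: list[SubjectRecord], truth: pd.DataFrame | None,
                 out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "centrelines").mkdir(parents=True, exist_ok=True)
    (out / "waveforms").mkdir(exist_ok=True)
    rows = []
    for rec in records:
        write_centreline_csv(rec.centreline,
                             out / "centrelines" / f"{rec.subject_id}.csv")
        write_waveforms_csv(rec.flow, rec.area,
                            out / "waveforms" / f"{rec.subject_id}.csv")
        rows.append({"id": rec.subject_id, "p_sbp": rec.p_sbp, "dbp": rec.dbp,
                     "mbp": rec.mbp, "bsa": rec.bsa, "lvmi": rec.lvmi,
                     "lvef": rec.lvef, "gothic": int(rec.gothic)})
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False,
                              float_format="%.9g")
    if truth is not None:
        truth_dict = {str(k): {c: (float(v) if np.isreal(v) else v)
                               for c, v in row.items()}
                      for k, row in truth.to_dict(orient="index").items()}
        (out / "truth.json").write_text(
            json.dumps(truth_dict, indent=1, sort_keys=True, default=float))


def read_cohort(in_dir: str | Path) -> list[SubjectRecord]:
    src = Path(in_dir)
    subjects = pd.read_csv(src / "subjects.csv")
    truth: dict = {}
    truth_path = src / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    records = []
    for _, row in subjects.iterrows():
        sid = str(row["id"])
        cl = read_centreline_csv(src / "centrelines" / f"{sid}.csv", sid)
        flow, area = read_waveforms_csv(src / "waveforms" / f"{sid}.csv")
        records.append(SubjectRecord(
            subject_id=sid, centreline=cl, flow=flow, area=area,
            p_sbp=float(row["p_sbp"]), dbp=float(row["dbp"]),
            mbp=float(row["mbp"]), bsa=float(row["bsa"]),
            lvmi=float(row["lvmi"]), lvef=float(row["lvef"]),
            gothic=bool(row["gothic"]), truth=truth.get(sid, {}),
        ))
    return records


# ---------------------------------------------------------------------------
# shape models


def save_shape_model(model: ShapeModel, path: str | Path) -> None:
    payload = {
        "kind": model.kind,
        "n_points": model.n_points,
        "mean_vector": model.mean_vector.tolist(),
        "components": model.components.tolist(),
        "variance_fraction": model.variance_fraction.tolist(),
        "sd": model.sd.tolist(),
        "subject_weights": model.subject_weights.tolist(),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_shape_model(path: str | Path) -> ShapeModel:
    d = json.loads(Path(path).read_text())
    return ShapeModel(
        kind=d["kind"],
        mean_vector=np.asarray(d["mean_vector"]),
        components=np.asarray(d["components"]),
        variance_fraction=np.asarray(d["variance_fraction"]),
        sd=np.asarray(d["sd"]),
        subject_weights=np.asarray(d["subject_weights"]),
        n_points=int(d["n_points"]),
    )


# ---------------------------------------------------------------------------
# VTK XML polyline (.vtp), ASCII encoding


def read_vtp_centreline(path: str | Path, subject_id: str = "",
                        radius_array: str = "MaximumInscribedSphereRadius",
                        ) -> Centreline:
    """Read an ASCII VTK XML polyline with a per-point radius array.

    Only the inline-ASCII dialect is supported (the interchange format the
    usual centreline-extraction tools export); binary/appended encodings are
    rejected.
    """
    root = ET.parse(Path(path)).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise ValueError(f"{path}: no <Piece> element")

    def ascii_array(parent, name=None):
        for da in parent.iter("DataArray"):
            if name is None or da.get("Name") == name:
                if da.get("format", "ascii") != "ascii":
                    raise ValueError(f"{path}: only ascii format supported")
                return np.fromstring(da.text, sep=" ")
        raise ValueError(f"{path}: missing DataArray {name!r}")

    pts = ascii_array(piece.find("Points")).reshape(-1, 3)
    rad = ascii_array(piece.find("PointData"), radius_array)
    # honour polyline connectivity order when present
    lines = piece.find("Lines")
    if lines is not None:
        conn = ascii_array(lines, "connectivity").astype(int)
        pts = pts[conn]
        rad = rad[conn]
    sid = subject_id or Path(path).stem
    return Centreline(pts, rad, {}, sid)
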