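"""On-disk formats: JSON sidecars, point clouds, DICOM metadata.

Per-patient folder layout (inputs and outputs co-located)::

    <patient>/
        radiograph_frontal.json   calibrated frame (JSON sidecar or from DICOM)
        radiograph_lateral.json
        annotation_frontal.json   marker picks + drawn spine line (pixels)
        annotation_lateral.json
        scan_cloud.ply            back-surface point cloud (PLY/PCD/STL)
        scan_annotation.json      scanner-frame markers + drawn SPL (mm)
        truth.json                phantom ground truth (never read by the
                                  pipeline; excluded by naming convention)
        result.json               pipeline output

JSON files are written with sorted keys so identical inputs reproduce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .phantom import PhantomBundle
from .types import Annotation2D, RadiographFrame, RigidTransform, SpinalignError, View

__all__ = [
    "write_json",
    "read_json",
    "frame_from_dicom",
    "load_point_cloud",
    "save_point_cloud",
    "write_phantom_folder",
    "load_patient_folder",
]


def write_json(path: Path | str, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())


def frame_from_dicom(path: Path | str, view: View | str, frame_id: str = "") -> RadiographFrame:
    """Build a calibrated frame from the DICOM tags of one radiograph.

    Reads ``PixelSpacing`` (row, col), ``ImagePositionPatient``,
    ``Rows`` and ``Columns``; pixel data are never touched (annotations
    arrive as coordinates).  The view label cannot be inferred reliably
    from tags, so the caller supplies it.
    """
    import pydicom

    ds = pydicom.dcmread(str(path), stop_before_pixels=True)
    try:
        spacing = tuple(float(v) for v in ds.PixelSpacing)
        origin = tuple(float(v) for v in ds.ImagePositionPatient)
        size = (int(ds.Rows), int(ds.Columns))
    except AttributeError as exc:
        raise SpinalignError(f"DICOM file {path} lacks required calibration tags: {exc}")
    return RadiographFrame(
        view=View(view),
        pixel_spacing=spacing,
        origin_mm=origin,
        image_size_px=size,
        frame_id=frame_id or Path(path).stem,
    )


# ------------------------------------------------------------- point clouds


def _write_pcd(path: Path, points: np.ndarray) -> None:
    n = len(points)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\nFIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
    )
    body = "\n".join(" ".join(f"{v:.6f}" for v in p) for p in points)
    path.write_text(header + body + "\n")


def _read_pcd(path: Path) -> np.ndarray:
    lines = path.read_text().splitlines()
    data_at = next(i for i, l in enumerate(lines) if l.startswith("DATA"))
    if "ascii" not in lines[data_at]:
        raise SpinalignError(f"{path}: only ASCII PCD is supported")
    return np.array([[float(v) for v in l.split()[:3]] for l in lines[data_at + 1 :] if l.strip()])


def save_point_cloud(path: Path | str, points: np.ndarray) -> None:
    """Write an (n, 3) cloud as ASCII PLY or PCD, by file extension."""
    path = Path(path)
    points = np.asarray(points, dtype=float)
    if path.suffix.lower() == ".pcd":
        _write_pcd(path, points)
    elif path.suffix.lower() == ".ply":
        data = trimesh.PointCloud(points).export(file_type="ply", encoding="ascii")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    else:
        raise SpinalignError(f"unsupported point-cloud format {path.suffix!r}")


def load_point_cloud(path: Path | str) -> np.ndarray:
    """Load an (n, 3) cloud from PLY, STL or PCD."""
    path = Path(path)
    if path.suffix.lower() == ".pcd":
        return _read_pcd(path)
    if path.suffix.lower() in (".ply", ".stl"):
        obj = trimesh.load(str(path))
        return np.asarray(obj.vertices, dtype=float)
    raise SpinalignError(f"unsupported point-cloud format {path.suffix!r}")


# ------------------------------------------------------------- folders


def write_phantom_folder(bundle: PhantomBundle, folder: Path | str, cloud_format: str = "ply") -> Path:
    """Write one phantom as the on-disk layout the pipeline consumes."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    for view in (View.FRONTAL, View.LATERAL):
        write_json(folder / f"radiograph_{view.value}.json", bundle.frames[view].to_dict())
        write_json(folder / f"annotation_{view.value}.json", bundle.annotations[view].to_dict())
    save_point_cloud(folder / f"scan_cloud.{cloud_format}", bundle.scan.cloud)
    write_json(
        folder / "scan_annotation.json",
        {
            "markers": {k: v.tolist() for k, v in bundle.scan.markers.items()},
            "spl_polyline": bundle.scan.spl_polyline.tolist(),
        },
    )
    t = bundle.truth
    write_json(
        folder / "truth.json",
        {
            "cobb_frontal_deg": t.cobb_frontal_deg,
            "cobb_kyphotic_deg": t.cobb_kyphotic_deg,
            "cobb_lordotic_deg": t.cobb_lordotic_deg,
            "pcc_frontal": t.pcc_frontal,
            "pcc_sagittal": t.pcc_sagittal,
            "postural_transform": t.postural_transform.to_dict(),
            "markers_eos": {k: v.tolist() for k, v in t.markers_eos.items()},
            "seed": bundle.spec.seed,
        },
    )
    return folder


def load_patient_folder(folder: Path | str) -> dict:
    """Load the pipeline inputs of one patient folder.

    Returns a dict with frames, annotations, scan markers, SPL polyline
    and the point cloud.  ``truth.json`` (phantom ground truth) is
    never read here.  Missing files raise :class:`FileNotFoundError`
    naming the missing piece.
    """
    folder = Path(folder)
    out: dict = {"patient_id": folder.name}
    for view in (View.FRONTAL, View.LATERAL):
        fpath = folder / f"radiograph_{view.value}.json"
        apath = folder / f"annotation_{view.value}.json"
        if not fpath.exists():
            raise FileNotFoundError(f"missing {view.value} radiograph metadata: {fpath}")
        if not apath.exists():
            raise FileNotFoundError(f"missing {view.value} annotation: {apath}")
        out[f"frame_{view.value}"] = RadiographFrame.from_dict(read_json(fpath))
        out[f"annotation_{view.value}"] = Annotation2D.from_dict(read_json(apath))
    spath = folder / "scan_annotation.json"
    if not spath.exists():
        raise FileNotFoundError(f"missing scan annotation: {spath}")
    scan = read_json(spath)
    out["scan_markers"] = {k: np.asarray(v, float) for k, v in scan["markers"].items()}
    out["spl_polyline"] = np.asarray(scan["spl_polyline"], float)
    cloud = None
    for ext in ("ply", "pcd", "stl"):
        cpath = folder / f"scan_cloud.{ext}"
        if cpath.exists():
            cloud = load_point_cloud(cpath)
            out["cloud_path"] = cpath
            break
    out["cloud"] = cloud  # optional: registration only needs the markers
    return out
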