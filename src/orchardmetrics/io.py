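"""Scene file interchange.

A scene directory holds one 16-bit grayscale TIFF per band (GRE.tif,
RED.tif, REG.tif, NIR.tif; reflectance scaled by ``band_scale``), an
ASCII PLY 1.0 point cloud (cloud.ply), a ``scene.json`` sidecar with the
geometry metadata, and a ``truth.csv`` table when ground truth exists.
Index images, segmentations, morphology and feature tables are written as
TIFF/JSON/CSV next to them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

from .indices import BandStack, IndexImage
from .segmentation import GridSegmentation
from .synthetic import OrchardLayout, PointCloud, SceneBundle, TreeTruth

BAND_FILES = {"gre": "GRE.tif", "red": "RED.tif", "reg": "REG.tif", "nir": "NIR.tif"}


def write_ply(path: str | Path, cloud: PointCloud) -> None:
    """Write an ASCII PLY 1.0 with float x/y/z vertex properties."""
    pc = trimesh.PointCloud(cloud.points.astype(np.float32))
    Path(path).write_bytes(pc.export(file_type="ply", encoding="ascii"))


def read_ply(path: str | Path) -> PointCloud:
    mesh = trimesh.load(str(path), process=False)
    return PointCloud(points=np.asarray(mesh.vertices, dtype=np.float64))


def write_scene(directory: str | Path, scene: SceneBundle) -> Path:
    """Write bands, cloud, sidecar and truth for a scene bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": scene.seed,
        "field_length_m": scene.layout.field_length,
        "field_width_m": scene.layout.field_width,
        "n_rows": scene.layout.n_rows,
        "trees_per_row": list(scene.layout.trees_per_row),
        "row_spacing_m": scene.layout.row_spacing,
        "plant_spacing_m": scene.layout.plant_spacing,
        "dead_fraction": scene.layout.dead_fraction,
        "trunk_height_m": scene.layout.trunk_height,
        "origin_xy": [0.0, 0.0],
    }
    if scene.bands is not None:
        b = scene.bands
        meta.update({"gsd_cm_px": b.gsd, "band_scale": b.band_scale})
        for name, fname in BAND_FILES.items():
            arr = np.clip(getattr(b, name) * b.band_scale, 0, 65535).astype(np.uint16)
            tifffile.imwrite(directory / fname, arr)
    if scene.cloud is not None:
        write_ply(directory / "cloud.ply", scene.cloud)
    (directory / "scene.json").write_text(json.dumps(meta, indent=2))
    truth_table(scene.trees).to_csv(directory / "truth.csv", index=False)
    return directory


def truth_table(trees: list[TreeTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tree_id": range(len(trees)),
            "row": [t.row_index for t in trees],
            "col": [t.col_index for t in trees],
            "center_x": [t.center_xy[0] for t in trees],
            "center_y": [t.center_xy[1] for t in trees],
            "trunk_height": [t.trunk_height for t in trees],
            "H": [t.canopy_height_total for t in trees],
            "radius": [t.canopy_radius for t in trees],
            "is_dead": [t.is_dead for t in trees],
            "yield_kg": [t.yield_kg for t in trees],
        }
    )


def read_scene(directory: str | Path) -> SceneBundle:
    """Read a scene directory back into a bundle (truth optional)."""
    directory = Path(directory)
    meta = json.loads((directory / "scene.json").read_text())
    layout = OrchardLayout(
        n_rows=meta["n_rows"],
        trees_per_row=tuple(meta["trees_per_row"]),
        row_spacing=meta["row_spacing_m"],
        plant_spacing=meta["plant_spacing_m"],
        field_length=meta["field_length_m"],
        field_width=meta["field_width_m"],
        dead_fraction=meta.get("dead_fraction", 0.0),
        trunk_height=meta.get("trunk_height_m", 0.6),
    )
    bands = None
    if (directory / BAND_FILES["gre"]).exists():
        scale = meta.get("band_scale", 10000)
        arrays = {
            name: tifffile.imread(directory / fname).astype(np.float32) / scale
            for name, fname in BAND_FILES.items()
        }
        bands = BandStack(gsd=meta["gsd_cm_px"], **arrays)
    cloud = read_ply(directory / "cloud.ply") if (directory / "cloud.ply").exists() else None
    trees: list[TreeTruth] = []
    if (directory / "truth.csv").exists():
        df = pd.read_csv(directory / "truth.csv")
        for _, r in df.iterrows():
            trees.append(
                TreeTruth(
                    row_index=int(r["row"]),
                    col_index=int(r["col"]),
                    center_xy=(float(r["center_x"]), float(r["center_y"])),
                    trunk_height=float(r["trunk_height"]),
                    canopy_height_total=float(r["H"]),
                    canopy_radius=float(r["radius"]),
                    is_dead=bool(r["is_dead"]),
                    yield_kg=float(r["yield_kg"]),
                )
            )
    return SceneBundle(layout=layout, trees=trees, bands=bands, cloud=cloud,
                       seed=meta.get("seed", 0))


def write_index_image(directory: str | Path, img: IndexImage, float_raster: bool = False) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"INDEX_{img.name}.tif", img.gray)
    if float_raster:
        tifffile.imwrite(
            directory / f"INDEX_{img.name}_f32.tif", img.values.astype(np.float32)
        )


def read_index_image(path: str | Path, gsd: float) -> IndexImage:
    path = Path(path)
    gray = tifffile.imread(path)
    name = path.stem.replace("INDEX_", "")
    return IndexImage(name=name, values=gray.astype(np.float64), gray=gray, gsd=gsd)


def segmentation_to_json(seg: GridSegmentation, scores: dict | None = None) -> str:
    payload = {
        "L_2D": None if seg.L_2D is None else np.asarray(seg.L_2D).tolist(),
        "C_2D": None if seg.C_2D is None else [np.asarray(c).tolist() for c in seg.C_2D],
        "L_3D": None if seg.L_3D is None else np.asarray(seg.L_3D).tolist(),
        "C_3D": None if seg.C_3D is None else [np.asarray(c).tolist() for c in seg.C_3D],
        "m_2D": seg.m_2D,
        "n_2D": seg.n_2D,
        "m_3D": seg.m_3D,
        "n_3D": seg.n_3D,
    }
    if scores:
        payload["scores"] = scores
    return json.dumps(payload, indent=2)


def segmentation_from_json(text: str) -> GridSegmentation:
    d = json.loads(text)
    return GridSegmentation(
        L_2D=None if d["L_2D"] is None else np.asarray(d["L_2D"]),
        C_2D=None if d["C_2D"] is None else [np.asarray(c) for c in d["C_2D"]],
        L_3D=None if d["L_3D"] is None else np.asarray(d["L_3D"]),
        C_3D=None if d["C_3D"] is None else [np.asarray(c) for c in d["C_3D"]],
        m_2D=d["m_2D"],
        n_2D=d["n_2D"],
        m_3D=d["m_3D"],
        n_3D=d["n_3D"],
    )
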