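"""File formats: scene TIFF + JSON sidecar, expression TSV, result CSVs.

A scene is stored as a multipage TIFF in CZYX page order plus a sidecar
JSON (same path, ``.json`` suffix) holding the voxel size, channel names,
seed and the geometric ground truth when available.  The nucleus mask of
the truth is stored as ellipsoid geometry (centre + semiaxes) and rebuilt
on load, keeping the sidecar small and lossless for the analytic nuclei
the simulator produces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import Scene, SceneTruth, TerritoryTruth, ellipsoid_mask

__all__ = [
    "SceneFormatError",
    "write_scene",
    "read_scene",
    "write_expression",
    "read_expression",
    "measurements_to_frame",
]


class SceneFormatError(ValueError):
    """A scene file or its metadata cannot be read."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_scene(scene: Scene, path, truth: SceneTruth | None = None,
                seed: int | None = None) -> Path:
    """Write a scene to ``path`` (TIFF, CZYX pages) with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, scene.voxels, photometric="minisblack")
    meta = {
        "voxel_size": list(scene.voxel_size),
        "channel_names": list(scene.channel_names),
        "scene_id": scene.scene_id,
        "shape": list(scene.voxels.shape),
        "seed": seed,
    }
    if truth is not None:
        meta["truth"] = {
            "nucleus_center": list(map(float, truth.nucleus_center)),
            "nucleus_semiaxes": list(map(float, truth.nucleus_semiaxes)),
            "territories": [
                {
                    "channel": t.channel,
                    "true_center": list(map(float, t.true_center)),
                    "true_fractional_rd": t.true_fractional_rd,
                    "direction": list(map(float, t.direction)),
                    "applied_semiaxes": list(map(float, t.applied_semiaxes)),
                }
                for t in truth.territories
            ],
        }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_scene(path, voxel_size=None) -> tuple[Scene, SceneTruth | None]:
    """Read a scene TIFF; the sidecar (or ``voxel_size``) supplies metadata.

    Without a sidecar, ``voxel_size`` must be given explicitly (CLI flags
    ``--voxel-z`` / ``--voxel-xy``).
    """
    path = Path(path)
    try:
        voxels = tifffile.imread(path)
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise SceneFormatError(f"cannot read TIFF {path}: {exc}") from exc

    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    if voxel_size is None:
        voxel_size = meta.get("voxel_size")
    if voxel_size is None:
        raise SceneFormatError(
            f"{path} has no voxel-size metadata; supply it with "
            "--voxel-z and --voxel-xy (or the voxel_size argument)"
        )
    if voxels.ndim == 3:
        shape = meta.get("shape")
        if shape and len(shape) == 4 and int(np.prod(shape)) == voxels.size:
            voxels = voxels.reshape(shape)  # CZYX pages without series metadata
        else:
            voxels = voxels[None]  # single-channel stack
    if voxels.ndim != 4:
        raise SceneFormatError(f"expected a CZYX stack, got shape {voxels.shape}")

    scene = Scene(
        voxels=voxels,
        voxel_size=tuple(float(v) for v in voxel_size),
        channel_names=tuple(meta.get("channel_names", ("blue", "green", "red"))[: voxels.shape[0]]),
        scene_id=meta.get("scene_id", path.stem),
    )
    truth = None
    if "truth" in meta:
        t = meta["truth"]
        center = np.asarray(t["nucleus_center"], dtype=float)
        semiaxes = tuple(t["nucleus_semiaxes"])
        truth = SceneTruth(
            nucleus_mask=ellipsoid_mask(voxels.shape[1:], scene.voxel_size,
                                        center, semiaxes),
            nucleus_center=center,
            nucleus_semiaxes=semiaxes,
            territories=[
                TerritoryTruth(
                    channel=d["channel"],
                    true_center=np.asarray(d["true_center"], dtype=float),
                    true_fractional_rd=float(d["true_fractional_rd"]),
                    direction=np.asarray(d["direction"], dtype=float),
                    applied_semiaxes=tuple(d["applied_semiaxes"]),
                )
                for d in t["territories"]
            ],
        )
    return scene, truth


def write_expression(table: pd.DataFrame, path) -> Path:
    """Write an expression table as TSV (gene_id, chromosome, fpkm_*, log2fc_*)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_expression(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chromosome"}
    if not required.issubset(table.columns):
        raise SceneFormatError(f"expression table needs columns {sorted(required)}")
    return table


def measurements_to_frame(measurements, condition: str = "",
                          chromosome_by_channel: dict[str, str] | None = None) -> pd.DataFrame:
    """Flatten TerritoryMeasurement objects into a tidy DataFrame.

    %RD is additionally reported rounded to 2 decimals (``percent_rd_2dp``)
    alongside the full-precision value.
    """
    rows = []
    for m in measurements:
        chrom = (chromosome_by_channel or {}).get(m.channel, m.channel)
        rows.append({
            "scene_id": m.scene_id,
            "condition": condition,
            "channel": m.channel,
            "chromosome": chrom,
            "N_z": m.N[0], "N_y": m.N[1], "N_x": m.N[2],
            "C_z": m.C[0], "C_y": m.C[1], "C_x": m.C[2],
            "B_z": m.B[0], "B_y": m.B[1], "B_x": m.B[2],
            "R_um": m.R, "Y_um": m.Y,
            "percent_rd": m.percent_rd,
            "percent_rd_2dp": round(m.percent_rd, 2),
            "clamped": m.clamped,
        })
    return pd.DataFrame(rows)
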