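"""File formats: TIFF grids with JSON sidecars, CSV tables, JSON results.

Grids (en-face maps, standard grids, raw per-A-scan volumes) are stored as
single-channel float32 TIFFs with a ``<name>.json`` sidecar carrying the
metadata (feature, spacing, foveal annotation, laterality); tables are
plain CSV. Everything round-trips exactly at float32 precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from .enface import EnFaceMap, Feature, Laterality, SegVolume
from .grid import StandardGrid

PathLike = Union[str, Path]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_grid(path: Path, grid: np.ndarray, meta: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(grid, dtype=np.float32))
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def _read_grid(path: Path) -> Tuple[np.ndarray, dict]:
    grid = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(_sidecar(path).read_text())
    return grid, meta


def save_volume(volume: SegVolume, path: PathLike) -> None:
    _write_grid(
        Path(path),
        volume.data,
        {
            "kind": "seg_volume",
            "feature": volume.feature.value,
            "laterality": volume.laterality.value,
            "fovea_xy_mm": list(volume.fovea_xy_mm),
            "field_mm": list(volume.field_mm),
        },
    )


def load_volume(path: PathLike) -> SegVolume:
    grid, meta = _read_grid(Path(path))
    return SegVolume(
        feature=Feature(meta["feature"]),
        data=grid,
        laterality=Laterality(meta["laterality"]),
        fovea_xy_mm=tuple(meta["fovea_xy_mm"]),
        field_mm=tuple(meta["field_mm"]),
    )


def save_enface(emap: EnFaceMap, path: PathLike) -> None:
    _write_grid(
        Path(path),
        emap.grid,
        {
            "kind": "enface_map",
            "feature": emap.feature.value,
            "spacing_mm": list(emap.spacing_mm),
            "fovea_xy_mm": list(emap.fovea_xy_mm),
            "laterality": emap.laterality.value,
        },
    )


def load_enface(path: PathLike) -> EnFaceMap:
    grid, meta = _read_grid(Path(path))
    return EnFaceMap(
        feature=Feature(meta["feature"]),
        grid=grid,
        spacing_mm=tuple(meta["spacing_mm"]),
        fovea_xy_mm=tuple(meta["fovea_xy_mm"]),
        laterality=Laterality(meta["laterality"]),
    )


def save_standard_grid(sg: StandardGrid, path: PathLike) -> None:
    _write_grid(
        Path(path),
        sg.grid,
        {
            "kind": "standard_grid",
            "feature": sg.feature.value if sg.feature else None,
            "extent_mm": sg.extent_mm,
            "fill_value": sg.fill_value,
        },
    )


def load_standard_grid(path: PathLike) -> StandardGrid:
    grid, meta = _read_grid(Path(path))
    return StandardGrid(
        grid=grid,
        extent_mm=meta["extent_mm"],
        feature=Feature(meta["feature"]) if meta.get("feature") else None,
        fill_value=meta.get("fill_value", 0.0),
    )


def save_cohort(cohort, outdir: PathLike) -> None:
    """Write a synthetic cohort: per-eye feature TIFFs, cohort.csv, truth.json."""
    outdir = Path(outdir)
    voldir = outdir / "volumes"
    for eye_id, feats in cohort.volumes.items():
        for feat, vol in feats.items():
            save_volume(vol, voldir / eye_id / f"{feat.value}.tiff")
    cols = [
        "patient_id",
        "eye_id",
        "eye_side",
        "fovea_x_mm",
        "fovea_y_mm",
        "va_letters",
        "llva_letters",
        "lld_letters",
    ]
    cohort.outcomes[cols].to_csv(outdir / "cohort.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(cohort.truth, indent=1, sort_keys=True))


def load_cohort_volumes(outdir: PathLike) -> Dict[str, Dict[Feature, SegVolume]]:
    voldir = Path(outdir) / "volumes"
    volumes: Dict[str, Dict[Feature, SegVolume]] = {}
    for eyedir in sorted(p for p in voldir.iterdir() if p.is_dir()):
        volumes[eyedir.name] = {
            (v := load_volume(f)).feature: v for f in sorted(eyedir.glob("*.tiff"))
        }
    return volumes


def load_cohort_outcomes(outdir: PathLike) -> pd.DataFrame:
    return pd.read_csv(Path(outdir) / "cohort.csv")


def write_json(obj: dict, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))
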