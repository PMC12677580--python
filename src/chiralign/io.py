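"""File I/O: TIFF scenes, angle tables (CSV/XLSX), YAML configuration.

Angle tables come in two layouts, auto-detected per sheet/file:

* tidy — columns ``group`` and ``theta_deg`` (one row per rectangle);
* wide — one numeric column of angles per group, the header naming the
  group (the layout of raw-data workbooks deposited with the study this
  pipeline reproduces: one sheet or column per experimental group).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .circstats import AngleSample
from .geometry import GridSpec
from .synthetic import SceneParams

__all__ = [
    "read_image",
    "write_image",
    "read_angle_tables",
    "write_ground_truth",
    "load_config",
]


def read_image(path) -> np.ndarray:
    """Read a single-channel TIFF as a 2-D array."""
    img = tifffile.imread(str(path))
    img = np.squeeze(img)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, "
                         f"got shape {img.shape}")
    return img


def write_image(path, image: np.ndarray) -> None:
    """Write a scene as single-channel 16-bit TIFF."""
    arr = np.asarray(image)
    if arr.dtype != np.uint16:
        arr = np.clip(arr, 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def write_ground_truth(path, truth: pd.DataFrame) -> None:
    cols = ["rect_id", "orientation", "theta_true_deg", "coverage",
            "expected_included"]
    extra = [c for c in truth.columns if c not in cols]
    truth[cols + extra].to_csv(path, index=False)


def _groups_from_frame(df: pd.DataFrame, default_label: str) -> dict[str, np.ndarray]:
    cols = {str(c).strip().lower(): c for c in df.columns}
    if "group" in cols and "theta_deg" in cols:
        out = {}
        for g, sub in df.groupby(cols["group"], sort=False):
            vals = pd.to_numeric(sub[cols["theta_deg"]], errors="coerce").dropna()
            out[str(g)] = vals.to_numpy(float)
        return out
    out = {}
    numeric = df.apply(pd.to_numeric, errors="coerce")
    for c in df.columns:
        vals = numeric[c].dropna().to_numpy(float)
        if vals.size == 0:
            continue
        label = str(c)
        if label.lower().startswith("unnamed"):
            label = default_label
        out[label] = vals
    return out


def read_angle_tables(paths) -> dict[str, AngleSample]:
    """Read one or more angle tables into labelled samples.

    Angles are wrapped axially to (−90, 90]; empty groups are dropped.
    Duplicate labels across files get a numeric suffix.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    groups: dict[str, np.ndarray] = {}

    def _add(label, vals):
        base, k = label, 1
        while label in groups:
            k += 1
            label = f"{base}_{k}"
        groups[label] = vals

    for path in paths:
        p = Path(path)
        if p.suffix.lower() in (".xlsx", ".xls"):
            sheets = pd.read_excel(p, sheet_name=None)
            multi = len(sheets) > 1
            for sheet, df in sheets.items():
                found = _groups_from_frame(df, default_label=str(sheet))
                for label, vals in found.items():
                    if multi and label not in (str(sheet),) and len(found) > 1:
                        label = f"{sheet}/{label}"
                    _add(label, vals)
        else:
            df = pd.read_csv(p)
            for label, vals in _groups_from_frame(df, p.stem).items():
                _add(label, vals)

    return {label: AngleSample.from_degrees(label, vals)
            for label, vals in groups.items() if vals.size > 0}


def load_config(path) -> dict:
    """Load a YAML config with optional ``grid``, ``scene`` and ``run``
    sections mirroring GridSpec / SceneParams / RunConfig field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    if "grid" in raw:
        grid = dict(raw["grid"])
        if grid.get("f_mark_anchor") is not None:
            grid["f_mark_anchor"] = tuple(grid["f_mark_anchor"])
        out["grid"] = GridSpec(**grid)
    if "scene" in raw:
        scene = dict(raw["scene"])
        cov = scene.get("coverage_fraction_dist")
        if isinstance(cov, list):
            scene["coverage_fraction_dist"] = tuple(cov)
        out["scene"] = SceneParams(**scene)
    out["run"] = dict(raw.get("run", {}))
    return out
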