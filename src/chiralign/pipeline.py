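"""End-to-end orchestration: image → angles → group statistics → report.

`run_image_pipeline` executes the full workflow on a stitched image
(grid registration → primary crop and rotation → cell-area detection
and the 80% exclusion filter → central crop → structure-tensor dominant
orientation → axial circular summary and chirality call), writing a
per-rectangle manifest with the reason for every exclusion, the angle
table, a JSON summary and a frequency histogram.  `run_stats_only`
applies the statistics to pre-extracted angle tables (the deposited
raw-data layout), including pairwise Watson U² tests.

Outputs are deterministic for a fixed configuration and seed (plots
excepted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import io as _io
from .circstats import (
    AngleSample,
    CircularSummary,
    frequency_distribution,
    summarize,
    watson_u2_test,
)
from .cropping import detect_cell_region, locate_grid, primary_crop, secondary_crop
from .geometry import GridSpec
from .orientation import dominant_orientation

__all__ = ["RunConfig", "run_image_pipeline", "run_stats_only"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str | None = None
    outdir: str | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    grad_sigma: float = 1.0
    coverage_threshold: float = 0.8
    bin_width_deg: float = 10.0
    ci_level: float = 0.95
    n_perm: int = 9999
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.coverage_threshold <= 1.0):
            raise ValueError("coverage_threshold must be in (0, 1]")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def _histogram_png(path: Path, sample: AngleSample, summary: CircularSummary,
                   bin_width: float) -> None:
    table = frequency_distribution(sample, bin_width)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(table.bin_left_deg + bin_width / 2, table["count"],
           width=bin_width * 0.92, color="#4878a8", edgecolor="none")
    ax.axvline(summary.mean_deg, color="crimson", lw=2,
               label=f"circular mean {summary.mean_deg:.2f}°")
    ax.axvline(0.0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("dominant orientation θ (deg)")
    ax.set_ylabel("rectangles")
    ax.set_xlim(-90, 90)
    ax.set_title(f"{sample.label}: n={summary.n}, SD={summary.sd_deg:.2f}°, "
                 f"{summary.chirality}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_image_pipeline(config: RunConfig, image=None):
    """Run the full image workflow.

    Returns ``(angles_df, summary, report)``; ``summary`` is None when
    no rectangle survives the coverage filter (the report then carries
    the explicit no-data status).  Fiducial-missing / image-flipped
    errors propagate to the caller (the CLI maps them to exit code 2).
    """
    if image is None:
        image = _io.read_image(config.input_path)
    grid = config.grid
    rois = locate_grid(image, grid)

    manifest_rows, angle_rows = [], []
    for roi in rois:
        crop = primary_crop(image, roi)
        region = detect_cell_region(crop, grid, config.coverage_threshold)
        reason = ""
        if not region.included:
            reason = (f"cell area {region.area_fraction:.3f} of pattern < "
                      f"{config.coverage_threshold:g}")
        else:
            central = secondary_crop(crop, region, grid)
            result = dominant_orientation(central, config.grad_sigma)
            if result.indeterminate:
                reason = "orientation indeterminate (blank crop)"
            else:
                angle_rows.append({
                    "rect_id": roi.rect_id,
                    "theta_deg": result.theta_deg,
                    "coherence": result.coherence,
                    "energy": result.energy,
                })
        manifest_rows.append({
            "rect_id": roi.rect_id,
            "included": region.included and not reason,
            "area_fraction": region.area_fraction,
            "center_row": region.center_px[0],
            "center_col": region.center_px[1],
            "rotated": roi.rotated,
            "reason": reason,
        })

    manifest = pd.DataFrame(manifest_rows)
    angles = pd.DataFrame(angle_rows,
                          columns=["rect_id", "theta_deg", "coherence", "energy"])

    label = Path(config.input_path).stem if config.input_path else "image"
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(outdir / "manifest.csv", index=False)
        angles.to_csv(outdir / "angles.csv", index=False)

    if len(angles) == 0:
        report = {
            "status": "no-data",
            "message": "no rectangle survived the coverage filter",
            "n_rectangles": len(rois),
            "n_included": 0,
        }
        if outdir:
            _write_json(outdir / "summary.json", report)
        return angles, None, report

    sample = AngleSample(label, angles.theta_deg.to_numpy())
    summary = summarize(sample, level=config.ci_level, seed=config.seed)
    hist = frequency_distribution(sample, config.bin_width_deg)
    report = {
        "status": "ok",
        "n_rectangles": len(rois),
        "n_included": int(manifest.included.sum()),
        "summary": summary.as_dict(),
        "histogram": hist.to_dict(orient="list"),
    }
    if outdir:
        _write_json(outdir / "summary.json", report)
        _histogram_png(outdir / "histogram.png", sample, summary,
                       config.bin_width_deg)
    return angles, summary, report


def run_stats_only(config: RunConfig, table_paths=None, *,
                   samples: dict[str, AngleSample] | None = None,
                   pairs: list[tuple[str, str]] | None = None) -> dict:
    """Circular summaries per group plus pairwise Watson U² tests.

    Groups are read from CSV/XLSX angle tables (or passed directly as
    ``samples``).  ``pairs`` restricts the two-sample tests to named
    group pairs; by default every pair with n ≥ 8 in both groups is
    tested.  Groups too small for a test are reported with a warning
    and skipped.
    """
    if samples is None:
        samples = _io.read_angle_tables(table_paths)
    warnings = []
    groups = {}
    for label, s in samples.items():
        if s.n < 1:
            warnings.append(f"group {label!r} is empty; skipped")
            continue
        groups[label] = summarize(s, level=config.ci_level,
                                  seed=config.seed).as_dict()

    if pairs is None:
        pairs = list(combinations([g for g in groups], 2))
    tests = []
    for a, b in pairs:
        if a not in samples or b not in samples:
            warnings.append(f"pair ({a}, {b}): unknown group; skipped")
            continue
        if samples[a].n < 8 or samples[b].n < 8:
            warnings.append(f"pair ({a}, {b}): fewer than 8 angles per "
                            "group; test skipped")
            continue
        res = watson_u2_test(samples[a], samples[b], n_perm=config.n_perm,
                             seed=config.seed)
        tests.append({"a": a, "b": b, "u2": res.u2, "p_value": res.p_value,
                      "method": res.method, "n_perm": res.n_perm})

    report = {"groups": groups, "pairwise_watson_u2": tests,
              "warnings": warnings}
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_json(outdir / "stats.json", report)
        for label, s in samples.items():
            if s.n >= 1 and label in groups:
                hist = frequency_distribution(s, config.bin_width_deg)
                safe = "".join(ch if ch.isalnum() or ch in "-_" else "_"
                               for ch in label)
                hist.to_csv(outdir / f"hist_{safe}.csv", index=False)
    return report
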