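"""File formats and batch structures.

On-disk conventions (all lossless, text- or PNG-class):

* RGB images — 8-bit 3-channel PNG;
* depth maps — 16-bit grayscale PNG in integer millimetres (range 0-65 m),
  or ``.npy`` float matrices in mm for sub-millimetre test data;
* masks — 8-bit PNG, 0 / 255;
* seeds, scene truths, intake reports — JSON;
* metric tables — CSV;
* configuration — YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import metrics as metrics_mod
from .errors import ConfigError, DepthPlateError, FormatError
from .pipeline import PipelineConfig, process_scene
from .synthetic import RGBDFrame, Scene, SceneTruth
from .volumetrics import IntakeReport, food_volume


# ------------------------------------------------------------ basic arrays


def read_rgb(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FormatError(f"{path}: expected an 8-bit 3-channel image, got {arr.shape}")
    return arr[..., :3]


def write_rgb(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(rgb, dtype=np.uint8))


def read_depth(path: str | Path) -> np.ndarray:
    """Depth in float mm from 16-bit PNG (integer mm) or .npy (float mm)."""
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path).astype(float)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: depth must be single-channel, got {arr.shape}")
    return arr.astype(float)


def write_depth(path: str | Path, depth_mm: np.ndarray) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.asarray(depth_mm, dtype=float))
        return
    arr = np.asarray(depth_mm)
    if np.nanmax(arr) >= 2**16:
        raise FormatError("depth exceeds the 16-bit integer-mm range")
    iio.imwrite(path, np.round(np.nan_to_num(arr)).astype(np.uint16))


def write_seeds(path: str | Path, seeds) -> None:
    """Serialise stroke seeds as JSON polylines ((row, col) vertex lists)."""
    doc = {
        "foreground": [[list(pt) for pt in stroke] for stroke in seeds.foreground],
        "background": [list(pt) for pt in seeds.background],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def read_seeds(path: str | Path):
    from .baselines import SeedAnnotation

    with open(path) as fh:
        doc = json.load(fh)
    return SeedAnnotation(
        foreground=tuple(
            tuple(tuple(int(v) for v in pt) for pt in stroke)
            for stroke in doc["foreground"]
        ),
        background=tuple(tuple(int(v) for v in pt) for pt in doc["background"]),
    )


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


# --------------------------------------------------------------- batches


@dataclass(frozen=True)
class AcquisitionRecord:
    """One acquisition: a calibration or plate shot of a given plate."""

    plate_id: str
    role: str  # calibration | plate
    rgb: Path
    depth: tuple[Path, ...]
    portion: str = ""
    truth_mask: Path | None = None
    diameter_mm: float = 259.0

    def __post_init__(self) -> None:
        if self.role not in ("calibration", "plate"):
            raise ConfigError(f"unknown acquisition role {self.role!r}")


def read_rgbd(record: AcquisitionRecord) -> list[RGBDFrame]:
    """Load a record as a burst of co-registered RGB-D frames."""
    rgb = read_rgb(record.rgb)
    frames = []
    for p in record.depth:
        depth = read_depth(p)
        if depth.shape != rgb.shape[:2]:
            raise FormatError(
                f"{p}: depth shape {depth.shape} does not match RGB {rgb.shape[:2]}"
            )
        frames.append(RGBDFrame(rgb=rgb, depth=depth))
    if not frames:
        raise FormatError(f"record {record.plate_id}/{record.role}: no depth frames")
    return frames


def load_batch(path: str | Path) -> list[AcquisitionRecord]:
    """Read a batch description YAML into acquisition records."""
    root = Path(path).parent
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    records = []
    for entry in doc.get("acquisitions", []):
        records.append(
            AcquisitionRecord(
                plate_id=str(entry["plate_id"]),
                role=entry["role"],
                rgb=root / entry["rgb"],
                depth=tuple(root / p for p in entry["depth"]),
                portion=str(entry.get("portion", "")),
                truth_mask=(root / entry["truth_mask"]) if entry.get("truth_mask") else None,
                diameter_mm=float(entry.get("diameter_mm", 259.0)),
            )
        )
    return records


def export_scene(scene: Scene, out_dir: str | Path, stem: str = "scene") -> dict:
    """Write a rendered scene in the standard fixture layout.

    Returns the manifest of written paths (also dumped as JSON) so a batch
    YAML can reference them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"calibration_depth": [], "plate_depth": []}
    write_rgb(out / f"{stem}_calib_rgb.png", scene.calibration[0].rgb)
    write_rgb(out / f"{stem}_plate_rgb.png", scene.plate[0].rgb)
    paths["calibration_rgb"] = f"{stem}_calib_rgb.png"
    paths["plate_rgb"] = f"{stem}_plate_rgb.png"
    for i, f in enumerate(scene.calibration):
        name = f"{stem}_calib_depth_{i:02d}.npy"
        write_depth(out / name, f.depth)
        paths["calibration_depth"].append(name)
    for i, f in enumerate(scene.plate):
        name = f"{stem}_plate_depth_{i:02d}.npy"
        write_depth(out / name, f.depth)
        paths["plate_depth"].append(name)
    write_mask(out / f"{stem}_truth_mask.png", scene.truth.mask)
    paths["truth_mask"] = f"{stem}_truth_mask.png"
    truth = {
        "volume_ml": scene.truth.volume_ml,
        "item_volumes_ml": list(scene.truth.item_volumes_ml),
        "portion": scene.truth.portion,
    }
    with open(out / f"{stem}_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    paths["truth_json"] = f"{stem}_truth.json"
    with open(out / f"{stem}_manifest.json", "w") as fh:
        json.dump(paths, fh, indent=2)
    return paths


# ------------------------------------------------------------ batch runs


METRIC_COLUMNS = [
    "method",
    "GSA",
    "FSA",
    "IOU",
    "intake_error_2d_pct",
    "intake_error_3d_pct",
    "mean_absolute_error_ml",
    "mean_error_bias_ml",
    "volume_intake_error_ml",
]


def run_pipeline(
    records: list[AcquisitionRecord],
    config: PipelineConfig | None = None,
) -> tuple[list[IntakeReport], pd.DataFrame, list[str]]:
    """Execute the full pipeline over a batch of acquisition records.

    Records are grouped by ``plate_id``; each group needs exactly one
    calibration record, and its plate records are treated as an intake
    series ordered by portion label (the first is the full reference).
    A failing plate is logged and skipped, not fatal to the batch.

    Returns intake reports, a per-plate metric table (rows only where
    ground-truth masks were provided) and the failure log.
    """
    config = config or PipelineConfig()
    groups: dict[str, dict] = {}
    for rec in records:
        g = groups.setdefault(rec.plate_id, {"calibration": None, "plates": []})
        if rec.role == "calibration":
            g["calibration"] = rec
        else:
            g["plates"].append(rec)

    reports: list[IntakeReport] = []
    rows: list[dict] = []
    failures: list[str] = []
    for plate_id, g in groups.items():
        if g["calibration"] is None:
            raise ConfigError(f"plate {plate_id!r} has no calibration record")
        try:
            calib_frames = read_rgbd(g["calibration"])
            series = sorted(g["plates"], key=lambda r: r.portion)
            pred_px, gt_px, pred_vol, gt_vol = [], [], [], []
            results = []
            for rec in series:
                plate_frames = read_rgbd(rec)
                truth_mask = read_mask(rec.truth_mask) if rec.truth_mask else None
                truth = SceneTruth(
                    mask=truth_mask if truth_mask is not None else np.zeros(1, bool),
                    height_mm=np.zeros(1),
                    volume_ml=0.0,
                    item_volumes_ml=(),
                    portion=rec.portion or "P?",
                ) if truth_mask is not None else None
                scene = Scene(
                    calibration=calib_frames,
                    plate=plate_frames,
                    truth=truth,
                    spec=None,  # in-memory only; file batches carry no spec
                )
                result = process_scene(scene, config)
                results.append((rec, result, truth_mask))
            full = results[0][1].volume_ml
            for rec, result, truth_mask in results:
                reports.append(
                    IntakeReport(
                        plate_id=plate_id,
                        portion=rec.portion or "P?",
                        plate_volume_ml=result.volume_ml,
                        full_portion_volume_ml=full,
                        mask_source=config.segmenter,
                        refined=config.refine,
                    )
                )
                if truth_mask is not None:
                    c = metrics_mod.confusion_counts(truth_mask, result.refined_mask)
                    pred_px.append(np.count_nonzero(result.refined_mask))
                    gt_px.append(np.count_nonzero(truth_mask))
                    pred_vol.append(result.volume_ml)
                    gt_vol.append(
                        food_volume(result.height, truth_mask, result.scale_mm_per_px)
                    )
                    rows.append(
                        {
                            "plate_id": plate_id,
                            "portion": rec.portion,
                            "method": config.segmenter + ("-D" if config.refine else ""),
                            "GSA": metrics_mod.global_accuracy(c),
                            "FSA": metrics_mod.food_segmentation_accuracy(c),
                            "IOU": metrics_mod.iou(truth_mask, result.refined_mask),
                        }
                    )
            if gt_px and gt_px[0] > 0 and gt_vol[0] > 0:
                e2 = metrics_mod.intake_error_2d(pred_px, gt_px)
                e3 = metrics_mod.intake_error_3d(pred_vol, gt_vol)
                stats = metrics_mod.volume_error_stats(pred_vol, gt_vol)
                for i, row in enumerate(rows[-len(gt_px):]):
                    row["intake_error_2d_pct"] = e2[i]
                    row["intake_error_3d_pct"] = e3[i]
                    row["mean_absolute_error_ml"] = stats.mean_absolute_error_ml
                    row["mean_error_bias_ml"] = stats.mean_error_bias_ml
                    row["volume_intake_error_ml"] = stats.volume_intake_error_ml[i]
        except DepthPlateError as exc:
            failures.append(f"plate {plate_id!r}: {exc}")
    table = pd.DataFrame(rows)
    return reports, table, failures


def summarize_metric_table(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD per method over the per-plate metric table."""
    cols = [c for c in METRIC_COLUMNS[1:] if c in table.columns]
    if table.empty:
        return pd.DataFrame(columns=["method"] + [f"{c}_{s}" for c in cols for s in ("mean", "sd")])
    out = []
    for method, grp in table.groupby("method"):
        row: dict = {"method": method}
        for c in cols:
            s = metrics_mod.summarize(grp[c].dropna()) if grp[c].notna().any() else None
            row[f"{c}_mean"] = s.mean if s else np.nan
            row[f"{c}_sd"] = s.sd if s else np.nan
        out.append(row)
    return pd.DataFrame(out)


def write_reports(
    reports: list[IntakeReport],
    table: pd.DataFrame,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    log: list[str] | None = None,
) -> None:
    """Write per-plate JSON reports, the CSV metric tables and a run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for r in reports:
        with open(out / f"report_{r.plate_id}_{r.portion}.json", "w") as fh:
            json.dump(r.to_dict(), fh, indent=2)
    pd.DataFrame([r.to_dict() for r in reports]).to_csv(out / "reports.csv", index=False)
    table.to_csv(out / "metrics_per_plate.csv", index=False)
    summarize_metric_table(table).to_csv(out / "metrics_summary.csv", index=False)
    with open(out / "run.log", "w") as fh:
        if config is not None:
            fh.write(f"config: {config}\n")
        for line in log or []:
            fh.write(line + "\n")
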