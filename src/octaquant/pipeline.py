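"""Disk formats and cohort-level orchestration.

On-disk layout of a generated cohort directory::

    cohort/
      manifest.json                     # config hash, seed, counts
      metadata.csv                      # one row per eye: covariates + paths
      truth.csv                         # drawn ground-truth outcomes per eye
      eyes/<participant>_<eye>_SCP.png  # 8-bit grayscale slabs
      eyes/<participant>_<eye>_DCP.png
      eyes/<participant>_<eye>_CC.png
      eyes/<participant>_<eye>_SCP.faz.json
      eyes/<participant>_<eye>_DCP.faz.json

FAZ annotation JSON dialect: ``{"slab": "SCP"|"DCP", "polygon_px":
[[x, y], ...]}`` with 0-based pixel-center coordinates, x rightward,
y downward, polygon implicitly closed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .magnification import EyeBiometry
from .metrics import OUTCOME_COLUMNS, AnalysisParams, compute_eye_metrics
from .segmentation import EnFaceAngiogram, FazAnnotation
from .synthetic import CohortConfig, EyeBundle, generate_truth_table, iter_cohort

__all__ = [
    "write_cohort",
    "read_metadata",
    "load_eye",
    "measure_eye_files",
    "measure_cohort_dir",
    "measure_bundles",
    "run_cohort",
    "write_faz_annotation",
    "read_faz_annotation",
]

log = logging.getLogger("octaquant")

RECORD_COLUMNS = (
    "participant_id", "eye", "group", "age", "gender", "iop_mmHg",
    "axial_length_mm", "hypertension", "signal_strength", "duration_years",
    "episodes", "rnfl_um",
)


def write_faz_annotation(path: Path, annotation: FazAnnotation) -> None:
    payload = {
        "slab": annotation.slab,
        "polygon_px": np.asarray(annotation.polygon_px, dtype=float).round(4).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_faz_annotation(path: Path) -> FazAnnotation:
    payload = json.loads(Path(path).read_text())
    return FazAnnotation(slab=payload["slab"], polygon_px=np.asarray(payload["polygon_px"]))


def _config_hash(config: CohortConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_cohort(config: CohortConfig, out_dir: Path, force: bool = False) -> Path:
    """Generate a cohort and write it to ``out_dir``; returns the directory.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    eyes_dir = out / "eyes"
    eyes_dir.mkdir(parents=True, exist_ok=True)

    frame = generate_truth_table(config)
    meta_rows = []
    for i, bundle in iter_cohort(config):
        rec = bundle.record
        stem = f"{rec.participant_id}_{rec.eye}"
        paths = {}
        for slab, ang in bundle.images.items():
            p = eyes_dir / f"{stem}_{slab}.png"
            iio.imwrite(p, ang.pixels.astype(np.uint8))
            paths[slab] = str(p.relative_to(out))
        for slab, annot in bundle.faz.items():
            p = eyes_dir / f"{stem}_{slab}.faz.json"
            write_faz_annotation(p, annot)
            paths[f"{slab}_faz"] = str(p.relative_to(out))
        row = {c: getattr(rec, c) for c in RECORD_COLUMNS}
        row["paths"] = json.dumps(paths)
        row.update({f"truth_{k}": v for k, v in bundle.truth.as_dict().items()})
        meta_rows.append(row)
        if (i + 1) % 50 == 0:
            log.info("generated %d eyes", i + 1)
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(out / "metadata.csv", index=False)
    frame.to_csv(out / "truth.csv", index=False)
    manifest = {
        "config_hash": _config_hash(config),
        "master_seed": config.master_seed,
        "n_eyes": len(meta),
        "n_participants": int(meta["participant_id"].nunique()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_metadata(cohort_dir: Path) -> pd.DataFrame:
    cohort_dir = Path(cohort_dir)
    if not (cohort_dir / "manifest.json").exists():
        raise FileNotFoundError(f"no manifest.json in {cohort_dir}")
    return pd.read_csv(cohort_dir / "metadata.csv")


def load_eye(
    cohort_dir: Path, row: pd.Series
) -> Tuple[Dict[str, EnFaceAngiogram], Dict[str, FazAnnotation]]:
    """Load one eye's slab images and FAZ annotations from disk."""
    cohort_dir = Path(cohort_dir)
    paths = json.loads(row["paths"])
    images = {
        slab: EnFaceAngiogram(iio.imread(cohort_dir / paths[slab]), slab)
        for slab in ("SCP", "DCP", "CC")
    }
    faz = {
        slab: read_faz_annotation(cohort_dir / paths[f"{slab}_faz"])
        for slab in ("SCP", "DCP")
    }
    return images, faz


def measure_eye_files(
    cohort_dir: Path, row: pd.Series, params: AnalysisParams = AnalysisParams()
) -> Dict[str, float]:
    images, faz = load_eye(cohort_dir, row)
    biometry = EyeBiometry(float(row["axial_length_mm"]))
    return compute_eye_metrics(images, faz, biometry, params).as_dict()


def measure_cohort_dir(
    cohort_dir: Path, params: AnalysisParams = AnalysisParams()
) -> Tuple[pd.DataFrame, List[str]]:
    """Measure every eye of an on-disk cohort.

    Returns the metrics table (covariates + nine outcomes, one row per eye)
    and a list of per-eye failure messages; failed eyes are skipped so one
    corrupt file does not abort the run.
    """
    meta = read_metadata(cohort_dir)
    rows, failures = [], []
    for i, row in meta.iterrows():
        try:
            m = measure_eye_files(cohort_dir, row, params)
        except Exception as exc:  # noqa: BLE001 - row-level error, recorded
            msg = f"{row['participant_id']}_{row['eye']}: {exc}"
            failures.append(msg)
            log.warning("measurement failed for %s", msg)
            continue
        out = {c: row[c] for c in RECORD_COLUMNS}
        out.update(m)
        rows.append(out)
        if (i + 1) % 50 == 0:
            log.info("measured %d eyes", i + 1)
    return pd.DataFrame(rows), failures


def measure_bundles(
    bundles: Iterable[EyeBundle], params: AnalysisParams = AnalysisParams()
) -> pd.DataFrame:
    """Measure in-memory eye bundles (no disk round trip)."""
    rows = []
    for b in bundles:
        biometry = EyeBiometry(b.record.axial_length_mm)
        m = compute_eye_metrics(b.images, b.faz, biometry, params)
        out = {c: getattr(b.record, c) for c in RECORD_COLUMNS}
        out.update(m.as_dict())
        out.update({f"truth_{k}": v for k, v in b.truth.as_dict().items()})
        rows.append(out)
    return pd.DataFrame(rows)


def run_cohort(
    config: CohortConfig,
    params: Optional[AnalysisParams] = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Generate and measure a whole cohort eye by eye, in memory.

    The returned frame holds covariates, measured outcomes, and the
    counted ground truths (``truth_*`` columns) for validation.
    """
    if params is None:
        params = AnalysisParams(lv_removal_radius_px=config.lv_removal_radius_px)
    rows = []
    for i, b in iter_cohort(config):
        biometry = EyeBiometry(b.record.axial_length_mm, camera_factor_p=config.camera_factor_p)
        m = compute_eye_metrics(b.images, b.faz, biometry, params)
        out = {c: getattr(b.record, c) for c in RECORD_COLUMNS}
        out.update(m.as_dict())
        out.update({f"truth_{k}": v for k, v in b.truth.as_dict().items()})
        rows.append(out)
        if progress and (i + 1) % 20 == 0:
            log.info("processed %d eyes", i + 1)
    return pd.DataFrame(rows)
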