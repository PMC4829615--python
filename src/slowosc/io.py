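"""Cohort serialization: NIfTI-1 / TSV scans, manifests, motion tracks.

A cohort on disk is a manifest TSV with columns ``subject_id, group,
data_path, tr, motion_path`` (motion optional).  Scan data is either a
4D NIfTI-1 volume or a TSV matrix (voxels x time); both round-trip to
the same in-memory ``CohortScan`` and yield identical downstream
results.  All frequencies and parameters are serialized in plain text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .simulate import CohortScan, GroundTruth

__all__ = ["read_cohort", "write_cohort", "write_ground_truth", "read_motion", "write_motion"]

MANIFEST_COLUMNS = ["subject_id", "group", "data_path", "tr"]
MOTION_COLUMNS = ["x_mm", "y_mm", "z_mm", "roll_deg", "pitch_deg", "yaw_deg"]


def write_motion(motion: np.ndarray, path: Path) -> None:
    pd.DataFrame(motion, columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_motion(path: Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_cohort(
    scans: Sequence[CohortScan],
    outdir: str | Path,
    format: str = "tsv",
) -> Path:
    """Write scans + manifest under ``outdir``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in scans:
        if format == "nifti":
            fname = f"{scan.subject_id}.nii"
            img = nib.Nifti1Image(
                scan.volume().astype(np.float32), affine=np.eye(4)
            )
            img.header.set_zooms((1.0, 1.0, 1.0, scan.tr_seconds))
            nib.save(img, outdir / fname)
        elif format == "tsv":
            fname = f"{scan.subject_id}.tsv"
            np.savetxt(outdir / fname, scan.data, delimiter="\t", fmt="%.8g")
        else:
            raise ValidationError(f"unknown format {format!r}")
        row = {
            "subject_id": scan.subject_id,
            "group": scan.group,
            "data_path": fname,
            "tr": scan.tr_seconds,
        }
        if scan.motion is not None:
            mname = f"{scan.subject_id}_motion.tsv"
            write_motion(scan.motion, outdir / mname)
            row["motion_path"] = mname
        rows.append(row)
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[CohortScan]:
    """Load a cohort from its manifest; validates grid and TR uniformity."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    base = manifest_path.parent
    scans: list[CohortScan] = []
    for i, row in df.iterrows():
        path = base / str(row["data_path"])
        if not path.exists():
            raise ValidationError(f"manifest row {i} ({row['subject_id']}): {path} not found")
        try:
            if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
                img = nib.load(str(path))
                vol = np.asarray(img.dataobj, dtype=float)
                if vol.ndim != 4:
                    raise ValidationError(f"{path}: expected 4D volume")
                data = vol.reshape(-1, vol.shape[-1])
                shape3d = vol.shape[:3]
            else:
                data = np.loadtxt(path, delimiter="\t", ndmin=2)
                shape3d = None
        except (OSError, ValueError) as exc:
            raise ValidationError(
                f"manifest row {i} ({row['subject_id']}): cannot read {path}: {exc}"
            ) from exc
        motion = None
        if "motion_path" in df.columns and isinstance(row.get("motion_path"), str):
            motion = read_motion(base / row["motion_path"])
        scans.append(
            CohortScan(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                data=data,
                tr_seconds=float(row["tr"]),
                motion=motion,
                shape3d=shape3d,
            )
        )
    trs = {s.tr_seconds for s in scans}
    if len(trs) > 1:
        raise ValidationError(f"mixed TR across cohort: {sorted(trs)}")
    grids = {s.n_voxels for s in scans}
    if len(grids) > 1:
        raise ValidationError(f"mixed voxel grids across cohort: {sorted(grids)}")
    return scans


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> None:
    """Persist generator ground truth: JSON summary + TSV maps/time courses."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
    maps = pd.DataFrame({label: m for label, m in truth.maps.items()})
    maps.to_csv(outdir / "true_maps.tsv", sep="\t", index=False)
    tc_dir = outdir / "true_timecourses"
    tc_dir.mkdir(exist_ok=True)
    for sid, tcs in truth.timecourses.items():
        pd.DataFrame(tcs).to_csv(tc_dir / f"{sid}.tsv", sep="\t", index=False)
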