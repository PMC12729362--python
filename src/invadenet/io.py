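"""Disk formats: per-patient NIfTI volumes (phases stacked on the third
axis), NIfTI masks, and a cohort manifest CSV."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PhantomSample
from .preprocess import RoiBox

__all__ = ["write_cohort", "read_cohort", "read_manifest"]

_AFFINE = np.eye(4)


def _save_nifti(path: Path, data: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _AFFINE), str(path))


def write_cohort(samples: list[PhantomSample], out_dir) -> Path:
    """Write phases + masks as NIfTI and a manifest CSV; returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        img = out / f"{s.patient_id}_phases.nii.gz"
        tum = out / f"{s.patient_id}_tumor.nii.gz"
        wal = out / f"{s.patient_id}_wall.nii.gz"
        _save_nifti(img, s.phases)
        _save_nifti(tum, s.tumor_mask.astype(np.float32))
        _save_nifti(wal, s.wall_mask.astype(np.float32))
        rows.append(
            {
                "patient_id": s.patient_id,
                "label": s.label,
                "n_phases": s.n_phases_actual,
                "roi": json.dumps(
                    [s.roi.row_start, s.roi.row_stop, s.roi.col_start, s.roi.col_stop]
                ),
                "phases_path": img.name,
                "tumor_mask_path": tum.name,
                "wall_mask_path": wal.name,
                "clean_curve": json.dumps(list(np.round(s.clean_curve, 6))),
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path) -> pd.DataFrame:
    path = Path(manifest_path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    return pd.read_csv(path)


def read_cohort(manifest_path) -> list[PhantomSample]:
    """Reload a cohort written by :func:`write_cohort`."""
    path = Path(manifest_path)
    df = read_manifest(path)
    base = path.parent
    samples = []
    for _, row in df.iterrows():
        phases = np.asarray(
            nib.load(str(base / row["phases_path"])).get_fdata(), dtype=np.float64
        )
        tumor = np.asarray(
            nib.load(str(base / row["tumor_mask_path"])).get_fdata()
        ).astype(bool)
        wall = np.asarray(
            nib.load(str(base / row["wall_mask_path"])).get_fdata()
        ).astype(bool)
        r0, r1, c0, c1 = json.loads(row["roi"])
        samples.append(
            PhantomSample(
                patient_id=str(row["patient_id"]),
                phases=phases,
                tumor_mask=tumor,
                wall_mask=wall,
                label=int(row["label"]),
                roi=RoiBox(r0, r1, c0, c1),
                n_phases_actual=int(row["n_phases"]),
                clean_curve=np.asarray(json.loads(row["clean_curve"])),
            )
        )
    return samples
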