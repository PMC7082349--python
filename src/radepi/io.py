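"""NIfTI and manifest I/O for cohorts on disk."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from radepi.synthetic import PhantomStudy
from radepi.volume import ImageVolume, RoiMask


def _affine(spacing, origin) -> np.ndarray:
    """RAS+ affine with diagonal spacing and the given origin (mm)."""
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def write_study(study: PhantomStudy, out_dir: Path) -> tuple[Path, Path]:
    """Write one study's volume and mask as NIfTI-1 (.nii.gz)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pid = study.record.patient_id
    vol_path = out_dir / f"{pid}_volume.nii.gz"
    mask_path = out_dir / f"{pid}_mask.nii.gz"
    aff = _affine(study.volume.voxel_spacing, study.volume.origin)
    try:
        nib.save(nib.Nifti1Image(study.volume.intensities.astype(np.float32), aff), vol_path)
        nib.save(
            nib.Nifti1Image(study.mask.support.astype(np.uint8), aff), mask_path
        )
    except OSError as exc:  # pragma: no cover - disk-level failure
        raise OSError(f"failed to write study {pid} under {out_dir}: {exc}") from exc
    return vol_path, mask_path


def read_study_arrays(vol_path: Path, mask_path: Path) -> tuple[ImageVolume, RoiMask]:
    """Load a volume + mask pair written by :func:`write_study`."""
    img = nib.load(str(vol_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    volume = ImageVolume(np.asanyarray(img.dataobj, dtype=float), spacing, origin)
    mask = RoiMask(np.asanyarray(msk.dataobj) > 0)
    return volume, mask


def write_cohort(studies, manifest: pd.DataFrame, out_dir: Path) -> Path:
    """Write all studies plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = manifest.copy()
    vol_paths, mask_paths = [], []
    for study in studies:
        vp, mp = write_study(study, out_dir / "images")
        vol_paths.append(str(vp.relative_to(out_dir)))
        mask_paths.append(str(mp.relative_to(out_dir)))
    rows["volume_path"] = vol_paths
    rows["mask_path"] = mask_paths
    manifest_path = out_dir / "manifest.csv"
    rows.to_csv(manifest_path, index=False)
    return manifest_path
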