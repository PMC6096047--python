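"""ROI definitions and cohort ingestion.

ROI masks may be NIfTI volumes (the voxel-to-mm affine is honoured) or
plain coordinate tables (TSV with x/y/z columns in mm and an roi column).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["roi_table_from_nifti", "load_roi_table", "load_cohort_dir"]


def roi_table_from_nifti(path: str | Path, roi_label: str) -> pd.DataFrame:
    """Voxel mm-coordinate table of the nonzero voxels of a NIfTI mask."""
    import nibabel as nib

    img = nib.load(str(path))
    mask = np.asanyarray(img.dataobj) != 0
    ijk = np.column_stack(np.nonzero(mask))
    xyz = nib.affines.apply_affine(img.affine, ijk)
    return pd.DataFrame({"x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
                         "roi": roi_label})


def load_roi_table(path: str | Path, roi_label: str | None = None) -> pd.DataFrame:
    """Load an ROI definition from NIfTI (.nii/.nii.gz) or TSV."""
    p = Path(path)
    if p.suffix in (".nii", ".gz"):
        if roi_label is None:
            raise ValueError("NIfTI masks need an explicit roi label")
        return roi_table_from_nifti(p, roi_label)
    tab = pd.read_csv(p, sep="\t")
    missing = {"x", "y", "z", "roi"} - set(tab.columns)
    if missing:
        raise ValueError(f"ROI table {p} lacks columns: {sorted(missing)}")
    return tab


def load_cohort_dir(path: str | Path):
    """Re-load a cohort saved by :func:`mvblife.cohort.save_cohort`."""
    from .cohort import ROIDataset, Subject, TrialTable
    from .design import ScanParams, build_design_matrix

    root = Path(path)
    cfg = json.loads((root / "cohort.json").read_text())
    paradigm = cfg.get("paradigm", "LTM")
    subjects = []
    for sdir in sorted(p for p in root.iterdir() if p.is_dir()):
        trials = TrialTable.from_tsv(sdir / "events.tsv", paradigm)
        arr = np.load(sdir / "data.npz", allow_pickle=False)
        data = ROIDataset(
            data=arr["data"], voxel_mm=arr["voxel_mm"],
            roi_labels=arr["roi_labels"].astype(str),
            session_index=arr["session_index"], tr=float(arr["tr"]))
        truth_meta = json.loads((sdir / "truth.json").read_text())
        n = int(arr["data"].shape[0] / len(np.unique(arr["session_index"])))
        design = build_design_matrix(
            trials, ScanParams(tr=float(arr["tr"]), n_scans_per_session=n),
            voxel_mm=arr["voxel_mm"])
        subjects.append(Subject(sdir.name, float(truth_meta["age"]), trials,
                                design, data, None))
    return subjects
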