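"""First-level design matrices: HRF-convolved task regressors, motion and
cosine drift confounds, target contrasts, and grand-mean scaling.

Event regressors are built per session with nilearn's design machinery
(canonical double-gamma HRF, cosine high-pass basis at 1/128 Hz) and the
session blocks are concatenated block-diagonally with separate drift and
constant columns per session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from nilearn.glm.first_level import make_first_level_design_matrix

from .cohort import TrialTable

__all__ = [
    "ScanParams",
    "DesignMatrix",
    "build_design_matrix",
    "contrast_vector",
    "scale_grand_mean",
    "HIGH_PASS_HZ",
]

HIGH_PASS_HZ = 1.0 / 128.0   # slowest modelled fluctuation


@dataclass
class ScanParams:
    tr: float
    n_scans_per_session: int
    motion: np.ndarray | None = None   # (total scans, 6) rigid-body series

    def with_motion(self, rng: np.random.Generator, n_sessions: int | None = None,
                    step_sd: float = 0.02) -> "ScanParams":
        """Attach a smooth random-walk motion series (6 rigid-body params)."""
        n_sessions = n_sessions or 2
        n = self.n_scans_per_session
        blocks = [np.cumsum(rng.normal(0, step_sd, size=(n, 6)), axis=0)
                  for _ in range(n_sessions)]
        return ScanParams(self.tr, n, np.vstack(blocks))


@dataclass
class DesignMatrix:
    """Concatenated multi-session design with labelled columns.

    Column labels are ``s<session>/<name>``; task columns are the
    HRF-convolved event regressors, confounds are motion, cosine drifts and
    per-session constants.
    """

    matrix: np.ndarray
    labels: list[str]
    task_column_indices: np.ndarray
    confound_column_indices: np.ndarray
    feature_column_indices: np.ndarray   # columns defining the task F contrast
    session_index: np.ndarray            # per scan, 1-based
    tr: float
    trial_counts: pd.DataFrame           # per session x condition
    missing_conditions: list[str] = field(default_factory=list)
    voxel_mm: np.ndarray | None = None
    paradigm: str = "LTM"

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def column(self, label: str) -> int:
        return self.labels.index(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _session_events(trials: TrialTable, session: int,
                    collapse_forgotten: bool = True) -> pd.DataFrame:
    """Map one session's components to nilearn trial_type labels."""
    ev = trials.events[trials.events["session"] == session]
    rows = []
    for _, r in ev.iterrows():
        comp = r["component"]
        if trials.paradigm == "LTM":
            if comp == "scene":
                name = f"scene_{r['valence']}"
            elif comp == "object":
                if collapse_forgotten:
                    mem = "remembered" if r["memory"] == "remembered" else "forgotten"
                else:
                    if r["memory"] == "remembered":
                        mem = "remembered"
                    elif r["memory"] == "item_miss":
                        mem = "item_forgotten"
                    else:
                        mem = "assoc_forgotten"
                name = f"epoch_{r['valence']}_{mem}"
            else:
                name = "keypress"
        else:
            prefix = {"encoding": "enc", "maintenance": "maint", "probe": "probe"}[comp]
            name = f"{prefix}_{int(r['load'])}"
        rows.append(dict(trial_type=name, onset=r["onset"], duration=r["duration"]))
    return pd.DataFrame(rows)


def build_design_matrix(
    trials: TrialTable,
    scan_params: ScanParams,
    collapse_forgotten: bool = True,
    voxel_mm: np.ndarray | None = None,
) -> DesignMatrix:
    """Build the multi-session first-level design for a trial table.

    LTM: per session, 3 scene-onset delta regressors (by valence), epoch
    regressors by valence x subsequent memory (2-way, or 3-way when item
    misses are modelled separately), one shared keypress regressor, 6 motion
    regressors, cosine drift basis to 1/128 Hz and a constant.  STM: 3
    encoding + 3 maintenance + 3 probe regressors by load plus confounds.
    Conditions with no trials in a session yield no column and are recorded
    in ``missing_conditions``.
    """
    tr, n = scan_params.tr, scan_params.n_scans_per_session
    sessions = sorted(trials.events["session"].unique())
    frame_times = tr * np.arange(n)
    blocks, all_labels = [], []
    task_idx, conf_idx, feat_idx = [], [], []
    missing = []
    col_offset = 0

    if trials.paradigm == "LTM":
        mems = ["remembered", "forgotten"] if collapse_forgotten else [
            "remembered", "assoc_forgotten", "item_forgotten"]
        expected_task = ([f"scene_{v}" for v in ("positive", "neutral", "negative")]
                         + [f"epoch_{v}_{m}" for v in ("positive", "neutral", "negative")
                            for m in mems] + ["keypress"])
        feature_names = [lab for lab in expected_task if lab.startswith("epoch_")]
    else:
        expected_task = [f"{p}_{l}" for p in ("enc", "maint", "probe") for l in (1, 2, 3)]
        feature_names = [f"maint_{l}" for l in (1, 2, 3)]

    for s in sessions:
        events = _session_events(trials, s, collapse_forgotten)
        if events["onset"].max() > tr * n:
            raise ValueError(f"session {s}: trial onsets exceed the scan window")
        add_regs = None
        add_names = None
        if scan_params.motion is not None:
            si = sessions.index(s)
            add_regs = scan_params.motion[si * n:(si + 1) * n]
            add_names = [f"motion{j + 1}" for j in range(add_regs.shape[1])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dm = make_first_level_design_matrix(
                frame_times, events=events, hrf_model="spm",
                drift_model="cosine", high_pass=HIGH_PASS_HZ,
                add_regs=add_regs, add_reg_names=add_names)
        present = set(events["trial_type"])
        for name in expected_task:
            if name not in present:
                missing.append(f"s{s}/{name}")
        # stable column order: expected task names first, then confounds
        task_cols = [c for c in expected_task if c in dm.columns]
        conf_cols = [c for c in dm.columns if c not in task_cols]
        dm = dm[task_cols + conf_cols]
        for j, c in enumerate(dm.columns):
            gi = col_offset + j
            (task_idx if c in task_cols else conf_idx).append(gi)
            if c in feature_names:
                feat_idx.append(gi)
            all_labels.append(f"s{s}/{c}")
        blocks.append(dm.to_numpy())
        col_offset += dm.shape[1]

    total_cols = col_offset
    matrix = np.zeros((n * len(sessions), total_cols))
    r0, c0 = 0, 0
    for b in blocks:
        matrix[r0:r0 + b.shape[0], c0:c0 + b.shape[1]] = b
        r0 += b.shape[0]
        c0 += b.shape[1]

    anchor = trials.trials()
    if trials.paradigm == "LTM":
        mem2 = anchor["memory"].map(lambda m: "remembered" if m == "remembered"
                                    else "forgotten")
        counts = (anchor.assign(mem=mem2)
                  .groupby(["session", "valence", "mem"]).size()
                  .rename("n").reset_index())
    else:
        counts = (anchor.groupby(["session", "load"]).size()
                  .rename("n").reset_index())

    session_index = np.repeat(sessions, n)
    return DesignMatrix(
        matrix=matrix, labels=all_labels,
        task_column_indices=np.array(task_idx, int),
        confound_column_indices=np.array(conf_idx, int),
        feature_column_indices=np.array(feat_idx, int),
        session_index=np.asarray(session_index),
        tr=tr, trial_counts=counts, missing_conditions=missing,
        voxel_mm=voxel_mm, paradigm=trials.paradigm,
    )


def contrast_vector(design: DesignMatrix, kind: str = "subsequent_memory") -> np.ndarray:
    """Target contrast over design columns.

    ``subsequent_memory``: weighted mean of remembered epoch betas minus
    weighted mean of forgotten epoch betas, weights proportional to trial
    counts per session/valence.  ``load_linear``: linear load contrast
    [-1, 0, +1] on the maintenance regressors, averaged over runs.
    """
    c = np.zeros(design.n_regressors)
    if kind == "subsequent_memory":
        counts = design.trial_counts
        for mem, sign in (("remembered", 1.0), ("forgotten", -1.0)):
            sub = counts[counts["mem"] == mem]
            total = sub["n"].sum()
            if total == 0:
                raise ValueError(f"no {mem} trials: contrast undefined")
            for _, r in sub.iterrows():
                lab = f"s{r['session']}/epoch_{r['valence']}_{mem}"
                if lab in design.labels:
                    c[design.column(lab)] = sign * r["n"] / total
    elif kind == "load_linear":
        sessions = np.unique(design.session_index)
        for s in sessions:
            for load, w in ((1, -1.0), (2, 0.0), (3, 1.0)):
                lab = f"s{s}/maint_{load}"
                if lab in design.labels:
                    c[design.column(lab)] = w / len(sessions)
    else:
        raise ValueError(f"unknown contrast kind: {kind!r}")
    return c


def scale_grand_mean(dataset, target: float = 100.0):
    """Scale data to a grand mean of ``target`` over all voxels and scans,
    independently within each session."""
    from .cohort import ROIDataset

    data = dataset.data.copy()
    for s in dataset.sessions:
        mask = dataset.session_index == s
        m = data[mask].mean()
        if m <= 0:
            raise ValueError(f"session {s}: non-positive grand mean {m}")
        data[mask] *= target / m
    return ROIDataset(data=data, voxel_mm=dataset.voxel_mm,
                      roi_labels=dataset.roi_labels,
                      session_index=dataset.session_index, tr=dataset.tr)
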