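"""Per-subject dependent measures derived from GLM and MVB fits,
plus the inclusion rules applied before group inference."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mvb import MVBResults, MVBComparison

__all__ = ["SubjectRecord", "weight_spread", "top_voxel_pfc_proportion",
           "decodability", "summarize_subject", "DECODABILITY_THRESHOLD"]

DECODABILITY_THRESHOLD = 3.0
TOP_VOXEL_Z = 2.0


def weight_spread(fit: MVBResults) -> float:
    """Sample SD of the posterior voxel weights: how many voxels carry
    substantial (nondirectional) information about the target."""
    if fit.n_voxels < 2:
        raise ValueError("weight spread needs at least two voxels")
    return float(np.std(fit.weights, ddof=1))


def top_voxel_pfc_proportion(joint_fit: MVBResults, roi_labels: np.ndarray,
                             z_threshold: float = TOP_VOXEL_Z
                             ) -> tuple[float | None, bool]:
    """Fraction of top-weighted voxels (|w - mean| > z * SD) lying in PFC.

    Returns (proportion, defined).  An empty top set (e.g. all weights
    equal) yields (None, False) and is excluded from group fits.
    """
    w = np.asarray(joint_fit.weights, float)
    labels = np.asarray(roi_labels)
    if len(w) != len(labels):
        raise ValueError("weights and ROI labels differ in length")
    sd = w.std(ddof=1)
    if sd == 0:
        return None, False
    top = np.abs(w - w.mean()) > z_threshold * sd
    if not top.any():
        return None, False
    prop = float((labels[top] == "PFC").sum() / top.sum())
    return prop, True


def decodability(real_f: float, shuffled_mean_f: float,
                 threshold: float = DECODABILITY_THRESHOLD
                 ) -> tuple[float, bool]:
    """Real-minus-shuffled log evidence and whether it exceeds the
    strong-evidence threshold (delta <= threshold fails)."""
    if not (np.isfinite(real_f) and np.isfinite(shuffled_mean_f)):
        raise ValueError("free energies must be finite")
    delta = float(real_f - shuffled_mean_f)
    return delta, delta > threshold


@dataclass
class SubjectRecord:
    """One subject's row of dependent measures for group inference."""

    subject_id: str
    age: float
    univariate_mean: dict[str, float] = field(default_factory=dict)
    univariate_sd: dict[str, float] = field(default_factory=dict)
    weight_spread: dict[str, float] = field(default_factory=dict)
    decodability_delta: dict[str, float] = field(default_factory=dict)
    decodable: dict[str, bool] = field(default_factory=dict)
    boost_delta: float | None = None
    boost_category: str | None = None
    top_pfc_proportion: float | None = None
    top_pfc_defined: bool = False
    included: bool = True
    exclusion_reason: str | None = None

    def to_row(self) -> dict:
        row = dict(subject_id=self.subject_id, age=self.age,
                   included=self.included,
                   exclusion_reason=self.exclusion_reason or "",
                   boost_delta=self.boost_delta,
                   boost_category=self.boost_category,
                   top_pfc_proportion=self.top_pfc_proportion,
                   top_pfc_defined=self.top_pfc_defined)
        for roi in ("PVC", "PFC"):
            row[f"univariate_mean_{roi}"] = self.univariate_mean.get(roi)
            row[f"univariate_sd_{roi}"] = self.univariate_sd.get(roi)
            row[f"weight_spread_{roi}"] = self.weight_spread.get(roi)
            row[f"decodability_{roi}"] = self.decodability_delta.get(roi)
            row[f"decodable_{roi}"] = self.decodable.get(roi)
        return row


def summarize_subject(
    subject_id: str,
    age: float,
    roi_fits: dict[str, MVBResults],
    shuffled_means: dict[str, float],
    univariate: dict[str, tuple[float, float]],
    joint_fit: MVBResults | None,
    comparison: MVBComparison | None,
    roi_labels_joint: np.ndarray | None,
    exclusion_policy: str = "any",
) -> SubjectRecord:
    """Assemble one complete SubjectRecord and apply the decodability rule.

    ``exclusion_policy``: "any" excludes a subject who fails decodability in
    at least one ROI; "both" only when both ROIs fail.  Undefined measures
    are flagged, never imputed.
    """
    if exclusion_policy not in ("any", "both"):
        raise ValueError("exclusion_policy must be 'any' or 'both'")
    rec = SubjectRecord(subject_id=subject_id, age=age)
    for roi, fit in roi_fits.items():
        rec.weight_spread[roi] = weight_spread(fit)
        if roi in shuffled_means and np.isfinite(shuffled_means[roi]):
            delta, ok = decodability(fit.free_energy, shuffled_means[roi])
            rec.decodability_delta[roi] = delta
            rec.decodable[roi] = ok
    for roi, (mean, sd) in univariate.items():
        rec.univariate_mean[roi] = mean
        rec.univariate_sd[roi] = sd
    if joint_fit is not None and comparison is not None:
        rec.boost_delta = comparison.delta_log_evidence
        rec.boost_category = comparison.category
        if roi_labels_joint is not None:
            prop, defined = top_voxel_pfc_proportion(joint_fit, roi_labels_joint)
            rec.top_pfc_proportion = prop
            rec.top_pfc_defined = defined
    fails = [roi for roi, ok in rec.decodable.items() if not ok]
    if exclusion_policy == "any":
        excluded = len(fails) >= 1
    else:
        excluded = len(fails) == len(rec.decodable) and len(rec.decodable) > 0
    if excluded:
        rec.included = False
        rec.exclusion_reason = "not decodable in: " + ",".join(sorted(fails))
    return rec
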