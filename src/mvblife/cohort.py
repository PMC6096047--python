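"""Synthetic adult-lifespan fMRI cohorts with known decoding ground truth.

Generates per-subject trial tables and two-ROI voxel time series in which
both the mean univariate contrast amplitude and the number/spread of
uniquely informative voxels vary with age under named scenario functions
("dedifferentiation", "compensation", "null", ...).  The forward model is
the same event-related GLM used for analysis, run generatively, with
AR(1)-correlated noise added per session.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialTable",
    "GroundTruth",
    "NoiseSpec",
    "ScenarioState",
    "CohortSpec",
    "ROIDataset",
    "Subject",
    "SCENARIOS",
    "memory_probability",
    "forgotten_subtype_probabilities",
    "generate_trial_table",
    "generate_subject_data",
    "generate_cohort",
    "make_voxel_lattice",
]

# ---------------------------------------------------------------------------
# Behavioural calibration: remembered / forgotten trial counts by age tertile
# (means over 120 study trials; tertile midpoints in years).
# ---------------------------------------------------------------------------

_TERTILE_MIDPOINTS = np.array([32.0, 55.0, 76.5])
_REMEMBERED_MEAN = np.array([55.0, 44.0, 23.0])
# forgotten subtypes: associative miss, associative intrusion, item miss
_SUBTYPE_MEANS = np.array(
    [
        [31.0, 11.0, 22.0],
        [38.0, 13.0, 25.0],
        [46.0, 10.0, 42.0],
    ]
)

VALENCES = ("positive", "neutral", "negative")
FORGOTTEN_SUBTYPES = ("assoc_miss", "assoc_intrusion", "item_miss")


def memory_probability(age: float) -> float:
    """Probability that a study trial is later remembered, at a given age.

    Piecewise-linear interpolation through the tertile mean remembered
    counts (55/120, 44/120, 23/120 at tertile midpoints 32, 55, 76.5 y),
    constant beyond the extreme midpoints.
    """
    return float(np.interp(age, _TERTILE_MIDPOINTS, _REMEMBERED_MEAN / 120.0))


def forgotten_subtype_probabilities(age: float) -> np.ndarray:
    """Multinomial probabilities over forgotten subtypes at a given age."""
    props = _SUBTYPE_MEANS / _SUBTYPE_MEANS.sum(axis=1, keepdims=True)
    p = np.array([np.interp(age, _TERTILE_MIDPOINTS, props[:, j]) for j in range(3)])
    return p / p.sum()


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

# timing constants (seconds)
LTM_TRIAL_PERIOD = 10.0     # 2 s scene + 7.5 s object + 0.5 s blank
LTM_SCENE_TO_OBJECT = 2.0
LTM_OBJECT_DURATION = 7.5
STM_TRIAL_PERIOD = 22.0
STM_FIXATION = 7.0          # fixation dot before the dot displays
STM_ENCODING_DURATION = 1.0
STM_ENC_TO_MAINT = 2.25     # offset of last display after onset of first
STM_MAINTENANCE_DURATION = 4.0
STM_MAINTENANCE_PERIOD = 8.0

LTM_N_SESSIONS = 2
LTM_TRIALS_PER_SESSION = 60
STM_N_RUNS = 3
STM_TRIALS_PER_RUN = 30
STM_TRIALS_PER_LOAD = 10

LTM_TR = 1.97
LTM_SCANS_PER_SESSION = 320
STM_TR = 2.0
STM_SCANS_PER_SESSION = 340


@dataclass
class TrialTable:
    """Event table for one subject, long format (one row per neural component).

    ``events`` columns: trial_id, session, onset (s, within session),
    duration (s), component, valence, memory, load.  Onsets are strictly
    increasing within a session for the trial-anchor component.
    """

    paradigm: str
    events: pd.DataFrame
    n_sessions: int

    @property
    def n_trials(self) -> int:
        return self.events["trial_id"].nunique()

    def trials(self) -> pd.DataFrame:
        """One row per trial (anchor component)."""
        anchor = "scene" if self.paradigm == "LTM" else "encoding"
        return (
            self.events[self.events["component"] == anchor]
            .sort_values(["session", "onset"])
            .reset_index(drop=True)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, paradigm: str) -> "TrialTable":
        events = pd.read_csv(path, sep="\t")
        return cls(paradigm=paradigm, events=events,
                   n_sessions=int(events["session"].max()))

    def validate(self) -> None:
        for _, grp in self.trials().groupby("session"):
            onsets = grp["onset"].to_numpy()
            if not np.all(np.diff(onsets) > 0):
                raise ValueError("trial onsets must be strictly increasing within session")
        if self.paradigm == "LTM":
            if self.n_trials != LTM_N_SESSIONS * LTM_TRIALS_PER_SESSION:
                raise ValueError("LTM paradigm requires 120 trials")
            if self.n_sessions != LTM_N_SESSIONS:
                raise ValueError("LTM paradigm requires 2 sessions")
        elif self.paradigm == "STM":
            tr = self.trials()
            if self.n_trials != STM_N_RUNS * STM_TRIALS_PER_RUN:
                raise ValueError("STM paradigm requires 90 trials")
            counts = tr.groupby(["session", "load"]).size()
            if not (counts == STM_TRIALS_PER_LOAD).all():
                raise ValueError("STM paradigm requires 10 trials per load per run")


def generate_trial_table(
    paradigm: str,
    age: float,
    spec: "CohortSpec | None" = None,
    seed: int | np.random.Generator = 0,
) -> TrialTable:
    """Draw a trial table for one subject.

    Memory labels (LTM) are Bernoulli draws from the age-dependent
    remembered probability; forgotten trials are split multinomially into
    associative miss / intrusion / item miss with age-interpolated
    proportions.  STM loads are exactly balanced within run.
    """
    rng = np.random.default_rng(seed)
    spec = spec or CohortSpec()
    if paradigm == "LTM":
        p_rem = (spec.memory_prob_fn or memory_probability)(age)
        if not 0.0 <= p_rem <= 1.0:
            raise ValueError(f"memory probability {p_rem} outside [0, 1]")
        p_sub = forgotten_subtype_probabilities(age)
        rows = []
        trial_id = 0
        for session in range(1, LTM_N_SESSIONS + 1):
            valences = np.repeat(VALENCES, LTM_TRIALS_PER_SESSION // 3)
            rng.shuffle(valences)
            for i in range(LTM_TRIALS_PER_SESSION):
                onset = i * LTM_TRIAL_PERIOD
                if rng.random() < p_rem:
                    memory = "remembered"
                else:
                    memory = FORGOTTEN_SUBTYPES[rng.choice(3, p=p_sub)]
                key_offset = LTM_SCENE_TO_OBJECT + rng.uniform(1.0, 7.0)
                common = dict(trial_id=trial_id, session=session,
                              valence=valences[i], memory=memory, load=None)
                rows.append(dict(common, component="scene", onset=onset, duration=0.0))
                rows.append(dict(common, component="object",
                                 onset=onset + LTM_SCENE_TO_OBJECT,
                                 duration=LTM_OBJECT_DURATION))
                rows.append(dict(common, component="keypress",
                                 onset=onset + key_offset, duration=0.0))
                trial_id += 1
        table = TrialTable("LTM", pd.DataFrame(rows), LTM_N_SESSIONS)
    elif paradigm == "STM":
        rows = []
        trial_id = 0
        for run in range(1, STM_N_RUNS + 1):
            loads = np.repeat([1, 2, 3], STM_TRIALS_PER_LOAD)
            rng.shuffle(loads)
            for i in range(STM_TRIALS_PER_RUN):
                onset = i * STM_TRIAL_PERIOD
                enc_onset = onset + STM_FIXATION
                maint_onset = enc_onset + STM_ENC_TO_MAINT
                probe_onset = maint_onset + STM_MAINTENANCE_PERIOD + rng.uniform(0.5, 3.0)
                common = dict(trial_id=trial_id, session=run, valence=None,
                              memory=None, load=int(loads[i]))
                rows.append(dict(common, component="encoding", onset=enc_onset,
                                 duration=STM_ENCODING_DURATION))
                rows.append(dict(common, component="maintenance", onset=maint_onset,
                                 duration=STM_MAINTENANCE_DURATION))
                rows.append(dict(common, component="probe", onset=probe_onset,
                                 duration=0.0))
                trial_id += 1
        table = TrialTable("STM", pd.DataFrame(rows), STM_N_RUNS)
    else:
        raise ValueError(f"unknown paradigm: {paradigm!r}")
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioState:
    """Age-resolved generative parameters for one subject."""

    univariate_amplitude: dict[str, float]   # mean contrast effect, BOLD units
    informative_fraction: dict[str, float]   # fraction of voxels carrying info
    # SD of informative differential betas (scalar, or per-ROI dict)
    weight_scale: float | dict[str, float] = 0.5
    pfc_unique: bool = True                  # PFC info independent of PVC's

    def roi_weight_scale(self, roi: str) -> float:
        if isinstance(self.weight_scale, dict):
            return self.weight_scale[roi]
        return self.weight_scale


def _age_frac(age: float, lo: float = 20.0, hi: float = 88.0) -> float:
    return float(np.clip((age - lo) / (hi - lo), 0.0, 1.0))


def _scenario_dedifferentiation(age: float) -> ScenarioState:
    # more activity, less information: the univariate amplitude rises with
    # age while both the number of informative voxels and their per-voxel
    # differential tuning decline
    a = _age_frac(age)
    return ScenarioState(
        univariate_amplitude={"PVC": 0.3, "PFC": 0.2 + 0.45 * a},
        informative_fraction={"PVC": 0.5 - 0.3 * a, "PFC": 0.5 - 0.3 * a},
        weight_scale=0.5 - 0.2 * a,
    )


def _scenario_compensation(age: float) -> ScenarioState:
    # posterior information constant over life; unique prefrontal
    # information absent in youth and recruited increasingly with age
    a = _age_frac(age)
    return ScenarioState(
        univariate_amplitude={"PVC": 0.3, "PFC": 0.3},
        informative_fraction={"PVC": 0.4, "PFC": 0.3 * a},
        weight_scale={"PVC": 0.4, "PFC": 0.5},
    )


def _scenario_null(age: float) -> ScenarioState:
    return ScenarioState(
        univariate_amplitude={"PVC": 0.3, "PFC": 0.3},
        informative_fraction={"PVC": 0.3, "PFC": 0.3},
        weight_scale=0.4,
    )


def _scenario_zero_signal(age: float) -> ScenarioState:
    return ScenarioState(
        univariate_amplitude={"PVC": 0.0, "PFC": 0.0},
        informative_fraction={"PVC": 0.0, "PFC": 0.0},
        weight_scale=0.0,
    )


def _scenario_strong_signal(age: float) -> ScenarioState:
    return ScenarioState(
        univariate_amplitude={"PVC": 0.5, "PFC": 0.5},
        informative_fraction={"PVC": 0.5, "PFC": 0.5},
        weight_scale=1.0,
    )


SCENARIOS: dict[str, Callable[[float], ScenarioState]] = {
    "dedifferentiation": _scenario_dedifferentiation,
    "compensation": _scenario_compensation,
    "null": _scenario_null,
    "zero_signal": _scenario_zero_signal,
    "strong_signal": _scenario_strong_signal,
}


@dataclass
class NoiseSpec:
    """Voxel-independent plus ROI-shared AR(1) noise.

    ``sigma`` is the voxel-unique noise SD; ``sigma_shared`` the SD of a
    single AR(1) series added to every voxel of an ROI, emulating regional
    physiological fluctuations.  The shared component bounds the SNR of the
    ROI-mean signal, so a mean activation difference is not by itself
    high-grade multivariate information.
    """

    ar1_rho: float = 0.3       # lag-1 autocorrelation of both components
    sigma: float = 1.0         # voxel-unique SD, BOLD units (grand mean 100)
    sigma_shared: float = 1.0  # ROI-shared SD, BOLD units

    def validate(self) -> None:
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.sigma < 0 or self.sigma_shared < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class CohortSpec:
    """Defines a synthetic cohort: who is simulated and under which scenario."""

    n_subjects: int = 48
    age_range: tuple[float, float] = (20.0, 88.0)
    paradigm: str = "LTM"
    scenario: str | Callable[[float], ScenarioState] = "null"
    n_voxels_per_roi: int = 200
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    memory_prob_fn: Callable[[float], float] | None = None
    # amplitudes of trial-locked responses not carrying the target contrast
    base_epoch_amplitude: float = 0.5
    scene_amplitude: float = 0.3
    keypress_amplitude: float = 0.3
    rng_seed: int = 0

    def scenario_fn(self) -> Callable[[float], ScenarioState]:
        if callable(self.scenario):
            return self.scenario
        try:
            return SCENARIOS[self.scenario]
        except KeyError:
            raise ValueError(f"unknown scenario: {self.scenario!r}") from None

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("invalid age range")
        if self.paradigm not in ("LTM", "STM"):
            raise ValueError(f"unknown paradigm: {self.paradigm!r}")
        self.scenario_fn()
        self.noise.validate()


# ---------------------------------------------------------------------------
# Voxel lattice and datasets
# ---------------------------------------------------------------------------

ROI_LABELS = ("PVC", "PFC")
_ROI_BLOCK_ORIGIN_MM = {"PVC": (-20.0, -95.0, -5.0), "PFC": (20.0, 30.0, 15.0)}
VOXEL_SIZE_MM = 3.0


def make_voxel_lattice(n_per_roi: int) -> tuple[np.ndarray, np.ndarray]:
    """3 mm isotropic lattice: two disjoint cubic blocks labelled PVC and PFC.

    Returns (voxel_mm, roi_labels) with voxel_mm of shape (2*n_per_roi, 3).
    """
    coords, labels = [], []
    side = int(np.ceil(n_per_roi ** (1.0 / 3.0)))
    for roi in ROI_LABELS:
        ox, oy, oz = _ROI_BLOCK_ORIGIN_MM[roi]
        grid = [(ox + VOXEL_SIZE_MM * i, oy + VOXEL_SIZE_MM * j, oz + VOXEL_SIZE_MM * k)
                for i in range(side) for j in range(side) for k in range(side)]
        coords.extend(grid[:n_per_roi])
        labels.extend([roi] * n_per_roi)
    return np.asarray(coords, dtype=float), np.asarray(labels)


@dataclass
class ROIDataset:
    """Scans x voxels BOLD matrix with voxel coordinates and ROI labels."""

    data: np.ndarray                 # (n_scans, n_voxels), BOLD units
    voxel_mm: np.ndarray             # (n_voxels, 3)
    roi_labels: np.ndarray           # (n_voxels,), values in {"PVC", "PFC"}
    session_index: np.ndarray        # (n_scans,), 1-based session of each scan
    tr: float                        # seconds

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.isfinite(self.data).all():
            raise ValueError("ROIDataset contains non-finite values")
        if self.data.shape[1] != len(self.roi_labels):
            raise ValueError("voxel dimension mismatch")
        for roi in np.unique(self.roi_labels):
            if (self.roi_labels == roi).sum() < 1:
                raise ValueError(f"ROI {roi} has no voxels")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def roi_indices(self, roi: str) -> np.ndarray:
        return np.flatnonzero(self.roi_labels == roi)

    @property
    def sessions(self) -> np.ndarray:
        return np.unique(self.session_index)


@dataclass
class GroundTruth:
    """Generative per-voxel effects for one subject.

    ``differential`` holds the condition-differential beta of each voxel
    (zero for uninformative voxels); drawn N(0, weight_scale^2) for
    informative ones so information is nondirectional.
    """

    age: float
    differential: np.ndarray                     # (n_voxels,)
    informative_voxel_indices: dict[str, np.ndarray]
    univariate_amplitude: dict[str, float]
    weight_scale: float
    base_epoch_amplitude: float
    scene_amplitude: float
    keypress_amplitude: float
    roi_labels: np.ndarray

    def column_betas(self, labels: Sequence[str]) -> np.ndarray:
        """Generative beta matrix (n_regressors x n_voxels) for design columns.

        Column label conventions follow the design module: task columns
        contain 'epoch' (LTM), 'maint'/'enc'/'probe' (STM), 'scene' or
        'keypress'; confound columns get zero betas except the per-session
        constant, which carries the baseline of 100.
        """
        v = len(self.differential)
        uni = np.array([self.univariate_amplitude[r] for r in self.roi_labels])
        betas = np.zeros((len(labels), v))
        for i, lab in enumerate(labels):
            name = lab.split("/", 1)[1] if "/" in lab else lab
            if name.startswith("epoch_"):
                # epoch_<valence>_<memory>: remembered vs forgotten carries
                # the univariate amplitude and the informative differential
                sign = 0.5 if name.endswith("_remembered") else -0.5
                betas[i] = self.base_epoch_amplitude + sign * (uni + self.differential)
            elif name.startswith("maint_"):
                load = int(name.split("_")[1])
                betas[i] = (self.base_epoch_amplitude
                            + (load - 2) * (uni + self.differential))
            elif name.startswith("enc_") or name.startswith("probe_"):
                betas[i] = self.scene_amplitude
            elif name.startswith("scene_"):
                betas[i] = self.scene_amplitude
            elif name == "keypress":
                betas[i] = self.keypress_amplitude
            elif name == "constant":
                betas[i] = 100.0
            # motion / drift columns: zero
        return betas


def _draw_ground_truth(
    age: float,
    state: ScenarioState,
    spec: CohortSpec,
    roi_labels: np.ndarray,
    rng: np.random.Generator,
) -> GroundTruth:
    v = len(roi_labels)
    differential = np.zeros(v)
    informative: dict[str, np.ndarray] = {}
    for roi in ROI_LABELS:
        idx = np.flatnonzero(roi_labels == roi)
        n_info = int(round(state.informative_fraction[roi] * len(idx)))
        chosen = rng.choice(idx, size=n_info, replace=False) if n_info else np.array([], int)
        informative[roi] = np.sort(chosen)
        differential[informative[roi]] = rng.normal(
            0.0, state.roi_weight_scale(roi), size=n_info)
    return GroundTruth(
        age=age,
        differential=differential,
        informative_voxel_indices=informative,
        univariate_amplitude=dict(state.univariate_amplitude),
        weight_scale=state.weight_scale,
        base_epoch_amplitude=spec.base_epoch_amplitude,
        scene_amplitude=spec.scene_amplitude,
        keypress_amplitude=spec.keypress_amplitude,
        roi_labels=roi_labels,
    )


# ---------------------------------------------------------------------------
# Noise and data synthesis
# ---------------------------------------------------------------------------


def ar1_noise(
    n_scans: int,
    n_voxels: int,
    rho: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sigma`` and lag-1 corr ``rho``."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if sigma == 0.0:
        return np.zeros((n_scans, n_voxels))
    x = np.empty((n_scans, n_voxels))
    x[0] = rng.normal(0.0, sigma, size=n_voxels)
    innov_sd = sigma * np.sqrt(1.0 - rho ** 2)
    eps = rng.normal(0.0, innov_sd, size=(n_scans - 1, n_voxels))
    for t in range(1, n_scans):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x


def generate_subject_data(
    design,
    truth: GroundTruth,
    noise: NoiseSpec,
    seed: int | np.random.Generator = 0,
) -> ROIDataset:
    """Forward-simulate one subject: data = design @ betas + AR(1) noise.

    ``design`` is a DesignMatrix (see mvblife.design); noise is generated
    independently per session.
    """
    rng = np.random.default_rng(seed)
    noise.validate()
    betas = truth.column_betas(design.labels)
    if betas.shape[0] != design.matrix.shape[1]:
        raise ValueError("design / ground-truth dimension mismatch")
    signal = design.matrix @ betas
    data = signal.copy()
    for s in np.unique(design.session_index):
        mask = design.session_index == s
        nt = int(mask.sum())
        data[mask] += ar1_noise(nt, betas.shape[1],
                                noise.ar1_rho, noise.sigma, rng)
        if noise.sigma_shared > 0:
            for roi in np.unique(truth.roi_labels):
                shared = ar1_noise(nt, 1, noise.ar1_rho, noise.sigma_shared, rng)
                data[np.ix_(mask, truth.roi_labels == roi)] += shared
    return ROIDataset(
        data=data,
        voxel_mm=design.voxel_mm if design.voxel_mm is not None else np.zeros((betas.shape[1], 3)),
        roi_labels=truth.roi_labels,
        session_index=design.session_index,
        tr=design.tr,
    )


@dataclass
class Subject:
    subject_id: str
    age: float
    trials: TrialTable
    design: "object"          # DesignMatrix
    data: ROIDataset
    truth: GroundTruth


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Generate a seeded cohort: (age, trial table, design, data, truth) per subject.

    Output is a pure function of the spec (including its rng_seed): ages are
    drawn uniformly over the age range, per-subject streams are spawned from
    one master SeedSequence so any subject is reproducible in isolation.
    """
    from .design import ScanParams, build_design_matrix

    spec.validate()
    master = np.random.SeedSequence(spec.rng_seed)
    age_rng = np.random.default_rng(master.spawn(1)[0])
    ages = np.sort(age_rng.uniform(*spec.age_range, size=spec.n_subjects))
    scen = spec.scenario_fn()
    voxel_mm, roi_labels = make_voxel_lattice(spec.n_voxels_per_roi)

    subjects = []
    child_seeds = master.spawn(spec.n_subjects)
    for i, (age, seed) in enumerate(zip(ages, child_seeds)):
        rng = np.random.default_rng(seed)
        trials = generate_trial_table(spec.paradigm, age, spec, rng)
        state = scen(age)
        truth = _draw_ground_truth(age, state, spec, roi_labels, rng)
        if spec.paradigm == "LTM":
            params = ScanParams(tr=LTM_TR, n_scans_per_session=LTM_SCANS_PER_SESSION)
            params = params.with_motion(rng, n_sessions=LTM_N_SESSIONS)
        else:
            params = ScanParams(tr=STM_TR, n_scans_per_session=STM_SCANS_PER_SESSION)
            params = params.with_motion(rng, n_sessions=STM_N_RUNS)
        design = build_design_matrix(trials, params, voxel_mm=voxel_mm)
        data = generate_subject_data(design, truth, spec.noise, rng)
        subjects.append(Subject(f"sub-{i + 1:03d}", float(age), trials, design,
                                data, truth))
    return subjects


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_cohort(subjects: list[Subject], spec: CohortSpec, out_dir: str | Path) -> None:
    """Write one events TSV + one data array + ground-truth sidecar per subject."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(spec)
    cfg["scenario"] = spec.scenario if isinstance(spec.scenario, str) else "<callable>"
    cfg.pop("memory_prob_fn", None)
    (out / "cohort.json").write_text(json.dumps(cfg, indent=2, default=str))
    for s in subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        s.trials.to_tsv(sdir / "events.tsv")
        np.savez_compressed(
            sdir / "data.npz",
            data=s.data.data, voxel_mm=s.data.voxel_mm,
            roi_labels=s.data.roi_labels, session_index=s.data.session_index,
            tr=s.data.tr,
        )
        sidecar = {
            "age": s.age,
            "univariate_amplitude": s.truth.univariate_amplitude,
            "weight_scale": s.truth.weight_scale,
            "informative_voxel_indices": {
                k: v.tolist() for k, v in s.truth.informative_voxel_indices.items()
            },
        }
        (sdir / "truth.json").write_text(json.dumps(sidecar, indent=2))
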