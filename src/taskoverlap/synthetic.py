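"""Synthetic two-task block-design fMRI with known ground truth.

Generates cohorts of runs that mirror the target acquisition (TR = 1 s,
244 volumes/run, 2.5 mm isotropic voxels, two arithmetic + two rhyming runs
per subject) with controllable activation geometry, cross-condition pattern
correlations, AR(1) temporally and Gaussian spatially correlated noise, and
injectable motion artifacts — so that every downstream analysis stage can be
validated against a known generative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from taskoverlap.hrf import convolve_events

__all__ = [
    "ARITHMETIC_CONDITIONS",
    "RHYMING_CONDITIONS",
    "CONDITION_ORDER",
    "AcquisitionSpec",
    "BlockDesign",
    "BoldRun",
    "ConfigurationError",
    "Event",
    "GroundTruth",
    "SubjectData",
    "Cohort",
    "default_ground_truth",
    "generate_cohort",
    "generate_run",
    "make_block_design",
    "simulate_pattern_set",
]

ARITHMETIC_CONDITIONS = ("Small", "Large", "PlusOne")
RHYMING_CONDITIONS = ("Rhyme", "LetterMatch")
CONDITION_ORDER = ARITHMETIC_CONDITIONS + RHYMING_CONDITIONS

TASK_CONDITIONS = {
    "arithmetic": ARITHMETIC_CONDITIONS,
    "rhyming": RHYMING_CONDITIONS,
}

#: scheduled task time occupied by stimulation blocks (6 blocks x 30 s)
_BLOCK_TOTAL_S = 180.0
#: number of fixation intervals: lead-in + 5 inter-block + lead-out
_N_FIXATIONS = 6 + 1
_JITTER_LOW_S, _JITTER_HIGH_S = 8.6, 9.4


class ConfigurationError(ValueError):
    """Raised when a requested design cannot fit the acquisition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scanner-side description of one run."""

    tr_seconds: float = 1.0
    n_volumes: int = 244
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.5

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_volumes <= 0:
            raise ValueError("n_volumes must be positive")
        if len(self.grid_shape) != 3 or any(int(g) < 4 for g in self.grid_shape):
            raise ValueError("grid_shape must be 3 integers, each >= 4")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        object.__setattr__(self, "grid_shape", tuple(int(g) for g in self.grid_shape))

    @property
    def duration_s(self) -> float:
        """Scheduled run duration in seconds (``n_volumes * TR``)."""
        return self.n_volumes * self.tr_seconds

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass(frozen=True)
class Event:
    """One trial: condition label, onset/duration in run seconds, accuracy."""

    condition: str
    onset_s: float
    duration_s: float
    correct: bool = True


@dataclass
class BlockDesign:
    """Ordered, non-overlapping trial schedule for one run of one task."""

    task: str
    events: list[Event]
    run_label: str = "run-1"

    def __post_init__(self) -> None:
        if self.task not in TASK_CONDITIONS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {sorted(TASK_CONDITIONS)}")
        valid = set(TASK_CONDITIONS[self.task])
        prev_end = -np.inf
        for ev in self.events:
            if ev.condition not in valid:
                raise ValueError(
                    f"condition {ev.condition!r} is not part of task {self.task!r} "
                    f"(valid: {sorted(valid)})"
                )
            if ev.onset_s < prev_end - 1e-9:
                raise ValueError("events must be sorted by onset and non-overlapping")
            prev_end = ev.onset_s + ev.duration_s

    @property
    def conditions(self) -> tuple[str, ...]:
        return TASK_CONDITIONS[self.task]

    @property
    def end_s(self) -> float:
        return max((ev.onset_s + ev.duration_s for ev in self.events), default=0.0)

    def onsets(self, condition: str, correct_only: bool | None = None) -> np.ndarray:
        sel = [
            ev
            for ev in self.events
            if ev.condition == condition
            and (correct_only is None or ev.correct == correct_only)
        ]
        return np.array([ev.onset_s for ev in sel], dtype=float)


@dataclass
class GroundTruth:
    """Generative parameters: where, how strongly and how similarly conditions activate.

    ``condition_amplitudes`` are default response amplitudes applied inside
    every ROI; ``roi_condition_amplitudes`` optionally overrides them per ROI
    (conditions absent from the override are silent in that ROI). Voxel
    patterns are ``pattern_mean + pattern_sd * w`` where the fluctuation
    fields ``w`` have the requested cross-condition correlation matrix.
    """

    roi_masks: dict[str, np.ndarray]
    condition_amplitudes: dict[str, float]
    pattern_correlations: dict[frozenset, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    spatial_fwhm_mm: float = 5.0
    ar1_coefficient: float = 0.3
    pattern_mean: float = 1.0
    pattern_sd: float = 0.5
    roi_condition_amplitudes: dict[str, dict[str, float]] | None = None
    p_correct: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.roi_masks:
            raise ValueError("roi_masks must be non-empty")
        self.roi_masks = {k: np.asarray(v, dtype=bool) for k, v in self.roi_masks.items()}
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.spatial_fwhm_mm < 0:
            raise ValueError("spatial_fwhm_mm must be non-negative")
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must lie in [0, 1]")
        norm: dict[frozenset, float] = {}
        for pair, rho in self.pattern_correlations.items():
            key = frozenset(pair)
            if len(key) != 2:
                raise ValueError(f"pattern correlation key {pair!r} is not a pair")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"pattern correlation for {sorted(key)} must lie in (-1, 1)")
            norm[key] = float(rho)
        self.pattern_correlations = norm

    @property
    def conditions(self) -> tuple[str, ...]:
        """Canonically ordered conditions carrying an amplitude entry."""
        return tuple(c for c in CONDITION_ORDER if c in self.condition_amplitudes)

    def amplitude(self, roi: str, condition: str) -> float:
        if self.roi_condition_amplitudes and roi in self.roi_condition_amplitudes:
            return float(self.roi_condition_amplitudes[roi].get(condition, 0.0))
        return float(self.condition_amplitudes.get(condition, 0.0))

    def correlation_matrix(self, conditions: Sequence[str] | None = None) -> np.ndarray:
        """Target cross-condition correlation matrix (unspecified pairs -> 0)."""
        conds = tuple(conditions) if conditions is not None else self.conditions
        k = len(conds)
        corr = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                rho = self.pattern_correlations.get(frozenset({conds[i], conds[j]}), 0.0)
                corr[i, j] = corr[j, i] = rho
        return corr


@dataclass
class BoldRun:
    """One run: 4D data (T x grid), acquisition/design metadata and nuisances."""

    data: np.ndarray
    spec: AcquisitionSpec
    design: BlockDesign | None
    motion: np.ndarray | None = None
    global_signal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (T x grid)")
        if self.data.shape[0] != self.spec.n_volumes:
            raise ValueError(
                f"data has {self.data.shape[0]} volumes but spec declares {self.spec.n_volumes}"
            )
        if self.data.shape[1:] != self.spec.grid_shape:
            raise ValueError("data grid does not match spec.grid_shape")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.spec.n_volumes, 6):
                raise ValueError("motion must be T x 6")
        if self.global_signal is not None:
            self.global_signal = np.asarray(self.global_signal, dtype=float)
            if self.global_signal.shape != (self.spec.n_volumes,):
                raise ValueError("global_signal must have length T")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    def flat_data(self) -> np.ndarray:
        """Time x voxel view (C-order voxel flattening)."""
        return self.data.reshape(self.n_volumes, -1)


@dataclass
class SubjectData:
    """Four runs (2 arithmetic, 2 rhyming) plus subject-specific patterns."""

    subject_id: str
    runs: list[BoldRun]
    patterns: dict[str, dict[str, np.ndarray]]

    def runs_for(self, task: str) -> list[BoldRun]:
        return [r for r in self.runs if r.design is not None and r.design.task == task]


@dataclass
class Cohort:
    subjects: list[SubjectData]
    truth: GroundTruth
    spec: AcquisitionSpec
    seed: int

    def __len__(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# schedule generation
# ---------------------------------------------------------------------------


def _iti_sequence(rng: np.random.Generator, n: int, low: float, mid: float, high: float,
                  target_mean: float) -> np.ndarray:
    """Random ITI sequence drawn from {low, mid, high} summing to n * target_mean.

    Requires ``mid == target_mean`` and ``low + high == 2 * mid``; balance is
    kept by drawing equal counts of the low and high values.
    """
    n_extreme = int(rng.integers(0, n // 2 + 1))
    itis = [low] * n_extreme + [high] * n_extreme + [mid] * (n - 2 * n_extreme)
    return rng.permutation(np.array(itis))


_TASK_BLOCKS = {
    # task: (block conditions, trials/block, trial duration, ITI choices)
    "arithmetic": (("Small", "Small", "Large", "Large", "PlusOne", "PlusOne"),
                   6, 3.5, (1.0, 1.5, 2.0)),
    "rhyming": (("Rhyme", "Rhyme", "Rhyme", "LetterMatch", "LetterMatch", "LetterMatch"),
                5, 4.0, (1.5, 2.0, 2.5)),
}


def make_block_design(
    task: str,
    spec: AcquisitionSpec,
    seed: int | np.random.SeedSequence,
    p_correct: float = 1.0,
    run_label: str = "run-1",
) -> BlockDesign:
    """Build one run's block schedule.

    Arithmetic runs contain six 30 s blocks (two per condition, order permuted
    by ``seed``) of six 3.5 s trials separated by ITIs from {1, 1.5, 2} s;
    rhyming runs contain six 30 s blocks (three per condition) of five 4 s
    trials with ITIs from {1.5, 2, 2.5} s. Each block's ITIs sum so the block
    lasts exactly 30 s. Fixation intervals (lead-in, five inter-block, lead-
    out) are drawn uniformly from [8.6, 9.4] s and rescaled so the schedule
    fills the run exactly (244 s at the default acquisition).
    """
    if task not in _TASK_BLOCKS:
        raise ValueError(f"unknown task {task!r}")
    block_conditions, n_trials, trial_dur, iti_choices = _TASK_BLOCKS[task]
    fixation_total = spec.duration_s - _BLOCK_TOTAL_S
    if fixation_total < 0:
        raise ConfigurationError(
            f"run duration {spec.duration_s} s cannot fit {_BLOCK_TOTAL_S} s of task blocks"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(block_conditions))
    fixations = rng.uniform(_JITTER_LOW_S, _JITTER_HIGH_S, size=_N_FIXATIONS)
    fixations *= fixation_total / fixations.sum()

    iti_mean = (30.0 - n_trials * trial_dur) / n_trials
    events: list[Event] = []
    t = fixations[0]
    for b, block_idx in enumerate(order):
        condition = block_conditions[block_idx]
        itis = _iti_sequence(rng, n_trials, iti_choices[0], iti_choices[1],
                             iti_choices[2], iti_mean)
        for trial in range(n_trials):
            correct = bool(rng.random() < p_correct)
            events.append(Event(condition, round(t, 6), trial_dur, correct))
            t += trial_dur + itis[trial]
        if b < len(order) - 1:
            t += fixations[b + 1]
    t += fixations[-1]
    if t > spec.duration_s + 1e-6:
        raise ConfigurationError(
            f"scheduled duration {t:.3f} s exceeds run duration {spec.duration_s} s"
        )
    return BlockDesign(task=task, events=events, run_label=run_label)


# ---------------------------------------------------------------------------
# pattern simulation
# ---------------------------------------------------------------------------


def _check_psd(corr: np.ndarray, conditions: Sequence[str], tol: float = 1e-10) -> None:
    if np.min(np.linalg.eigvalsh(corr)) >= -tol:
        return
    # find a smallest failing principal submatrix to name the offending pair
    k = corr.shape[0]
    from itertools import combinations

    for size in range(2, k + 1):
        for idx in combinations(range(k), size):
            sub = corr[np.ix_(idx, idx)]
            if np.min(np.linalg.eigvalsh(sub)) < -tol:
                names = [conditions[i] for i in idx]
                off = np.abs(sub - np.eye(size))
                i, j = np.unravel_index(np.argmax(off), off.shape)
                raise ValueError(
                    "requested pattern correlations are not positive semi-definite; "
                    f"conditions {names} are inconsistent (largest off-diagonal: "
                    f"{names[i]}-{names[j]} = {sub[i, j]:+.3f})"
                )
    raise ValueError("requested pattern correlations are not positive semi-definite")


def _matrix_sqrt(corr: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def simulate_pattern_set(
    truth: GroundTruth,
    roi: str,
    seed: int | np.random.SeedSequence,
) -> dict[str, np.ndarray]:
    """Voxel patterns over one ROI with the requested correlation structure.

    Returns one vector per condition (length = ROI voxel count). The
    fluctuation parts are ``A @ Z`` with ``A`` the symmetric square root of
    the target correlation matrix and ``Z`` iid standard normal, so the
    expected pairwise Pearson correlation across voxels equals the request.
    """
    if roi not in truth.roi_masks:
        raise KeyError(f"unknown ROI {roi!r}; available: {sorted(truth.roi_masks)}")
    n_voxels = int(truth.roi_masks[roi].sum())
    if n_voxels == 0:
        raise ValueError(f"ROI {roi!r} mask is empty")
    conditions = truth.conditions
    corr = truth.correlation_matrix(conditions)
    _check_psd(corr, conditions)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(conditions), n_voxels))
    w = _matrix_sqrt(corr) @ z
    return {
        cond: truth.pattern_mean + truth.pattern_sd * w[i]
        for i, cond in enumerate(conditions)
    }


# ---------------------------------------------------------------------------
# BOLD generation
# ---------------------------------------------------------------------------


def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm


def _smoothing_variance_factor(sigma_vox: float) -> float:
    """Interior variance reduction of isotropic 3D Gaussian smoothing."""
    if sigma_vox <= 0:
        return 1.0
    half = max(int(np.ceil(8 * sigma_vox)), 4)
    delta = np.zeros(2 * half + 1)
    delta[half] = 1.0
    kernel = gaussian_filter1d(delta, sigma_vox)
    return float((kernel**2).sum() ** 3)


def _simulate_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    noise_sd: float,
    ar1: float,
    fwhm_mm: float,
    voxel_size_mm: float,
) -> np.ndarray:
    """Spatially smoothed AR(1) Gaussian noise with marginal sd ~ noise_sd."""
    t_len = shape[0]
    noise = rng.standard_normal(shape)
    sigma_vox = _fwhm_to_sigma_vox(fwhm_mm, voxel_size_mm)
    if sigma_vox > 0:
        noise = gaussian_filter(noise, sigma=(0, sigma_vox, sigma_vox, sigma_vox),
                                mode="constant")
        noise /= np.sqrt(_smoothing_variance_factor(sigma_vox))
    if ar1 > 0:
        innov_scale = np.sqrt(1.0 - ar1**2)
        for t in range(1, t_len):
            noise[t] = ar1 * noise[t - 1] + innov_scale * noise[t]
    return noise_sd * noise


def generate_run(
    design: BlockDesign,
    truth: GroundTruth,
    spec: AcquisitionSpec,
    seed: int | np.random.SeedSequence,
    patterns: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    motion_spikes: Sequence[tuple[int, float]] | None = None,
    baseline: float = 100.0,
) -> BoldRun:
    """Forward-simulate one BOLD run.

    Signal: each condition's boxcar convolved with the canonical HRF, scaled
    by the ROI amplitude and multiplied into the ROI voxel patterns. Noise:
    Gaussian with AR(1) temporal and Gaussian spatial correlation. Motion is
    a slow random walk; ``motion_spikes`` = [(volume, jump_mm), ...] inject
    step displacements that downstream outlier flagging should catch.
    """
    grid = spec.grid_shape
    t_len = spec.n_volumes
    if design.end_s > spec.duration_s + 1e-6:
        raise ConfigurationError("design events extend beyond the run duration")
    for roi, mask in truth.roi_masks.items():
        if mask.shape != grid:
            raise ConfigurationError(
                f"ROI {roi!r} mask shape {mask.shape} does not match grid {grid}"
            )

    seq = np.random.SeedSequence(seed) if isinstance(seed, (int, np.integer)) else seed
    pattern_seq, noise_seq, motion_seq = seq.spawn(3)
    if patterns is None:
        pattern_seeds = pattern_seq.spawn(len(truth.roi_masks))
        patterns = {
            roi: simulate_pattern_set(truth, roi, s)
            for roi, s in zip(truth.roi_masks, pattern_seeds)
        }

    # condition regressors (all trials, correct or not, evoke a response)
    regressors: dict[str, np.ndarray] = {}
    for cond in design.conditions:
        onsets = np.array([ev.onset_s for ev in design.events if ev.condition == cond])
        if onsets.size:
            durations = np.array(
                [ev.duration_s for ev in design.events if ev.condition == cond]
            )
            regressors[cond] = convolve_events(
                onsets, durations, t_len, spec.tr_seconds
            )

    data = np.full((t_len,) + grid, baseline, dtype=float)
    flat = data.reshape(t_len, -1)
    for roi, mask in truth.roi_masks.items():
        voxel_idx = np.flatnonzero(mask.ravel())
        for cond, reg in regressors.items():
            amp = truth.amplitude(roi, cond)
            if amp == 0.0:
                continue
            pattern = np.asarray(patterns[roi][cond], dtype=float)
            if pattern.shape != voxel_idx.shape:
                raise ConfigurationError(
                    f"pattern for ROI {roi!r}/{cond} has {pattern.size} voxels, "
                    f"mask has {voxel_idx.size}"
                )
            flat[:, voxel_idx] += np.outer(reg, amp * pattern)

    if truth.noise_sd > 0:
        noise_rng = np.random.default_rng(noise_seq)
        data += _simulate_noise(
            noise_rng,
            (t_len,) + grid,
            truth.noise_sd,
            truth.ar1_coefficient,
            truth.spatial_fwhm_mm,
            spec.voxel_size_mm,
        )

    motion_rng = np.random.default_rng(motion_seq)
    motion = np.cumsum(
        motion_rng.normal(0.0, [0.01] * 3 + [1e-4] * 3, size=(t_len, 6)), axis=0
    )
    for volume, jump_mm in motion_spikes or ():
        if not 0 <= volume < t_len:
            raise ConfigurationError(f"spike volume {volume} outside run of {t_len}")
        motion[volume:, 0] += jump_mm

    global_signal = data.mean(axis=(1, 2, 3))
    return BoldRun(
        data=data, spec=spec, design=design, motion=motion, global_signal=global_signal
    )


def generate_cohort(
    n_subjects: int,
    truth: GroundTruth,
    spec: AcquisitionSpec,
    seed: int,
) -> Cohort:
    """Simulate ``n_subjects`` subjects, each with 2 arithmetic + 2 rhyming runs.

    Per-subject seeds are spawned deterministically from the master seed and
    each subject's voxel patterns are drawn independently.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.SeedSequence(seed)
    subjects: list[SubjectData] = []
    for s, subject_seq in enumerate(master.spawn(n_subjects)):
        pattern_seq, *run_seqs = subject_seq.spawn(5)
        pattern_seeds = pattern_seq.spawn(len(truth.roi_masks))
        patterns = {
            roi: simulate_pattern_set(truth, roi, sq)
            for roi, sq in zip(truth.roi_masks, pattern_seeds)
        }
        runs: list[BoldRun] = []
        for i, (task, run_idx) in enumerate(
            [("arithmetic", 1), ("arithmetic", 2), ("rhyming", 1), ("rhyming", 2)]
        ):
            design_seq, bold_seq = run_seqs[i].spawn(2)
            design = make_block_design(
                task, spec, design_seq, p_correct=truth.p_correct,
                run_label=f"run-{run_idx}",
            )
            runs.append(generate_run(design, truth, spec, bold_seq, patterns=patterns))
        subjects.append(SubjectData(f"sub-{s + 1:02d}", runs, patterns))
    return Cohort(subjects=subjects, truth=truth, spec=spec, seed=seed)


# ---------------------------------------------------------------------------
# default demo geometry
# ---------------------------------------------------------------------------


def _box_mask(grid: tuple[int, int, int], center: tuple[int, int, int],
              half: int) -> np.ndarray:
    mask = np.zeros(grid, dtype=bool)
    sl = tuple(
        slice(max(c - half, 0), min(c + half + 1, g)) for c, g in zip(center, grid)
    )
    mask[sl] = True
    return mask


def default_ground_truth(
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> GroundTruth:
    """Demo truth: bilateral arithmetic blobs, a left posterior rhyming blob,
    and a left-frontal region activated by both tasks (the planted overlap).

    Pattern correlations follow the direction reported for the real cohorts:
    Large-Rhyme similarity exceeds Small-Rhyme similarity.
    """
    gx, gy, gz = grid_shape
    qx, qy, qz = gx // 4, gy // 4, gz // 4
    # blob half-width: as large as possible while keeping the four ROIs
    # disjoint (centers are one grid-quarter apart along some axis)
    half = min(max(min(grid_shape) // 10, 2), (min(qx, qy, qz) - 1) // 2)
    if half < 1:
        raise ValueError("grid too small for the default ROI geometry (need >= 12)")
    masks = {
        "overlap": _box_mask(grid_shape, (qx, 3 * qy, 2 * qz), half),
        "arith_left": _box_mask(grid_shape, (qx, qy, 2 * qz), half),
        "arith_right": _box_mask(grid_shape, (3 * qx, qy, 2 * qz), half),
        "rhyme_post": _box_mask(grid_shape, (qx, 2 * qy, qz), half),
    }
    arith_amps = {"Small": 2.0, "Large": 2.0, "PlusOne": 0.5}
    rhyme_amps = {"Rhyme": 2.0, "LetterMatch": 0.5}
    return GroundTruth(
        roi_masks=masks,
        condition_amplitudes={**arith_amps, **rhyme_amps},
        roi_condition_amplitudes={
            "arith_left": arith_amps,
            "arith_right": arith_amps,
            "rhyme_post": rhyme_amps,
            "overlap": {**arith_amps, **rhyme_amps},
        },
        pattern_correlations={
            frozenset({"Small", "Large"}): 0.6,
            frozenset({"Small", "Rhyme"}): 0.2,
            frozenset({"Large", "Rhyme"}): 0.5,
        },
        noise_sd=noise_sd,
        spatial_fwhm_mm=5.0,
        ar1_coefficient=0.3,
        pattern_mean=1.0,
        pattern_sd=0.5,
        seed=seed,
    )
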