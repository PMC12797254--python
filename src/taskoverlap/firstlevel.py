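"""Subject-level machinery: outlier flagging, design matrices, OLS, contrasts.

Conventions (recorded in output metadata by the pipeline):

* framewise displacement is the Power-style sum of absolute parameter
  differentials, with rotations converted to mm on a 50 mm sphere;
* drift handling is an intercept plus a linear trend per run;
* the fixation baseline is the implicit model baseline, so condition-vs-
  fixation effects are condition betas tested against 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from taskoverlap.hrf import convolve_events
from taskoverlap.synthetic import AcquisitionSpec, BlockDesign, BoldRun

__all__ = [
    "OutlierReport",
    "DesignMatrix",
    "GlmFit",
    "ContrastMap",
    "flag_outlier_volumes",
    "build_design_matrix",
    "concatenate_designs",
    "fit_glm",
    "fit_glm_multirun",
    "compute_contrast",
    "contrast_weights",
    "arithmetic_contrast",
    "rhyming_contrast",
    "condition_vs_fixation",
    "smooth_volume",
]

FD_THRESHOLD_MM = 1.5
GLOBAL_Z_THRESHOLD = 4.0
RUN_EXCLUSION_FRACTION = 0.20
ROTATION_RADIUS_MM = 50.0


# ---------------------------------------------------------------------------
# outlier detection
# ---------------------------------------------------------------------------


@dataclass
class OutlierReport:
    """Volumes flagged for excessive motion or global-signal deviation."""

    flagged_volumes: tuple[int, ...]
    reasons: dict[int, str]
    run_excluded: bool
    fraction_flagged: float
    fd_mm: np.ndarray | None = None
    global_z: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "flagged_volumes": list(self.flagged_volumes),
            "reasons": {str(k): v for k, v in self.reasons.items()},
            "run_excluded": self.run_excluded,
            "fraction_flagged": self.fraction_flagged,
            "fd_definition": "sum of |diff| of 6 parameters, rotations x 50 mm sphere",
        }


def framewise_displacement(
    motion: np.ndarray, rotation_radius_mm: float = ROTATION_RADIUS_MM
) -> np.ndarray:
    """Power-style FD: sum of absolute volume-to-volume parameter changes.

    ``motion`` is T x 6 (3 translations in mm, 3 rotations in radians); the
    rotations are converted to arc length on a sphere of the given radius.
    The first volume's FD is 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a T x 6 table")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion parameters contain non-finite values")
    diffs = np.abs(np.diff(motion, axis=0))
    fd = diffs[:, :3].sum(axis=1) + rotation_radius_mm * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def flag_outlier_volumes(
    motion: np.ndarray,
    global_signal: np.ndarray,
    fd_threshold_mm: float = FD_THRESHOLD_MM,
    global_z_threshold: float = GLOBAL_Z_THRESHOLD,
    exclusion_fraction: float = RUN_EXCLUSION_FRACTION,
    rotation_radius_mm: float = ROTATION_RADIUS_MM,
) -> OutlierReport:
    """ART-style volume flagging.

    A volume is flagged when its framewise displacement exceeds 1.5 mm or
    its z-normalized global signal deviates by more than 4 SD. The run is
    marked for exclusion when at least 20% of volumes are flagged.
    """
    global_signal = np.asarray(global_signal, dtype=float)
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    if global_signal.shape != (motion.shape[0],):
        raise ValueError("global_signal length must match motion rows")
    if not np.all(np.isfinite(global_signal)):
        raise ValueError("global signal contains non-finite values")

    fd = framewise_displacement(motion, rotation_radius_mm)
    sd = global_signal.std(ddof=1)
    z = np.zeros_like(global_signal) if sd == 0 else (global_signal - global_signal.mean()) / sd

    reasons: dict[int, str] = {}
    for idx in np.flatnonzero(fd > fd_threshold_mm):
        reasons[int(idx)] = "displacement"
    for idx in np.flatnonzero(np.abs(z) > global_z_threshold):
        reasons.setdefault(int(idx), "signal")

    flagged = tuple(sorted(reasons))
    fraction = len(flagged) / motion.shape[0]
    return OutlierReport(
        flagged_volumes=flagged,
        reasons=reasons,
        run_excluded=fraction >= exclusion_fraction,
        fraction_flagged=fraction,
        fd_mm=fd,
        global_z=z,
    )


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """T x P design with labelled columns.

    ``omitted_conditions`` records task conditions with no usable events in
    the run (their columns are dropped rather than left all-zero).
    """

    matrix: np.ndarray
    column_labels: list[str]
    hrf_model: str = "double-gamma"
    omitted_conditions: list[str] = field(default_factory=list)
    condition_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2D")
        if self.matrix.shape[1] != len(self.column_labels):
            raise ValueError("column_labels length must match matrix columns")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def column_index(self, label: str) -> int:
        try:
            return self.column_labels.index(label)
        except ValueError:
            raise KeyError(
                f"no column {label!r}; available: {self.column_labels}"
            ) from None


def build_design_matrix(
    design: BlockDesign,
    spec: AcquisitionSpec,
    motion: np.ndarray | None = None,
    outliers: OutlierReport | None = None,
    include_drift: bool = True,
) -> DesignMatrix:
    """First-level design: HRF-convolved condition regressors plus nuisances.

    Columns, in order: one regressor per condition with at least one correct
    event, one incorrect-trials regressor when any event is incorrect, six
    motion parameters (demeaned), one indicator per flagged volume, a linear
    drift and an intercept. All-zero nuisance columns (e.g. constant motion)
    are dropped.
    """
    t_len = spec.n_volumes
    if design.end_s > spec.duration_s + 1e-6:
        raise ValueError(
            f"events end at {design.end_s:.2f} s, beyond the run duration "
            f"{spec.duration_s:.2f} s"
        )

    columns: list[np.ndarray] = []
    labels: list[str] = []
    condition_labels: list[str] = []
    omitted: list[str] = []

    for cond in design.conditions:
        events = [ev for ev in design.events if ev.condition == cond and ev.correct]
        if not events:
            omitted.append(cond)
            continue
        reg = convolve_events(
            np.array([ev.onset_s for ev in events]),
            np.array([ev.duration_s for ev in events]),
            t_len,
            spec.tr_seconds,
        )
        columns.append(reg)
        labels.append(cond)
        condition_labels.append(cond)

    incorrect = [ev for ev in design.events if not ev.correct]
    if incorrect:
        columns.append(
            convolve_events(
                np.array([ev.onset_s for ev in incorrect]),
                np.array([ev.duration_s for ev in incorrect]),
                t_len,
                spec.tr_seconds,
            )
        )
        labels.append("incorrect")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (t_len, 6):
            raise ValueError("motion must be T x 6")
        demeaned = motion - motion.mean(axis=0)
        for j in range(6):
            if np.any(demeaned[:, j] != 0):
                columns.append(demeaned[:, j])
                labels.append(f"motion_{j}")

    if outliers is not None:
        for idx in outliers.flagged_volumes:
            spike = np.zeros(t_len)
            spike[idx] = 1.0
            columns.append(spike)
            labels.append(f"spike_{idx}")

    if include_drift:
        columns.append(np.linspace(-0.5, 0.5, t_len))
        labels.append("drift")
    columns.append(np.ones(t_len))
    labels.append("intercept")

    return DesignMatrix(
        matrix=np.column_stack(columns),
        column_labels=labels,
        omitted_conditions=omitted,
        condition_labels=condition_labels,
    )


def concatenate_designs(
    designs: Sequence[DesignMatrix],
    pool_conditions: bool = True,
) -> DesignMatrix:
    """Stack per-run designs into one multi-run design.

    Condition columns are shared across runs when ``pool_conditions`` (one
    beta per condition); nuisance columns (motion, spikes, drift, intercept)
    are always run-specific, giving run-wise intercepts and trends.
    """
    if not designs:
        raise ValueError("need at least one design")
    t_total = sum(dm.n_volumes for dm in designs)

    if pool_conditions:
        cond_labels: list[str] = []
        for dm in designs:
            for lbl in dm.condition_labels:
                if lbl not in cond_labels:
                    cond_labels.append(lbl)
    else:
        cond_labels = [
            f"{lbl}|run{i + 1}"
            for i, dm in enumerate(designs)
            for lbl in dm.condition_labels
        ]

    columns: list[np.ndarray] = []
    labels: list[str] = []
    for lbl in cond_labels:
        col = np.zeros(t_total)
        offset = 0
        for i, dm in enumerate(designs):
            src = lbl if pool_conditions else None
            if pool_conditions:
                if lbl in dm.condition_labels:
                    col[offset : offset + dm.n_volumes] = dm.matrix[
                        :, dm.column_index(lbl)
                    ]
            else:
                base, _, run = lbl.partition("|run")
                if int(run) == i + 1 and base in dm.condition_labels:
                    col[offset : offset + dm.n_volumes] = dm.matrix[
                        :, dm.column_index(base)
                    ]
            offset += dm.n_volumes
        columns.append(col)
        labels.append(lbl)

    offset = 0
    for i, dm in enumerate(designs):
        for j, lbl in enumerate(dm.column_labels):
            if lbl in dm.condition_labels:
                continue
            col = np.zeros(t_total)
            col[offset : offset + dm.n_volumes] = dm.matrix[:, j]
            columns.append(col)
            labels.append(f"{lbl}|run{i + 1}")
        offset += dm.n_volumes

    omitted = sorted({c for dm in designs for c in dm.omitted_conditions})
    return DesignMatrix(
        matrix=np.column_stack(columns),
        column_labels=labels,
        omitted_conditions=[c for c in omitted if c not in cond_labels],
        condition_labels=cond_labels,
    )


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------


@dataclass
class GlmFit:
    """Voxelwise OLS fit: betas (P x grid), residuals, sigma^2 and the design."""

    betas: np.ndarray
    residuals: np.ndarray
    sigma2: np.ndarray
    dof: int
    design: DesignMatrix
    grid_shape: tuple[int, ...]
    xtx_inv: np.ndarray

    def beta_map(self, label: str) -> np.ndarray:
        """Beta image for one labelled regressor (condition vs baseline)."""
        return self.betas[self.design.column_index(label)]

    def flat_betas(self) -> np.ndarray:
        return self.betas.reshape(self.betas.shape[0], -1)

    def flat_residuals(self) -> np.ndarray:
        return self.residuals.reshape(self.residuals.shape[0], -1)


def _collinear_columns(x: np.ndarray, labels: Sequence[str]) -> list[str]:
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [labels[j] for j in np.flatnonzero(diag <= tol)]


def fit_glm(data: BoldRun | np.ndarray, dm: DesignMatrix) -> GlmFit:
    """Ordinary least squares at every voxel.

    ``data`` is a :class:`BoldRun` or a T x grid (or T x voxel) array.
    Raises if the design is rank-deficient, naming the collinear columns.
    """
    if isinstance(data, BoldRun):
        y = data.data
    else:
        y = np.asarray(data, dtype=float)
    if y.shape[0] != dm.n_volumes:
        raise ValueError(
            f"data has {y.shape[0]} volumes, design expects {dm.n_volumes}"
        )
    grid_shape = y.shape[1:]
    y_flat = y.reshape(y.shape[0], -1)

    x = dm.matrix
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        bad = _collinear_columns(x, dm.column_labels)
        raise np.linalg.LinAlgError(
            f"design matrix is rank-deficient (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {bad}"
        )

    xtx_inv = np.linalg.inv(x.T @ x)
    betas = xtx_inv @ (x.T @ y_flat)
    residuals = y_flat - x @ betas
    dof = x.shape[0] - x.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (residuals**2).sum(axis=0) / dof

    return GlmFit(
        betas=betas.reshape((x.shape[1],) + grid_shape),
        residuals=residuals.reshape((x.shape[0],) + grid_shape),
        sigma2=sigma2.reshape(grid_shape),
        dof=dof,
        design=dm,
        grid_shape=grid_shape,
        xtx_inv=xtx_inv,
    )


def fit_glm_multirun(
    runs: Sequence[BoldRun | np.ndarray],
    designs: Sequence[DesignMatrix],
    pool_conditions: bool = True,
) -> GlmFit:
    """Fit several runs in one model (concatenated, run-wise nuisances)."""
    if len(runs) != len(designs):
        raise ValueError("runs and designs must align")
    dm = concatenate_designs(designs, pool_conditions=pool_conditions)
    stacked = np.concatenate(
        [r.flat_data() if isinstance(r, BoldRun) else np.asarray(r, dtype=float).reshape(len(r), -1) for r in runs],
        axis=0,
    )
    grid_shape = (
        runs[0].data.shape[1:] if isinstance(runs[0], BoldRun) else np.asarray(runs[0]).shape[1:]
    )
    fit = fit_glm(stacked.reshape((stacked.shape[0],) + grid_shape), dm)
    return fit


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------


@dataclass
class ContrastMap:
    """Effect and t images for one contrast of a fitted GLM."""

    weights: np.ndarray
    effect: np.ndarray
    t: np.ndarray
    dof: int
    label: str = ""


def contrast_weights(dm: DesignMatrix, weights: dict[str, float]) -> np.ndarray:
    """Dense weight vector from a {column label: weight} mapping.

    A weight on a column that was omitted from the design (condition with no
    events) raises, rather than silently testing nothing.
    """
    c = np.zeros(dm.n_regressors)
    for label, w in weights.items():
        if label in dm.omitted_conditions:
            raise KeyError(
                f"contrast weights condition {label!r}, which was omitted from "
                "the design (no events in this run)"
            )
        c[dm.column_index(label)] = w
    return c


def compute_contrast(
    fit: GlmFit, weights: np.ndarray | dict[str, float], label: str = ""
) -> ContrastMap:
    """Contrast effect c'beta and its t statistic at every voxel."""
    if isinstance(weights, dict):
        c = contrast_weights(fit.design, weights)
    else:
        c = np.asarray(weights, dtype=float)
    if c.shape != (fit.design.n_regressors,):
        raise ValueError(
            f"weights must have length {fit.design.n_regressors}, got {c.shape}"
        )
    if not np.any(c):
        raise ValueError("contrast weights are all zero")

    effect = np.tensordot(c, fit.betas, axes=1)
    var_scale = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(fit.sigma2 * var_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    return ContrastMap(weights=c, effect=effect, t=t, dof=fit.dof, label=label)


def arithmetic_contrast(fit: GlmFit) -> ContrastMap:
    """[Small + Large > PlusOne]: mean of Small and Large against the control."""
    return compute_contrast(
        fit, {"Small": 0.5, "Large": 0.5, "PlusOne": -1.0}, label="Small+Large>PlusOne"
    )


def rhyming_contrast(fit: GlmFit) -> ContrastMap:
    """[Rhyme > LetterMatch]."""
    return compute_contrast(
        fit, {"Rhyme": 1.0, "LetterMatch": -1.0}, label="Rhyme>LetterMatch"
    )


def condition_vs_fixation(fit: GlmFit, condition: str) -> ContrastMap:
    """Condition against the implicit fixation baseline (beta vs 0)."""
    return compute_contrast(fit, {condition: 1.0}, label=f"{condition}>fixation")


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def smooth_volume(
    vol: np.ndarray, fwhm_mm: float, voxel_size_mm: float, mode: str = "constant"
) -> np.ndarray:
    """Separable Gaussian smoothing; ``fwhm_mm = 0`` is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    vol = np.asarray(vol, dtype=float)
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    return gaussian_filter(vol, sigma_vox, mode=mode)
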