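"""ROI pattern similarity: Pearson/Fisher, Steiger's Z, group inference.

Per participant and ROI, the distributed activation patterns for the Small,
Large and Rhyme conditions (each vs the implicit fixation baseline, from
unsmoothed fits) are compared pairwise with Pearson correlations; the two
dependent rhyme-arithmetic similarities are contrasted with Steiger's
pooled-estimate Z, and the per-participant Z values are tested against zero
at the group level with a Dunn-Šidák-corrected alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from taskoverlap.firstlevel import GlmFit

__all__ = [
    "RSA_CONDITIONS",
    "RoiPatternSet",
    "SimilarityRecord",
    "GroupInference",
    "extract_roi_patterns",
    "pairwise_similarity",
    "fisher_z",
    "steiger_z",
    "group_steiger_test",
    "dunn_sidak",
]

RSA_CONDITIONS = ("Small", "Large", "Rhyme")
MIN_ROI_VOXELS = 10


@dataclass
class RoiPatternSet:
    """Condition x voxel pattern matrix over one ROI (fixed voxel order)."""

    roi_id: str
    conditions: tuple[str, ...]
    patterns: np.ndarray
    n_voxels: int
    per_run_patterns: np.ndarray | None = None  # run x condition x voxel

    def pattern(self, condition: str) -> np.ndarray:
        return self.patterns[self.conditions.index(condition)]


def extract_roi_patterns(
    fits: GlmFit | Iterable[GlmFit] | Mapping[str, GlmFit],
    mask: np.ndarray,
    roi_id: str = "roi",
    conditions: Sequence[str] = RSA_CONDITIONS,
    min_voxels: int = MIN_ROI_VOXELS,
) -> RoiPatternSet:
    """Condition-vs-fixation effect vectors over the mask voxels.

    ``fits`` may be a single fit or several (e.g. one per task); each
    condition's beta is taken from the first fit whose design contains it.
    Voxel order is the lexicographic (C-order) index of the mask — identical
    for every condition, and invariant to how the mask was constructed.
    """
    if isinstance(fits, GlmFit):
        fit_list = [fits]
    elif isinstance(fits, Mapping):
        fit_list = list(fits.values())
    else:
        fit_list = list(fits)
    if not fit_list:
        raise ValueError("need at least one GLM fit")

    mask = np.asarray(mask, dtype=bool)
    grid = fit_list[0].grid_shape
    if mask.shape != grid:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid}")
    voxel_idx = np.flatnonzero(mask.ravel())
    if voxel_idx.size == 0:
        raise ValueError("ROI mask is empty")
    if voxel_idx.size < min_voxels:
        raise ValueError(
            f"ROI {roi_id!r} has {voxel_idx.size} voxels, below the floor of {min_voxels}"
        )

    rows = []
    for cond in conditions:
        for fit in fit_list:
            if cond in fit.design.column_labels:
                beta = fit.flat_betas()[fit.design.column_index(cond)]
                break
        else:
            raise KeyError(f"condition {cond!r} not found in any supplied fit")
        vec = beta[voxel_idx]
        if not np.all(np.isfinite(vec)):
            bad = voxel_idx[~np.isfinite(vec)][:10]
            raise ValueError(
                f"non-finite effects for condition {cond!r} at flat voxel indices {bad.tolist()}"
            )
        rows.append(vec)

    return RoiPatternSet(
        roi_id=roi_id,
        conditions=tuple(conditions),
        patterns=np.stack(rows),
        n_voxels=int(voxel_idx.size),
    )


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher's variance-stabilizing transform, z = atanh(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher transform requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def steiger_z(r12: float, r13: float, r23: float, n: int) -> float:
    """Steiger's Z for two dependent correlations sharing variable 1.

    Pooled-estimate form: with Fisher transforms ``z12, z13`` and pooled
    ``rbar = (r12 + r13) / 2``,

        psi = r23 (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r23^2) / 2
        s   = psi / (1 - rbar^2)^2
        Z   = (z12 - z13) sqrt((n - 3) / (2 - 2 s))

    ``n`` is the number of sampling units of the correlations (here, ROI
    voxels). Positive Z means variable 1 correlates more with variable 2
    than with variable 3.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly in (-1, 1), got {r}")
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar = (r12 + r13) / 2.0
    psi = r23 * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r23**2)
    s = psi / (1.0 - rbar**2) ** 2
    denom = 2.0 - 2.0 * s
    if denom <= 0:
        raise ValueError(
            f"degenerate correlation triple (r12={r12}, r13={r13}, r23={r23}): 2 - 2s <= 0"
        )
    return float((z12 - z13) * np.sqrt((n - 3.0) / denom))


@dataclass
class SimilarityRecord:
    """Per-participant, per-ROI pairwise similarities and their Steiger Z."""

    roi_id: str
    participant_id: str
    r_small_rhyme: float
    r_large_rhyme: float
    r_small_large: float
    z_small_rhyme: float
    z_large_rhyme: float
    z_small_large: float
    steiger_z: float
    n_voxels: int


def pairwise_similarity(
    pattern_set: RoiPatternSet, participant_id: str = ""
) -> SimilarityRecord:
    """Pearson similarities between the three RSA patterns plus Steiger's Z.

    Steiger's shared variable is Rhyme, so a positive Z means the rhyming
    pattern is more similar to Small than to Large problems.
    """
    for cond in RSA_CONDITIONS:
        if cond not in pattern_set.conditions:
            raise ValueError(f"pattern set lacks condition {cond!r}")
    small = pattern_set.pattern("Small")
    large = pattern_set.pattern("Large")
    rhyme = pattern_set.pattern("Rhyme")
    corr = np.corrcoef(np.stack([rhyme, small, large]))
    r_rs, r_rl, r_sl = corr[0, 1], corr[0, 2], corr[1, 2]
    return SimilarityRecord(
        roi_id=pattern_set.roi_id,
        participant_id=participant_id,
        r_small_rhyme=float(r_rs),
        r_large_rhyme=float(r_rl),
        r_small_large=float(r_sl),
        z_small_rhyme=fisher_z(r_rs),
        z_large_rhyme=fisher_z(r_rl),
        z_small_large=fisher_z(r_sl),
        steiger_z=steiger_z(r_rs, r_rl, r_sl, pattern_set.n_voxels),
        n_voxels=pattern_set.n_voxels,
    )


@dataclass
class GroupInference:
    """One-sample group test summary for one ROI (or ROI x pair cell)."""

    roi_id: str
    mean_statistic: float
    sd: float
    t: float
    p: float
    alpha_corrected: float
    significant: bool
    n_participants: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    cohen_d: float = float("nan")


def group_steiger_test(
    zs: Sequence[float],
    alpha_corrected: float,
    roi_id: str = "",
) -> GroupInference:
    """Two-sided one-sample t-test of per-participant Steiger Z values vs 0."""
    zs = np.asarray(zs, dtype=float)
    if zs.size < 2:
        raise ValueError("need at least 2 participants")
    sd = zs.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: zero variance across participants")
    n = zs.size
    mean = zs.mean()
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return GroupInference(
        roi_id=roi_id,
        mean_statistic=float(mean),
        sd=float(sd),
        t=float(t),
        p=float(p),
        alpha_corrected=float(alpha_corrected),
        significant=bool(p < alpha_corrected),
        n_participants=int(n),
        ci_low=float(mean - half),
        ci_high=float(mean + half),
        cohen_d=float(mean / sd),
    )


def dunn_sidak(alpha_family: float, m: int) -> float:
    """Per-comparison alpha 1 - (1 - alpha)^(1/m) for m comparisons."""
    if not 0.0 < alpha_family < 1.0:
        raise ValueError("alpha_family must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha_family) ** (1.0 / m)
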