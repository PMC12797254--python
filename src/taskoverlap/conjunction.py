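"""Group-level conjunction with Monte-Carlo cluster-extent correction.

The conjunction is the conservative minimum-statistic test: a voxel enters
the conjunction mask only when both contrasts are individually significant
at the voxelwise threshold. Cluster extent is calibrated by simulating
smooth Gaussian null fields, thresholding, and recording the maximum
suprathreshold cluster size per iteration (3dClustSim-style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "GroupStatMap",
    "ClusterSimResult",
    "group_ttest",
    "conjunction_mask",
    "estimate_cluster_threshold",
    "label_clusters",
    "connectivity_structure",
]

#: supported neighbourhoods: faces / faces+edges / faces+edges+corners
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}
DEFAULT_CONNECTIVITY = 18


def connectivity_structure(connectivity: int = DEFAULT_CONNECTIVITY) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


@dataclass
class GroupStatMap:
    """One-sample group t-map with one-sided p-values."""

    t: np.ndarray
    p_one_sided: np.ndarray
    n_subjects: int
    contrast_label: str = ""
    valid: np.ndarray | None = None  # False where variance degenerates

    @property
    def dof(self) -> int:
        return self.n_subjects - 1


def group_ttest(maps, contrast_label: str = "") -> GroupStatMap:
    """Voxelwise one-sample t of per-subject effect maps against zero.

    ``maps`` is a list of effect arrays (or objects with an ``effect``
    attribute), one per subject, on a common grid. Voxels with zero
    between-subject variance are masked out (``valid`` False, p = 1).
    """
    effects = [getattr(m, "effect", m) for m in maps]
    arrs = [np.asarray(e, dtype=float) for e in effects]
    if len(arrs) < 2:
        raise ValueError("need at least 2 subjects")
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError(f"grid mismatch: {a.shape} vs {shape}")
    stack = np.stack(arrs)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    valid = sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(valid, mean / (sd / np.sqrt(n)), np.nan)
    p = np.ones(shape)
    p[valid] = stats.t.sf(t[valid], n - 1)
    return GroupStatMap(
        t=t, p_one_sided=p, n_subjects=n, contrast_label=contrast_label, valid=valid
    )


def conjunction_mask(
    map_a: GroupStatMap, map_b: GroupStatMap, voxel_p: float = 0.001
) -> np.ndarray:
    """Voxels where both contrasts are significant at the one-sided voxel_p."""
    if map_a.p_one_sided.shape != map_b.p_one_sided.shape:
        raise ValueError("group maps must share one grid")
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must lie in (0, 1)")
    return (map_a.p_one_sided < voxel_p) & (map_b.p_one_sided < voxel_p)


@dataclass
class ClusterSimResult:
    """Null distribution of maximum cluster sizes and the derived threshold."""

    null_max_sizes: np.ndarray
    k_threshold: int
    alpha: float
    voxel_p: float
    smoothness_fwhm_mm: float
    n_iterations: int
    seed: int
    connectivity: int = DEFAULT_CONNECTIVITY

    def to_dict(self) -> dict:
        return {
            "k_threshold": int(self.k_threshold),
            "alpha": self.alpha,
            "voxel_p": self.voxel_p,
            "smoothness_fwhm_mm": self.smoothness_fwhm_mm,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "connectivity": self.connectivity,
            "null_max_sizes": [int(v) for v in self.null_max_sizes],
        }


def estimate_cluster_threshold(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float,
    smoothness_fwhm_mm: float,
    voxel_p: float = 0.001,
    alpha: float = 0.05,
    n_iterations: int = 1000,
    seed: int = 0,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> ClusterSimResult:
    """Monte-Carlo cluster-extent threshold for a smooth Gaussian null field.

    Per iteration: draw a white Gaussian volume, smooth it to the target
    FWHM, re-standardize empirically, threshold one-sided at ``voxel_p``,
    and record the largest suprathreshold cluster. The extent threshold is
    the ceiling of the (1 - alpha) quantile of those maxima (minimum 1).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    structure = connectivity_structure(connectivity)
    sigma_vox = smoothness_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    z_crit = stats.norm.isf(voxel_p)
    rng = np.random.default_rng(seed)

    max_sizes = np.zeros(n_iterations, dtype=int)
    for i in range(n_iterations):
        field = rng.standard_normal(grid_shape)
        if sigma_vox > 0:
            field = ndimage.gaussian_filter(field, sigma_vox, mode="constant")
            field = (field - field.mean()) / field.std()
        supra = field > z_crit
        if supra.any():
            labels, n_comp = ndimage.label(supra, structure)
            if n_comp:
                sizes = np.bincount(labels.ravel())[1:]
                max_sizes[i] = sizes.max()

    k = max(int(np.ceil(np.quantile(max_sizes, 1.0 - alpha))), 1)
    return ClusterSimResult(
        null_max_sizes=max_sizes,
        k_threshold=k,
        alpha=alpha,
        voxel_p=voxel_p,
        smoothness_fwhm_mm=smoothness_fwhm_mm,
        n_iterations=n_iterations,
        seed=seed,
        connectivity=connectivity,
    )


def estimate_smoothness_fwhm(
    residual: np.ndarray, voxel_size_mm: float
) -> float:
    """Residual-based smoothness estimate (Gaussian ACF fit, lag-1).

    Averages the lag-1 spatial autocorrelation of a residual volume (or a
    T x grid stack) over the three axes and inverts the Gaussian ACF
    ``rho(d) = exp(-d^2 / (4 sigma^2))``. Returns 0 for non-positive rho.
    """
    res = np.asarray(residual, dtype=float)
    if res.ndim == 3:
        res = res[None]
    rhos = []
    for axis in (1, 2, 3):
        a = np.moveaxis(res, axis, -1)
        x, y = a[..., :-1], a[..., 1:]
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        if denom > 0:
            rhos.append((xc * yc).sum() / denom)
    rho = float(np.mean(rhos)) if rhos else 0.0
    if rho <= 0:
        return 0.0
    sigma_vox = np.sqrt(-1.0 / (4.0 * np.log(rho)))
    return float(sigma_vox * voxel_size_mm * 2.0 * np.sqrt(2.0 * np.log(2.0)))


def label_clusters(
    mask: np.ndarray,
    k_min: int,
    stat: np.ndarray,
    voxel_size_mm: float = 2.5,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> pd.DataFrame:
    """Connected components of ``mask`` at least ``k_min`` voxels large.

    Returns a table with one row per retained cluster: ``cluster_id``,
    ``size_voxels``, peak voxel indices, their mm equivalents (voxel index
    times voxel size) and the peak statistic (max |stat|; ties broken by
    lexicographic voxel index). Sorted by size, largest first.
    """
    mask = np.asarray(mask, dtype=bool)
    stat = np.asarray(stat, dtype=float)
    if stat.shape != mask.shape:
        raise ValueError("stat grid must match mask")
    structure = connectivity_structure(connectivity)
    labels, n_comp = ndimage.label(mask, structure)

    rows = []
    for comp in range(1, n_comp + 1):
        voxels = np.argwhere(labels == comp)  # lexicographic order
        size = len(voxels)
        if size < k_min:
            continue
        vals = np.abs(stat[tuple(voxels.T)])
        peak = voxels[int(np.argmax(vals))]  # argmax -> first max, ties lexicographic
        rows.append(
            {
                "size_voxels": size,
                "peak_x_vox": int(peak[0]),
                "peak_y_vox": int(peak[1]),
                "peak_z_vox": int(peak[2]),
                "peak_x_mm": float(peak[0] * voxel_size_mm),
                "peak_y_mm": float(peak[1] * voxel_size_mm),
                "peak_z_mm": float(peak[2] * voxel_size_mm),
                "peak_stat": float(stat[tuple(peak)]),
            }
        )
    rows.sort(key=lambda r: -r["size_voxels"])
    table = pd.DataFrame(
        rows,
        columns=[
            "size_voxels",
            "peak_x_vox",
            "peak_y_vox",
            "peak_z_vox",
            "peak_x_mm",
            "peak_y_mm",
            "peak_z_mm",
            "peak_stat",
        ],
    )
    table.insert(0, "cluster_id", np.arange(1, len(table) + 1))
    return table


def cluster_masks(
    mask: np.ndarray,
    k_min: int,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> dict[int, np.ndarray]:
    """Boolean mask per retained cluster, keyed by size-ranked cluster id."""
    mask = np.asarray(mask, dtype=bool)
    structure = connectivity_structure(connectivity)
    labels, n_comp = ndimage.label(mask, structure)
    comps = []
    for comp in range(1, n_comp + 1):
        m = labels == comp
        if m.sum() >= k_min:
            comps.append(m)
    comps.sort(key=lambda m: -int(m.sum()))
    return {i + 1: m for i, m in enumerate(comps)}
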