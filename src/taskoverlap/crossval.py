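"""Noise-normalized, split-half cross-validated pattern similarity.

Naive within-run pattern correlations are inflated by noise shared across
conditions; correlating patterns estimated from independent runs removes
that inflation and restores a meaningful zero baseline. Patterns are first
whitened by the inverse principal square root of a shrinkage-regularized
voxel noise covariance estimated from GLM residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from taskoverlap.similarity import GroupInference, fisher_z

__all__ = [
    "CROSSVAL_PAIRS",
    "NoiseCovariance",
    "CrossvalSimilarityRecord",
    "estimate_noise_covariance",
    "whiten_patterns",
    "split_half_similarity",
    "group_crossval_test",
]

CROSSVAL_PAIRS = (("Small", "Rhyme"), ("Large", "Rhyme"))
#: below this many time points the covariance is not estimable: shrink fully
MIN_STABLE_TIMEPOINTS = 30


@dataclass
class NoiseCovariance:
    """Shrunk voxel noise covariance and its inverse principal square root."""

    sigma: np.ndarray
    shrinkage_lambda: float
    dof: int
    whitener: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.sigma.shape[0]


def _shrinkage_intensity(residuals: np.ndarray, sample_cov: np.ndarray) -> float:
    """Analytic off-diagonal shrinkage intensity (Ledoit-Wolf style).

    lambda* = sum_{i != j} Var_hat(s_ij) / sum_{i != j} s_ij^2, clipped to
    [0, 1]; the variance of each covariance entry is estimated from the
    cross-products' sample variance.
    """
    t_len = residuals.shape[0]
    x = residuals - residuals.mean(axis=0)
    # Var(s_ij) ~ n/(n-1)^3 * sum_t (x_ti x_tj - mean)^2
    xsq = x**2
    sum_w2 = xsq.T @ xsq  # sum_t (x_ti x_tj)^2
    wbar = (x.T @ x) / t_len
    var_s = t_len / (t_len - 1.0) ** 3 * (sum_w2 - t_len * wbar**2)
    off = ~np.eye(sample_cov.shape[0], dtype=bool)
    denom = float((sample_cov[off] ** 2).sum())
    if denom <= 0:
        return 1.0
    lam = float(var_s[off].sum()) / denom
    return float(np.clip(lam, 0.0, 1.0))


def estimate_noise_covariance(
    residuals: np.ndarray,
    dof: int | None = None,
    target: str = "diagonal",
    eigenvalue_floor: float = 1e-6,
) -> NoiseCovariance:
    """Shrinkage-regularized covariance of GLM residuals over time.

    The sample covariance is shrunk toward its own diagonal (or toward the
    scaled identity with ``target='identity'``) with an analytically chosen
    intensity; the whitener is Sigma^(-1/2) via eigendecomposition with a
    relative floor on the eigenvalues.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2:
        raise ValueError("residuals must be T x voxel")
    t_len, n_vox = residuals.shape
    if t_len < 2 or n_vox < 2:
        raise ValueError("need T > 1 and at least 2 voxels")
    if target not in ("diagonal", "identity"):
        raise ValueError("target must be 'diagonal' or 'identity'")
    if dof is None:
        dof = t_len - 1

    centered = residuals - residuals.mean(axis=0)
    sample = (centered.T @ centered) / dof

    if t_len < MIN_STABLE_TIMEPOINTS:
        warnings.warn(
            f"only {t_len} time points for {n_vox} voxels; covariance estimate "
            "is unstable, applying maximal shrinkage",
            stacklevel=2,
        )
        lam = 1.0
    else:
        lam = _shrinkage_intensity(centered, sample)

    if target == "diagonal":
        target_mat = np.diag(np.diag(sample))
    else:
        target_mat = np.eye(n_vox) * np.trace(sample) / n_vox
    sigma = lam * target_mat + (1.0 - lam) * sample
    sigma = (sigma + sigma.T) / 2.0

    vals, vecs = np.linalg.eigh(sigma)
    floor = eigenvalue_floor * vals.max()
    vals = np.clip(vals, floor, None)
    whitener = (vecs / np.sqrt(vals)) @ vecs.T

    return NoiseCovariance(sigma=sigma, shrinkage_lambda=lam, dof=dof, whitener=whitener)


def whiten_patterns(
    patterns: np.ndarray, cov: NoiseCovariance
) -> np.ndarray:
    """Right-multiply condition x voxel patterns by the whitener."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[-1] != cov.n_voxels:
        raise ValueError(
            f"patterns have {patterns.shape[-1]} voxels, whitener expects {cov.n_voxels}"
        )
    return patterns @ cov.whitener


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ValueError("zero-variance pattern; correlation undefined")
    return float((a * b).sum() / denom)


def split_half_similarity(
    patterns_run1: Mapping[str, np.ndarray],
    patterns_run2: Mapping[str, np.ndarray],
    pair: tuple[str, str],
) -> float:
    """Cross-validated similarity of two conditions across two runs.

    ``r_cv = [corr(a_1, b_2) + corr(a_2, b_1)] / 2`` — each condition's
    pattern from one run is correlated with the other condition's pattern
    from the other run, so shared within-run noise cannot inflate the
    estimate and independent patterns give expectation 0.
    """
    cond_a, cond_b = pair
    for name, mapping in (("run 1", patterns_run1), ("run 2", patterns_run2)):
        for cond in pair:
            if cond not in mapping:
                raise KeyError(f"{name} patterns lack condition {cond!r}")
    a1, a2 = np.asarray(patterns_run1[cond_a]), np.asarray(patterns_run2[cond_a])
    b1, b2 = np.asarray(patterns_run1[cond_b]), np.asarray(patterns_run2[cond_b])
    return 0.5 * (_pearson(a1, b2) + _pearson(a2, b1))


@dataclass
class CrossvalSimilarityRecord:
    roi_id: str
    pair: tuple[str, str]
    r_cv: float
    participant_id: str


def group_crossval_test(
    records: Sequence[CrossvalSimilarityRecord],
    alpha_corrected: float,
    use_fisher: bool = True,
) -> dict[tuple[str, tuple[str, str]], GroupInference]:
    """Per (ROI, pair) two-sided one-sample t-test of r_cv against zero.

    Values are Fisher-transformed before testing by default. Returns a dict
    keyed by ``(roi_id, pair)``; the summaries carry mean, SD, 95% CI, t, p,
    Cohen's d and a significance flag at the supplied corrected alpha.
    """
    cells: dict[tuple[str, tuple[str, str]], list[float]] = {}
    for rec in records:
        cells.setdefault((rec.roi_id, tuple(rec.pair)), []).append(rec.r_cv)

    out: dict[tuple[str, tuple[str, str]], GroupInference] = {}
    for key, values in cells.items():
        vals = np.asarray(values, dtype=float)
        if vals.size < 2:
            raise ValueError(f"cell {key} has fewer than 2 participants")
        tested = fisher_z(vals) if use_fisher else vals
        sd = tested.std(ddof=1)
        if sd == 0:
            raise ValueError(f"cell {key} has zero variance across participants")
        n = tested.size
        mean = tested.mean()
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), n - 1)
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        out[key] = GroupInference(
            roi_id=key[0],
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
    return out
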