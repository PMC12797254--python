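"""File formats and configuration.

NIfTI for volumes (RAS+, affine from the isotropic voxel size), BIDS-style
TSV for events and motion, JSON for ground truth / reports / provenance,
and YAML or JSON for the pipeline configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from taskoverlap.synthetic import (
    CONDITION_ORDER,
    TASK_CONDITIONS,
    AcquisitionSpec,
    BlockDesign,
    BoldRun,
    Event,
    GroundTruth,
)

__all__ = [
    "PipelineConfig",
    "read_bold",
    "write_bold",
    "read_events",
    "write_events",
    "read_motion",
    "write_motion",
    "read_ground_truth",
    "write_ground_truth",
    "write_mask",
    "read_mask",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def write_bold(run: BoldRun, path: str | Path) -> Path:
    """Write a run as 4D NIfTI (X, Y, Z, T order, RAS+ affine)."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.moveaxis(run.data, 0, -1).astype(np.float32),
        _affine(run.spec.voxel_size_mm),
    )
    img.header.set_zooms(
        (run.spec.voxel_size_mm,) * 3 + (run.spec.tr_seconds,)
    )
    nib.save(img, path)
    return path


def read_bold(path: str | Path, design: BlockDesign | None = None,
              motion: np.ndarray | None = None) -> BoldRun:
    """Load a 4D NIfTI back into a :class:`BoldRun`.

    Design/motion metadata are not stored in the NIfTI; pass them in if the
    run is to be fitted.
    """
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj, dtype=float)
    except Exception as exc:  # nibabel raises several unrelated types
        raise IOError(f"cannot read NIfTI {path}: {exc}") from exc
    if data.ndim != 4:
        raise IOError(f"{path} is {data.ndim}D; expected a 4D BOLD series")
    zooms = img.header.get_zooms()
    spec = AcquisitionSpec(
        tr_seconds=float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0,
        n_volumes=data.shape[3],
        grid_shape=data.shape[:3],
        voxel_size_mm=float(zooms[0]),
    )
    run = BoldRun(
        data=np.moveaxis(data, -1, 0),
        spec=spec,
        design=design,
        motion=motion,
    )
    run.global_signal = run.data.mean(axis=(1, 2, 3))
    return run


def write_events(design: BlockDesign, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "onset": [ev.onset_s for ev in design.events],
            "duration": [ev.duration_s for ev in design.events],
            "trial_type": [ev.condition for ev in design.events],
            "correct": [int(ev.correct) for ev in design.events],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path, run_label: str | None = None) -> BlockDesign:
    """Read a BIDS-style events TSV into a :class:`BlockDesign`.

    Unknown ``trial_type`` values raise with the list of valid conditions;
    out-of-order onsets are sorted with a warning. The task is inferred from
    the conditions present.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    if frame.empty:
        raise ValueError(f"events file {path} is empty")
    required = {"onset", "duration", "trial_type"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"events file {path} lacks columns {sorted(missing)}")

    conditions = set(frame["trial_type"])
    unknown = conditions - set(CONDITION_ORDER)
    if unknown:
        raise ValueError(
            f"unknown trial_type values {sorted(unknown)}; valid conditions are "
            f"{list(CONDITION_ORDER)}"
        )
    task_matches = [
        task for task, conds in TASK_CONDITIONS.items() if conditions <= set(conds)
    ]
    if not task_matches:
        raise ValueError(
            f"conditions {sorted(conditions)} mix tasks; events must belong to one task"
        )

    if not frame["onset"].is_monotonic_increasing:
        warnings.warn(f"events in {path} are out of order; sorting by onset", stacklevel=2)
        frame = frame.sort_values("onset", kind="stable")

    correct = frame["correct"] if "correct" in frame.columns else pd.Series(1, index=frame.index)
    events = [
        Event(
            condition=row.trial_type,
            onset_s=float(row.onset),
            duration_s=float(row.duration),
            correct=bool(c),
        )
        for row, c in zip(frame.itertuples(), correct)
    ]
    return BlockDesign(
        task=task_matches[0],
        events=events,
        run_label=run_label or path.stem,
    )


def write_motion(motion: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    pd.DataFrame(np.asarray(motion), columns=cols).to_csv(path, sep="\t", index=False)
    return path


def read_motion(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] != 6:
        raise ValueError(f"motion table {path} must have 6 columns, has {frame.shape[1]}")
    return frame.to_numpy(dtype=float)


def write_mask(mask: np.ndarray, voxel_size_mm: float, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size_mm))
    nib.save(img, path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(Path(path))
    return np.asanyarray(img.dataobj) > 0


# ---------------------------------------------------------------------------
# ground truth round trip (masks as voxel index lists; text-only format)
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, grid_shape: tuple[int, int, int],
                       path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "grid_shape": list(grid_shape),
        "roi_masks": {
            roi: np.flatnonzero(mask.ravel()).tolist()
            for roi, mask in truth.roi_masks.items()
        },
        "condition_amplitudes": truth.condition_amplitudes,
        "pattern_correlations": [
            {"pair": sorted(pair), "rho": rho}
            for pair, rho in truth.pattern_correlations.items()
        ],
        "noise_sd": truth.noise_sd,
        "spatial_fwhm_mm": truth.spatial_fwhm_mm,
        "ar1_coefficient": truth.ar1_coefficient,
        "pattern_mean": truth.pattern_mean,
        "pattern_sd": truth.pattern_sd,
        "roi_condition_amplitudes": truth.roi_condition_amplitudes,
        "p_correct": truth.p_correct,
        "seed": truth.seed,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    grid = tuple(payload["grid_shape"])
    masks = {}
    for roi, idx in payload["roi_masks"].items():
        mask = np.zeros(int(np.prod(grid)), dtype=bool)
        mask[np.asarray(idx, dtype=int)] = True
        masks[roi] = mask.reshape(grid)
    return GroundTruth(
        roi_masks=masks,
        condition_amplitudes=payload["condition_amplitudes"],
        pattern_correlations={
            frozenset(item["pair"]): item["rho"]
            for item in payload["pattern_correlations"]
        },
        noise_sd=payload["noise_sd"],
        spatial_fwhm_mm=payload["spatial_fwhm_mm"],
        ar1_coefficient=payload["ar1_coefficient"],
        pattern_mean=payload["pattern_mean"],
        pattern_sd=payload["pattern_sd"],
        roi_condition_amplitudes=payload["roi_condition_amplitudes"],
        p_correct=payload.get("p_correct", 1.0),
        seed=payload["seed"],
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything needed for a deterministic end-to-end run."""

    n_subjects: int = 8
    seed: int = 0
    group_label: str = "adults"
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    tr_seconds: float = 1.0
    n_volumes: int = 244
    voxel_size_mm: float = 2.5
    noise_sd: float = 3.0
    smoothing_fwhm_mm: float = 6.0
    voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    family_alpha: float = 0.05
    cluster_sim_iterations: int = 1000
    connectivity: int = 18
    min_roi_voxels: int = 10
    sidak_m: int | None = None  # None -> number of ROIs found

    def __post_init__(self) -> None:
        for name in ("voxel_p", "cluster_alpha", "family_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        self.grid_shape = tuple(int(g) for g in self.grid_shape)

    @property
    def acquisition(self) -> AcquisitionSpec:
        return AcquisitionSpec(
            tr_seconds=self.tr_seconds,
            n_volumes=self.n_volumes,
            grid_shape=self.grid_shape,
            voxel_size_mm=self.voxel_size_mm,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        """Stable hash identifying this configuration in output tables."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
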