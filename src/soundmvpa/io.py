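"""File formats: NIfTI-1 volumes, TSV labels/events, JSON configs & results."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datasets import BetaDataset, LABEL_COLUMNS
from .grid import VoxelGrid

__all__ = [
    "NiftiFormatError",
    "load_nifti",
    "save_nifti",
    "load_labels",
    "save_labels",
    "save_events",
    "save_betas",
    "load_betas",
    "save_mask",
    "load_grid",
    "fit_to_dict",
    "PipelineConfig",
]


class NiftiFormatError(ValueError):
    """Raised for files that are not readable NIfTI-1 images."""


def load_nifti(path):
    """Read a NIfTI file; returns ``(data array, affine)`` with the on-disk dtype."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as e:  # nibabel raises several unrelated types
        raise NiftiFormatError(f"cannot read {path} as NIfTI: {e}") from e
    return data, img.affine


def save_nifti(volume, affine, path):
    """Write an array as NIfTI-1, preserving its dtype (bit-exact round trip
    for float32/int16 and other fixed-width types)."""
    volume = np.asarray(volume)
    img = nib.Nifti1Image(volume, np.asarray(affine, dtype=float))
    img.header.set_data_dtype(volume.dtype)
    nib.save(img, str(path))


def save_labels(labels: pd.DataFrame, path):
    """Write the sample metadata TSV (sample, subject, run, category, item)."""
    out = labels.copy()
    out.insert(0, "sample", np.arange(len(out)))
    out.to_csv(path, sep="\t", index=False)


def load_labels(path, n_samples: int = None) -> pd.DataFrame:
    """Read a labels TSV; order matches the beta volumes."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"labels file {path} missing columns {missing}")
    if n_samples is not None and len(df) != n_samples:
        raise ValueError(
            f"labels file has {len(df)} rows but betas have {n_samples} samples"
        )
    return df[list(LABEL_COLUMNS)].copy()


def save_events(design, run: int, path):
    """BIDS-style events TSV (onset, duration, category, item) for one run."""
    onsets = design.onsets_s()
    rows = [
        {"onset": float(onsets[k]), "duration": 1.0, "category": c, "item": i}
        for k, (c, i) in enumerate(design.run_orders[run])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_betas(dataset: BetaDataset, nii_path, labels_path, mask_path=None):
    """Write a BetaDataset as a 4-D NIfTI (one volume per sample) + TSV."""
    grid = dataset.grid
    vol4 = np.zeros(grid.dims + (dataset.n_samples,), dtype=np.float32)
    for s in range(dataset.n_samples):
        vol4[..., s] = grid.to_volume(dataset.X[s].astype(np.float32))
    save_nifti(vol4, grid.affine, nii_path)
    save_labels(dataset.labels, labels_path)
    if mask_path is not None:
        save_mask(grid, mask_path)


def save_mask(grid: VoxelGrid, path):
    save_nifti(grid.mask.astype(np.int16), grid.affine, path)


def load_grid(mask_path) -> VoxelGrid:
    data, affine = load_nifti(mask_path)
    return VoxelGrid(dims=data.shape, affine=affine, mask=data > 0)


def load_betas(nii_path, labels_path, mask_path) -> BetaDataset:
    """Rebuild a BetaDataset from its 4-D NIfTI + labels TSV + mask NIfTI."""
    grid = load_grid(mask_path)
    data, _ = load_nifti(nii_path)
    if data.ndim != 4 or data.shape[:3] != grid.dims:
        raise ValueError("beta image does not match the mask geometry")
    labels = load_labels(labels_path, n_samples=data.shape[3])
    X = np.stack(
        [grid.from_volume(data[..., s]) for s in range(data.shape[3])]
    ).astype(float)
    return BetaDataset(X=X, labels=labels, grid=grid)


def fit_to_dict(fit) -> dict:
    """JSON-serializable summary of a FitResult (selection + trace + weights)."""
    return {
        "selected_voxels": fit.selected_voxels.tolist(),
        "trace_sizes": fit.trace.sizes,
        "cv_errors": [s.cv_error for s in fit.trace.steps],
        "class_labels": list(fit.final_model.class_labels),
        "weights": [m.w.tolist() for m in fit.final_model.models],
        "biases": [m.b for m in fit.final_model.models],
        "n_features": fit.n_features,
    }


# ---------------------------------------------------------------------------
# configuration


def _strict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class DesignConfig:
    n_runs: int = 7
    n_categories: int = 7
    items_per_category: int = 6
    tr_s: float = 3.0
    volumes_per_trial: int = 5
    isi_s: float = 15.0


@dataclass
class GridConfig:
    dims: tuple = (20, 20, 10)
    voxel_mm: tuple = (1.7, 1.7, 2.0)


@dataclass
class TruthConfig:
    n_informative_per_category: int = 50
    effect_size: float = 1.5
    overlap_fraction: float = 0.0


@dataclass
class SubjectConfig:
    n_subjects: int = 6
    spatial_jitter_voxels: int = 1
    gain_sd: float = 0.25
    offset_sd: float = 0.1


@dataclass
class NoiseConfig:
    sigma_item: float = 0.6
    sigma_run: float = 0.3
    sigma_noise: float = 1.0


@dataclass
class SvmConfig:
    C: float = 1.0
    standardize: bool = True
    tol: float = 1e-6


@dataclass
class CasesConfig:
    cases: tuple = ("WithinSub", "AcrossSub", "AvgItem", "AvgSub")
    n_reps: int = 5
    n_train_runs: int = 5
    exclude_subjects: tuple = ()


@dataclass
class MapsConfig:
    min_reps: int = 2
    min_subjects: int = 2
    connectivity: int = 6


@dataclass
class PipelineConfig:
    """Complete, JSON-round-trippable pipeline configuration.

    Unknown keys anywhere in the JSON are rejected so that typos never
    silently fall back to defaults.
    """

    design: DesignConfig = field(default_factory=DesignConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    subjects: SubjectConfig = field(default_factory=SubjectConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    cases: CasesConfig = field(default_factory=CasesConfig)
    maps: MapsConfig = field(default_factory=MapsConfig)
    seed: int = 0

    _SECTIONS = {
        "design": DesignConfig,
        "grid": GridConfig,
        "truth": TruthConfig,
        "subjects": SubjectConfig,
        "noise": NoiseConfig,
        "svm": SvmConfig,
        "cases": CasesConfig,
        "maps": MapsConfig,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - set(cls._SECTIONS) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, sub_cls in cls._SECTIONS.items():
            if name in d:
                sub = d.pop(name)
                if not isinstance(sub, dict):
                    raise ValueError(f"config section {name!r} must be an object")
                kwargs[name] = _strict(sub_cls, sub)
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {
            name: dataclasses.asdict(getattr(self, name))
            for name in self._SECTIONS
        }
        out["seed"] = self.seed
        # tuples -> lists for lossless JSON round trip
        return json.loads(json.dumps(out))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def __post_init__(self):
        # normalize list-typed JSON fields back to tuples
        self.grid.dims = tuple(self.grid.dims)
        self.grid.voxel_mm = tuple(self.grid.voxel_mm)
        self.cases.cases = tuple(self.cases.cases)
        self.cases.exclude_subjects = tuple(self.cases.exclude_subjects)
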