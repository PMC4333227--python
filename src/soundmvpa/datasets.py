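"""In-memory containers moved between pipeline stages.

``BetaDataset`` is the central currency: a samples x voxels matrix of
per-stimulus response amplitudes with per-sample metadata (subject, run,
category, item) and the :class:`~soundmvpa.grid.VoxelGrid` that defines the
column order.  ``BoldDataset`` holds simulated raw time series before GLM
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import VoxelGrid

__all__ = ["BetaDataset", "BoldDataset", "LABEL_COLUMNS"]

LABEL_COLUMNS = ("subject", "run", "category", "item")


@dataclass(eq=False)
class BetaDataset:
    """Sample x voxel response-amplitude matrix with labels.

    Attributes
    ----------
    X : ndarray, shape (n_samples, p)
        Response amplitude of each stimulus presentation at each in-mask
        voxel; column ``j`` is voxel ``j`` under ``grid``'s linearization.
    labels : DataFrame with columns subject, run, category, item
        One row per sample, aligned with ``X`` rows.
    grid : VoxelGrid
    """

    X: np.ndarray
    labels: pd.DataFrame
    grid: VoxelGrid

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x voxels)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise ValueError(f"labels missing columns: {missing}")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError(
                f"{len(self.labels)} label rows for {self.X.shape[0]} samples"
            )
        if self.grid is not None and self.grid.p != self.X.shape[1]:
            raise ValueError(
                f"grid has {self.grid.p} in-mask voxels but X has "
                f"{self.X.shape[1]} columns"
            )
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def subjects(self) -> list:
        """Unique subjects in first-appearance order."""
        return list(pd.unique(self.labels["subject"]))

    def runs(self) -> list:
        return list(pd.unique(self.labels["run"]))

    def categories(self) -> list:
        return list(pd.unique(self.labels["category"]))

    def subset(self, idx) -> "BetaDataset":
        """Row subset (new dataset, same grid)."""
        idx = np.asarray(idx)
        return BetaDataset(
            X=self.X[idx], labels=self.labels.iloc[idx], grid=self.grid
        )


@dataclass(eq=False)
class BoldDataset:
    """Per-(subject, run) voxel time series from the BOLD simulator.

    ``series[(subject, run)]`` is a volumes x p matrix; ``amplitudes`` keeps
    the generative per-trial response amplitudes (trials x p) so that GLM
    round-trip accuracy can be validated.
    """

    series: dict
    design: object  # StimulusDesign
    amplitudes: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    drift_amp: float = 0.0

    def __post_init__(self):
        vpr = self.design.volumes_per_run
        for key, arr in self.series.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape[0] != vpr:
                raise ValueError(
                    f"run {key}: {arr.shape[0]} volumes, expected {vpr}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"run {key}: non-finite values")
            self.series[key] = arr
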