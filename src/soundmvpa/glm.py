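"""Beta-series GLM: one response amplitude per stimulus trial per voxel.

Each functional run is modeled separately with ordinary least squares.  The
design matrix has one HRF-convolved indicator column per trial (beta-series
coding) followed by an intercept and polynomial drift columns; the estimated
trial coefficients are the per-stimulus responses fed into the decoder.  No
prewhitening is applied: the slow event-related timing (15 s ISI) leaves
little trial overlap and the noise model is left unspecified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .datasets import BetaDataset, BoldDataset
from .synth import StimulusDesign

__all__ = [
    "SingularDesignError",
    "DesignMatrix",
    "canonical_hrf",
    "build_design_matrix",
    "estimate_betas",
]


class SingularDesignError(ValueError):
    """Raised when the GLM design matrix is rank deficient."""


def canonical_hrf(t_seconds, peak_delay=6.0, undershoot_delay=16.0, ratio=1.0 / 6.0):
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    ``h(t) = g(t; peak_delay) - ratio * g(t; undershoot_delay)`` with unit-scale
    gamma densities; h(0) = 0 and the peak falls near 5 s with defaults.
    """
    t = np.asarray(t_seconds, dtype=float)
    if np.any(t < 0):
        raise ValueError("canonical_hrf requires t >= 0")

    def gpdf(x, shape):
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.exp(
            (shape - 1) * np.log(x[pos]) - x[pos] - special.gammaln(shape)
        )
        return out

    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    h = gpdf(t, peak_delay) - ratio * gpdf(t, undershoot_delay)
    # normalize so the canonical shape peaks at 1
    tt = np.linspace(0, 32, 3201)
    hh = gpdf(tt, peak_delay) - ratio * gpdf(tt, undershoot_delay)
    h = h / hh.max()
    return float(h[0]) if scalar else h


@dataclass(eq=False)
class DesignMatrix:
    """Volumes x (trials + nuisance) GLM design for one run.

    Trial columns (HRF-convolved single-trial indicators) come first, ordered
    by onset, followed by an intercept and polynomial drift terms.
    """

    matrix: np.ndarray
    n_trials: int
    nuisance_order: int
    onsets_s: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def build_design_matrix(
    design: StimulusDesign,
    run: int = 0,
    nuisance_order: int = 1,
    onsets_s=None,
) -> DesignMatrix:
    """Assemble the per-run beta-series design matrix.

    One column per trial (HRF at the volume times relative to that trial's
    onset), then an intercept and Legendre-like polynomial drift columns up
    to ``nuisance_order``.  Raises :class:`SingularDesignError` if the result
    is rank deficient (e.g. duplicated onsets).
    """
    if not 0 <= run < design.n_runs:
        raise KeyError(f"run {run} not in design (n_runs={design.n_runs})")
    if nuisance_order < 0:
        raise ValueError("nuisance_order must be >= 0")
    n_vol = design.volumes_per_run
    t = np.arange(n_vol) * design.tr_s
    onsets = design.onsets_s() if onsets_s is None else np.asarray(onsets_s, float)
    cols = []
    for onset in onsets:
        dt = t - onset
        col = np.zeros(n_vol)
        pos = dt >= 0
        col[pos] = canonical_hrf(dt[pos])
        cols.append(col)
    t_norm = np.linspace(-1, 1, n_vol)
    for k in range(nuisance_order + 1):
        cols.append(np.polynomial.legendre.Legendre.basis(k)(t_norm))
    M = np.column_stack(cols)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise SingularDesignError(
            "design matrix is rank deficient (duplicate onsets or excessive "
            "drift order)"
        )
    return DesignMatrix(
        matrix=M,
        n_trials=len(onsets),
        nuisance_order=nuisance_order,
        onsets_s=onsets,
    )


def estimate_betas(
    bold: BoldDataset,
    design_matrix: DesignMatrix = None,
    nuisance_order: int = 1,
    grid=None,
) -> BetaDataset:
    """OLS beta-series estimation, one fit per run.

    For every (subject, run) series the trial betas are the OLS coefficients
    of the trial columns; nuisance betas are discarded.  Output rows follow
    trial (onset) order within each run and carry the run's (category, item)
    labels.
    """
    design = bold.design
    if design_matrix is None:
        design_matrix = build_design_matrix(design, 0, nuisance_order)
    M = design_matrix.matrix
    # shared pseudo-inverse: trial spacing is identical across runs
    pinv = np.linalg.pinv(M)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    rows, recs = [], []
    for (subject, run), data in bold.series.items():
        if data.shape[0] != M.shape[0]:
            raise ValueError(
                f"run {(subject, run)}: {data.shape[0]} volumes != "
                f"{M.shape[0]} design rows"
            )
        betas = pinv @ data  # columns x voxels
        trial_betas = betas[: design_matrix.n_trials]
        for k, (c, i) in enumerate(design.run_orders[run]):
            rows.append(trial_betas[k])
            recs.append(
                {"subject": subject, "run": run, "category": c, "item": i}
            )
    return BetaDataset(X=np.array(rows), labels=pd.DataFrame(recs), grid=grid)
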