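"""Synthetic slow event-related auditory fMRI data.

The generator emulates the study conditions of a multi-subject sound-category
decoding experiment: 7 cognitive sound categories (English speech, non-English
speech, vocal, animal, mechanical, music, nature) x 6 items each, presented
once per functional run in pseudo-randomized order, 7 runs per subject, slow
event-related timing (15 s ISI, TR = 3 s, 5 volumes per trial).  Category
information is carried by sparse distributed voxel patterns; nuisance
variability is decomposed into item-, run-, subject-level and thermal
components so that the four experiment cases (within-subject, across-subject,
item-averaged, subject-averaged) probe different terms of that decomposition.

Key generative choices
----------------------
* Item effects are drawn once per token (category, item) and reused across
  runs and subjects, so averaging over items removes exactly the item-level
  variance component.
* Subject variation = an integer spatial jitter of each category template
  plus a multiplicative voxelwise gain field and an additive offset map,
  emulating imperfect inter-subject alignment and gain differences.
* Run effects are voxelwise offsets drawn per (subject, run).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import rng_for
from .datasets import BetaDataset, BoldDataset
from .grid import VoxelGrid

__all__ = [
    "DEFAULT_CATEGORIES",
    "StimulusDesign",
    "GroundTruth",
    "SubjectModel",
    "make_design",
    "make_ground_truth",
    "make_subjects",
    "simulate_betas",
    "simulate_bold",
]

#: The seven sound categories: English speech, non-English speech, vocal,
#: animal, mechanical, music, nature.
DEFAULT_CATEGORIES = ("EN", "NE", "VC", "AN", "MC", "MS", "NT")


@dataclass(eq=False)
class StimulusDesign:
    """Trial timing and per-run stimulus orders.

    ``run_orders[r]`` is the ordered list of (category, item) tokens of run
    ``r``; each run presents every token exactly once.  ``stimulus_volume_index``
    is the trial volume in whose preceding silent gap the sound is played.
    """

    n_runs: int
    categories: tuple
    items_per_category: int
    run_orders: list
    tr_s: float = 3.0
    volumes_per_trial: int = 5
    isi_s: float = 15.0
    stimulus_volume_index: int = 0

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def trials_per_run(self) -> int:
        return self.n_categories * self.items_per_category

    @property
    def volumes_per_run(self) -> int:
        return self.trials_per_run * self.volumes_per_trial

    @property
    def run_duration_s(self) -> float:
        return self.trials_per_run * self.isi_s

    def tokens(self) -> list:
        return [
            (c, i)
            for c in self.categories
            for i in range(1, self.items_per_category + 1)
        ]

    def onsets_s(self) -> np.ndarray:
        """Stimulus onset times (s) within a run, one per trial."""
        k = np.arange(self.trials_per_run)
        return k * self.isi_s + self.stimulus_volume_index * self.tr_s

    def validate(self):
        toks = set(self.tokens())
        if len(self.run_orders) != self.n_runs:
            raise ValueError("run_orders length != n_runs")
        for r, order in enumerate(self.run_orders):
            if set(order) != toks or len(order) != len(toks):
                raise ValueError(f"run {r} is not a permutation of all tokens")


@dataclass(eq=False)
class GroundTruth:
    """Category-selective spatial templates used to generate data.

    ``informative_sets[c]`` are the in-mask column indices carrying signal for
    category ``c``; ``pattern_means[c]`` is the length-p template, zero
    outside that set.
    """

    informative_sets: dict
    pattern_means: dict
    effect_size: float

    def all_informative(self) -> np.ndarray:
        """Sorted union of informative voxels over categories."""
        if not self.informative_sets:
            return np.array([], dtype=int)
        return np.unique(np.concatenate(list(self.informative_sets.values())))


@dataclass(eq=False)
class SubjectModel:
    """Per-subject perturbation of the group-level templates."""

    subject_id: str
    spatial_jitter_voxels: int
    gain_field: np.ndarray  # length p, mean ~1
    additive_offset: np.ndarray  # length p
    shifts: dict = field(default_factory=dict)  # category -> (dx, dy, dz)


def make_design(
    n_runs: int = 7,
    n_categories: int = 7,
    items_per_category: int = 6,
    seed: int = 0,
    *,
    categories=None,
    tr_s: float = 3.0,
    volumes_per_trial: int = 5,
    isi_s: float = 15.0,
    stimulus_volume_index: int = 0,
) -> StimulusDesign:
    """Draw per-run pseudo-random stimulus orders.

    Each run is an independent uniform permutation of all tokens; when more
    than one run is requested the orders are guaranteed pairwise distinct
    (re-drawn on collision), matching pseudo-randomization across runs.
    """
    if n_runs < 1 or n_categories < 2 or items_per_category < 1:
        raise ValueError(
            "need n_runs >= 1, n_categories >= 2, items_per_category >= 1"
        )
    if categories is None:
        if n_categories <= len(DEFAULT_CATEGORIES):
            categories = DEFAULT_CATEGORIES[:n_categories]
        else:
            categories = tuple(f"C{i+1}" for i in range(n_categories))
    categories = tuple(categories)
    if len(categories) != n_categories:
        raise ValueError("categories length != n_categories")

    tokens = [(c, i) for c in categories for i in range(1, items_per_category + 1)]
    n_tok = len(tokens)
    # number of distinct permutations (capped; 13! already exceeds any n_runs)
    n_perms = math.factorial(n_tok) if n_tok <= 13 else None
    if n_perms is not None and n_runs > n_perms:
        raise ValueError(
            f"cannot draw {n_runs} distinct orders of {n_tok} tokens"
        )
    rng = rng_for(seed, "design")
    orders, seen = [], set()
    while len(orders) < n_runs:
        perm = tuple(rng.permutation(n_tok))
        if n_runs > 1 and perm in seen:
            continue
        seen.add(perm)
        orders.append([tokens[j] for j in perm])
    return StimulusDesign(
        n_runs=n_runs,
        categories=categories,
        items_per_category=items_per_category,
        run_orders=orders,
        tr_s=tr_s,
        volumes_per_trial=volumes_per_trial,
        isi_s=isi_s,
        stimulus_volume_index=stimulus_volume_index,
    )


def make_ground_truth(
    grid: VoxelGrid,
    n_informative_per_category: int = 50,
    effect_size: float = 1.5,
    overlap_fraction: float = 0.0,
    seed: int = 0,
    categories=DEFAULT_CATEGORIES,
) -> GroundTruth:
    """Assign each category a sparse set of informative voxels.

    ``overlap_fraction`` of each category's voxels come from a single pool
    shared by all categories; the remainder are disjoint between categories.
    Templates take the value ``effect_size`` on informative voxels, 0
    elsewhere.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if n_informative_per_category < 0:
        raise ValueError("n_informative_per_category must be >= 0")
    categories = tuple(categories)
    K = len(categories)
    n_inf = int(n_informative_per_category)
    n_shared = int(round(overlap_fraction * n_inf))
    n_unique = n_inf - n_shared
    needed = n_shared + K * n_unique
    if needed > grid.p:
        raise ValueError(
            f"need {needed} informative voxels but mask has only {grid.p}"
        )
    rng = rng_for(seed, "truth")
    pool = rng.permutation(grid.p)
    shared = np.sort(pool[:n_shared])
    informative_sets, pattern_means = {}, {}
    off = n_shared
    for c in categories:
        unique = pool[off : off + n_unique]
        off += n_unique
        vox = np.sort(np.concatenate([shared, unique])).astype(int)
        informative_sets[c] = vox
        tpl = np.zeros(grid.p)
        tpl[vox] = effect_size
        pattern_means[c] = tpl
    return GroundTruth(
        informative_sets=informative_sets,
        pattern_means=pattern_means,
        effect_size=float(effect_size),
    )


def make_subjects(
    grid: VoxelGrid,
    n_subjects: int = 6,
    categories=DEFAULT_CATEGORIES,
    spatial_jitter_voxels: int = 1,
    gain_sd: float = 0.25,
    offset_sd: float = 0.1,
    seed: int = 0,
) -> list:
    """Draw per-subject perturbation models (jitter + gain + offset)."""
    if gain_sd < 0 or offset_sd < 0 or spatial_jitter_voxels < 0:
        raise ValueError("perturbation magnitudes must be >= 0")
    subjects = []
    for s in range(1, n_subjects + 1):
        rng = rng_for(seed, "subject", s)
        gain = 1.0 + gain_sd * rng.standard_normal(grid.p)
        offset = offset_sd * rng.standard_normal(grid.p)
        j = int(spatial_jitter_voxels)
        shifts = {
            c: tuple(rng.integers(-j, j + 1, size=3)) if j > 0 else (0, 0, 0)
            for c in categories
        }
        subjects.append(
            SubjectModel(
                subject_id=f"sub{s}",
                spatial_jitter_voxels=j,
                gain_field=gain,
                additive_offset=offset,
                shifts=shifts,
            )
        )
    return subjects


def _shift_template(grid: VoxelGrid, truth: GroundTruth, category, shift):
    """Category template displaced by an integer voxel shift.

    Displaced voxels falling outside the mask keep their original location
    (clipping at the mask boundary), so no signal is lost.
    """
    tpl = np.zeros(grid.p)
    if not any(shift):
        return truth.pattern_means[category].copy()
    coords = grid.coords()
    nx, ny, nz = grid.dims
    # flat-index lookup: position in column order, or -1 if outside mask
    flat_to_col = np.full(nx * ny * nz, -1, dtype=int)
    flat_to_col[grid.linear_indices] = np.arange(grid.p)
    amp = truth.effect_size
    for v in truth.informative_sets[category]:
        x, y, z = coords[v]
        tx = min(max(x + shift[0], 0), nx - 1)
        ty = min(max(y + shift[1], 0), ny - 1)
        tz = min(max(z + shift[2], 0), nz - 1)
        col = flat_to_col[tx + nx * (ty + ny * tz)]
        tpl[col if col >= 0 else v] += amp
    return tpl


def _subject_templates(grid, truth, subject):
    """Per-category subject-level mean patterns (jitter * gain + offset)."""
    return {
        c: _shift_template(grid, truth, c, subject.shifts.get(c, (0, 0, 0)))
        * subject.gain_field
        + subject.additive_offset
        for c in truth.pattern_means
    }


def _item_effects(design, truth, sigma_item, seed):
    """One fixed voxelwise effect per token, on the token's informative set."""
    effects = {}
    for c, i in design.tokens():
        delta = np.zeros(len(next(iter(truth.pattern_means.values()))))
        if sigma_item > 0:
            rng = rng_for(seed, "item", c, i)
            vox = truth.informative_sets[c]
            delta[vox] = sigma_item * rng.standard_normal(len(vox))
        effects[(c, i)] = delta
    return effects


def simulate_betas(
    design: StimulusDesign,
    truth: GroundTruth,
    subjects,
    sigma_item: float = 0.6,
    sigma_run: float = 0.3,
    sigma_noise: float = 1.0,
    seed: int = 0,
    grid: VoxelGrid = None,
) -> BetaDataset:
    """Generate per-stimulus response amplitudes for a list of subjects.

    Each sample is ``subject template(category) + item effect + run effect +
    thermal noise``.  Item effects (sd ``sigma_item`` on the category's
    informative voxels) are fixed per token across runs and subjects; run
    effects (sd ``sigma_run``, all voxels) are drawn per (subject, run);
    thermal noise (sd ``sigma_noise``) is iid per sample and voxel.
    """
    for name, sd in [
        ("sigma_item", sigma_item),
        ("sigma_run", sigma_run),
        ("sigma_noise", sigma_noise),
    ]:
        if sd < 0:
            raise ValueError(f"{name} must be >= 0, got {sd}")
    design.validate()
    if set(design.categories) - set(truth.pattern_means):
        raise ValueError("ground truth lacks templates for some categories")
    p = len(next(iter(truth.pattern_means.values())))
    if grid is not None and grid.p != p:
        raise ValueError("grid voxel count does not match templates")

    item_eff = _item_effects(design, truth, sigma_item, seed)
    rows, recs = [], []
    for subject in subjects:
        templates = _subject_templates_cached(grid, truth, subject, p)
        for r in range(design.n_runs):
            rng_run = rng_for(seed, "run_effect", subject.subject_id, r)
            run_eff = (
                sigma_run * rng_run.standard_normal(p) if sigma_run > 0 else 0.0
            )
            rng_noise = rng_for(seed, "noise", subject.subject_id, r)
            for c, i in design.run_orders[r]:
                x = templates[c] + item_eff[(c, i)] + run_eff
                if sigma_noise > 0:
                    x = x + sigma_noise * rng_noise.standard_normal(p)
                else:
                    x = x.copy()
                rows.append(x)
                recs.append(
                    {"subject": subject.subject_id, "run": r, "category": c, "item": i}
                )
    return BetaDataset(X=np.array(rows), labels=pd.DataFrame(recs), grid=grid)


def _subject_templates_cached(grid, truth, subject, p):
    if grid is None:
        # no geometry: jitter degenerates to identity
        return {
            c: truth.pattern_means[c] * subject.gain_field + subject.additive_offset
            for c in truth.pattern_means
        }
    return _subject_templates(grid, truth, subject)


def trial_amplitudes(
    design, truth, subject, run, sigma_item=0.0, sigma_run=0.0, seed=0, grid=None
) -> np.ndarray:
    """Trials x p generative response amplitudes for one (subject, run)."""
    p = len(next(iter(truth.pattern_means.values())))
    templates = _subject_templates_cached(grid, truth, subject, p)
    item_eff = _item_effects(design, truth, sigma_item, seed)
    rng_run = rng_for(seed, "run_effect", subject.subject_id, run)
    run_eff = sigma_run * rng_run.standard_normal(p) if sigma_run > 0 else 0.0
    amps = np.empty((design.trials_per_run, p))
    for t, (c, i) in enumerate(design.run_orders[run]):
        amps[t] = templates[c] + item_eff[(c, i)] + run_eff
    return amps


def simulate_bold(
    design: StimulusDesign,
    truth: GroundTruth,
    subject: SubjectModel,
    sigma_noise: float = 1.0,
    drift_amp: float = 0.0,
    seed: int = 0,
    *,
    sigma_item: float = 0.0,
    sigma_run: float = 0.0,
    grid: VoxelGrid = None,
    runs=None,
) -> BoldDataset:
    """Simulate BOLD time series for one subject under the slow design.

    Per voxel, the series is the sum over trials of ``amplitude *
    HRF(t - onset)`` sampled at the TR, plus a per-voxel linear drift (slope
    and intercept ~ N(0, drift_amp)) and iid Gaussian noise.  Amplitudes come
    from the same generative model as :func:`simulate_betas`.
    """
    if sigma_noise < 0 or drift_amp < 0:
        raise ValueError("sigma_noise and drift_amp must be >= 0")
    if design.tr_s <= 0 or design.isi_s <= 0 or design.volumes_per_trial < 1:
        raise ValueError("design timing fields must be positive")
    from .glm import canonical_hrf  # local import to avoid a cycle

    design.validate()
    runs = range(design.n_runs) if runs is None else runs
    n_vol = design.volumes_per_run
    t = np.arange(n_vol) * design.tr_s
    onsets = design.onsets_s()
    # volumes x trials HRF regressor matrix
    R = np.zeros((n_vol, design.trials_per_run))
    for k, onset in enumerate(onsets):
        dt = t - onset
        pos = dt >= 0
        R[pos, k] = canonical_hrf(dt[pos])

    series, amplitudes = {}, {}
    p = len(next(iter(truth.pattern_means.values())))
    t_norm = np.linspace(-1, 1, n_vol)[:, None]
    for r in runs:
        amps = trial_amplitudes(
            design, truth, subject, r,
            sigma_item=sigma_item, sigma_run=sigma_run, seed=seed, grid=grid,
        )
        data = R @ amps
        rng = rng_for(seed, "bold", subject.subject_id, r)
        if drift_amp > 0:
            c0 = drift_amp * rng.standard_normal(p)
            c1 = drift_amp * rng.standard_normal(p)
            data = data + c0[None, :] + t_norm * c1[None, :]
        if sigma_noise > 0:
            data = data + sigma_noise * rng.standard_normal((n_vol, p))
        key = (subject.subject_id, r)
        series[key] = data
        amplitudes[key] = amps
    return BoldDataset(
        series=series,
        design=design,
        amplitudes=amplitudes,
        noise_sd=sigma_noise,
        drift_amp=drift_amp,
    )
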