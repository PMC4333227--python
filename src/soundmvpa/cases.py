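"""The four decoding cases and the statistics used to compare them.

* **WithinSub** — per-subject decoding: 5 of the 7 runs train, 2 test,
  repeated with distinct random run splits.
* **AcrossSub** — leave-one-subject-out: the decoder trains on all runs of
  the remaining subjects and must generalize to a new brain.
* **AvgItem** — samples are first averaged over the items of each category
  within (subject, run), then decoded leave-one-subject-out; averaging
  removes item-level variance irrelevant to category membership.
* **AvgSub** — samples are averaged voxelwise over subjects and the
  "averaged subject" is decoded with the within-subject scheme.

Accuracies are compared against chance (1/K) with one-sample t tests and
between cases with pooled-variance two-sample t tests (Welch optional), the
conventions used for slow event-related decoding studies of this design.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_for
from .datasets import BetaDataset
from .msvmrfe import HyperParams, FitResult, evaluate, fit_msvm_rfe

__all__ = [
    "CASE_IDS",
    "SplitPlan",
    "CaseParams",
    "CaseResult",
    "StatTestResult",
    "plan_within_subject",
    "plan_across_subject",
    "average_over_items",
    "average_over_subjects",
    "run_case",
    "ttest_one_sample",
    "ttest_two_sample",
    "summarize_cases",
]

CASE_IDS = ("WithinSub", "AcrossSub", "AvgItem", "AvgSub")


@dataclass(eq=False)
class SplitPlan:
    """A family of train/test sample-index folds for one case."""

    case_id: str
    folds: list  # (train_idx, test_idx, description)
    n_repetitions: int

    def validate_disjoint(self):
        for train, test, _ in self.folds:
            if np.intersect1d(train, test).size:
                raise ValueError("train/test overlap within a fold")


@dataclass
class CaseParams:
    """Orchestration parameters shared by the four cases."""

    n_reps: int = 5
    n_train_runs: int = 5
    svm: HyperParams = field(default_factory=HyperParams)
    exclude_subjects: tuple = ()
    seed: int = 0
    keep_fits: bool = True


@dataclass(eq=False)
class CaseResult:
    """Per-fold accuracies and voxel selections for one case."""

    case_id: str
    accuracies: np.ndarray
    fold_keys: list  # (subject-or-"all", repetition) per fold
    selected_voxels: list
    fits: list = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


@dataclass
class StatTestResult:
    t: float
    df: float
    p: float
    n: int
    n2: int = None


def plan_within_subject(
    dataset: BetaDataset,
    subject,
    n_reps: int = 5,
    seed: int = 0,
    n_train_runs: int = 5,
) -> SplitPlan:
    """Random distinct train/test run partitions for one subject.

    Default 5 training / 2 test runs out of 7; ``n_reps`` distinct
    partitions are sampled without replacement from the C(runs, train)
    possibilities.
    """
    mask = (dataset.labels["subject"] == subject).to_numpy()
    if not mask.any():
        raise KeyError(f"subject {subject!r} not in dataset")
    runs = list(pd.unique(dataset.labels.loc[mask, "run"]))
    if len(runs) < 3:
        raise ValueError("within-subject splits need at least 3 runs")
    if not 1 <= n_train_runs < len(runs):
        raise ValueError("n_train_runs must leave at least one test run")
    combos = list(itertools.combinations(range(len(runs)), n_train_runs))
    if n_reps > len(combos):
        raise ValueError(
            f"requested {n_reps} distinct splits but only "
            f"C({len(runs)},{n_train_runs})={len(combos)} exist"
        )
    rng = rng_for(seed, "within_split", subject)
    chosen = rng.choice(len(combos), size=n_reps, replace=False)
    run_arr = dataset.labels["run"].to_numpy()
    idx_all = np.flatnonzero(mask)
    folds = []
    for rep, ci in enumerate(chosen):
        train_runs = {runs[k] for k in combos[ci]}
        in_train = np.isin(run_arr[idx_all], list(train_runs))
        folds.append(
            (
                idx_all[in_train],
                idx_all[~in_train],
                f"{subject}/rep{rep}:train_runs={sorted(train_runs)}",
            )
        )
    plan = SplitPlan(case_id="WithinSub", folds=folds, n_repetitions=n_reps)
    plan.validate_disjoint()
    return plan


def plan_across_subject(dataset: BetaDataset) -> SplitPlan:
    """Leave-one-subject-out: one fold per subject."""
    subjects = dataset.subjects()
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    subj_arr = dataset.labels["subject"].to_numpy()
    folds = []
    for s in subjects:
        test = np.flatnonzero(subj_arr == s)
        train = np.flatnonzero(subj_arr != s)
        folds.append((train, test, f"leave_{s}_out"))
    plan = SplitPlan(case_id="AcrossSub", folds=folds, n_repetitions=1)
    plan.validate_disjoint()
    return plan


def average_over_items(dataset: BetaDataset) -> BetaDataset:
    """Voxelwise mean over the items of each (subject, run, category).

    Every group must contain the dataset's full item set (strict); the item
    label of averaged samples becomes ``"avg"``.
    """
    labels = dataset.labels
    all_items = set(labels["item"].unique())
    rows, recs = [], []
    for (subject, run, category), g in labels.groupby(
        ["subject", "run", "category"], sort=False
    ):
        if set(g["item"]) != all_items or len(g) != len(all_items):
            raise ValueError(
                f"group {(subject, run, category)} does not contain every item"
            )
        rows.append(dataset.X[g.index.to_numpy()].mean(axis=0))
        recs.append(
            {"subject": subject, "run": run, "category": category, "item": "avg"}
        )
    return BetaDataset(X=np.array(rows), labels=pd.DataFrame(recs), grid=dataset.grid)


def average_over_subjects(dataset: BetaDataset) -> BetaDataset:
    """Voxelwise mean across subjects for matching (run, category, item).

    All subjects must share an identical design (same token in the same run
    exactly once); the subject label becomes ``"avg"``.
    """
    labels = dataset.labels
    n_subj = len(dataset.subjects())
    rows, recs = [], []
    for (run, category, item), g in labels.groupby(
        ["run", "category", "item"], sort=False
    ):
        if len(g) != n_subj or g["subject"].nunique() != n_subj:
            raise ValueError(
                f"token {(run, category, item)} not present exactly once per subject"
            )
        rows.append(dataset.X[g.index.to_numpy()].mean(axis=0))
        recs.append(
            {"subject": "avg", "run": run, "category": category, "item": item}
        )
    return BetaDataset(X=np.array(rows), labels=pd.DataFrame(recs), grid=dataset.grid)


def _run_plan(dataset, plan, params, fold_keys):
    accs, sels, fits = [], [], []
    for (train_idx, test_idx, _desc) in plan.folds:
        fit = fit_msvm_rfe(dataset.subset(train_idx), params.svm)
        res = evaluate(fit, dataset.subset(test_idx))
        accs.append(res.accuracy)
        sels.append(fit.selected_voxels)
        fits.append(fit if params.keep_fits else None)
    return accs, sels, fits


def run_case(dataset: BetaDataset, case_id: str, params: CaseParams = None) -> CaseResult:
    """Execute one of the four decoding cases end to end.

    Builds the case's split plan, fits MSVM-RFE per fold, and evaluates on
    the held-out samples.  ``params.exclude_subjects`` removes subjects
    before any split is formed.
    """
    params = params or CaseParams()
    if case_id not in CASE_IDS:
        raise ValueError(f"unknown case {case_id!r}; expected one of {CASE_IDS}")
    if params.exclude_subjects:
        keep = ~dataset.labels["subject"].isin(params.exclude_subjects).to_numpy()
        dataset = dataset.subset(np.flatnonzero(keep))

    accs, keys, sels, fits = [], [], [], []
    if case_id == "WithinSub":
        for s in dataset.subjects():
            plan = plan_within_subject(
                dataset, s, n_reps=params.n_reps, seed=params.seed,
                n_train_runs=params.n_train_runs,
            )
            a, v, f = _run_plan(dataset, plan, params, None)
            accs += a
            sels += v
            fits += f
            keys += [(s, rep) for rep in range(params.n_reps)]
    elif case_id in ("AcrossSub", "AvgItem"):
        data = average_over_items(dataset) if case_id == "AvgItem" else dataset
        plan = plan_across_subject(data)
        a, v, f = _run_plan(data, plan, params, None)
        accs, sels, fits = a, v, f
        keys = [(s, 0) for s in data.subjects()]
    else:  # AvgSub
        data = average_over_subjects(dataset)
        plan = plan_within_subject(
            data, "avg", n_reps=params.n_reps, seed=params.seed,
            n_train_runs=params.n_train_runs,
        )
        a, v, f = _run_plan(data, plan, params, None)
        accs, sels, fits = a, v, f
        keys = [("avg", rep) for rep in range(params.n_reps)]
    return CaseResult(
        case_id=case_id,
        accuracies=np.asarray(accs, dtype=float),
        fold_keys=keys,
        selected_voxels=sels,
        fits=fits if params.keep_fits else None,
    )


def ttest_one_sample(accs, mu0: float) -> StatTestResult:
    """Two-sided one-sample t test of mean accuracy against ``mu0``."""
    accs = np.asarray(accs, dtype=float)
    n = len(accs)
    if n < 2:
        raise ValueError("one-sample t test needs n >= 2")
    sd = accs.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(accs.mean())):
        raise ValueError("degenerate input: zero variance")
    t = (accs.mean() - mu0) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return StatTestResult(t=float(t), df=float(df), p=float(p), n=n)


def ttest_two_sample(accs1, accs2, welch: bool = False) -> StatTestResult:
    """Two-sided two-sample t test (pooled variance by default)."""
    a = np.asarray(accs1, dtype=float)
    b = np.asarray(accs2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two-sample t test needs n >= 2 in each group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate input: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return StatTestResult(
        t=float(res.statistic), df=df, p=float(res.pvalue), n=len(a), n2=len(b)
    )


def summarize_cases(results) -> tuple:
    """Summary table (one row per case) plus the pairwise comparisons.

    Emits WithinSub vs AcrossSub and AvgItem vs AcrossSub pooled-variance
    two-sample tests when both members are present.  Returns
    ``(table, comparisons)`` as DataFrames.
    """
    if not results:
        raise ValueError("no case results to summarize")
    by_id = {r.case_id: r for r in results}
    order = [c for c in CASE_IDS if c in by_id] + [
        c for c in by_id if c not in CASE_IDS
    ]
    table = pd.DataFrame(
        [
            {
                "case": c,
                "mean_accuracy": by_id[c].mean,
                "sd": by_id[c].sd,
                "n_folds": len(by_id[c].accuracies),
            }
            for c in order
        ]
    )
    comps = []
    for a, b in (("WithinSub", "AcrossSub"), ("AvgItem", "AcrossSub")):
        if a in by_id and b in by_id:
            try:
                r = ttest_two_sample(by_id[a].accuracies, by_id[b].accuracies)
                row = {"t": r.t, "df": r.df, "p": r.p, "n1": r.n, "n2": r.n2}
            except ValueError:
                # degenerate comparison (zero variance): report NaN statistics
                row = {
                    "t": float("nan"), "df": float("nan"), "p": float("nan"),
                    "n1": len(by_id[a].accuracies), "n2": len(by_id[b].accuracies),
                }
            comps.append({"case_a": a, "case_b": b, **row})
    return table, pd.DataFrame(comps)
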