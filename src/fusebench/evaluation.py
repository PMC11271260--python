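"""Repeated-split evaluation protocol, voting ensembles, model ranking and
permutation feature importance.

The protocol: draw ``n_repeats`` independent train/test partitions at
``train_fraction`` (75/25 by default, 50 repeats), fit the pipeline on each
training set, score test accuracy, and report the mean with a 95% confidence
interval on the mean of the split accuracies (normal approximation,
``mean +/- 1.96 * sd / sqrt(R)``; a percentile bootstrap is available as an
alternative). Two models are called significantly different (p < 0.05) when
their intervals do not overlap.

All pipelines and all ensemble members evaluated under one
:class:`SplitPlan` share the identical partitions per repeat, so comparisons
are paired and ensemble votes are well defined.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from ._errors import ConfigError, DataError
from .cohort import LabeledCohort, code_labels
from .fusion import FittedPipeline, PipelineSpec, fit_pipeline

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class SplitPlan:
    """Repeated random train/test split protocol."""

    train_fraction: float = 0.75
    n_repeats: int = 50
    base_seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )
        if self.n_repeats < 2:
            raise ConfigError(f"n_repeats must be >= 2, got {self.n_repeats}")


@dataclass
class EvalResult:
    """Aggregated repeated-split accuracies for one model."""

    name: str
    task: str
    per_split_accuracies: np.ndarray
    mean_accuracy: float
    ci_low: float
    ci_high: float
    plan: SplitPlan | None = None
    extras: dict = field(default_factory=dict)

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low

    def summary(self) -> str:
        r = len(self.per_split_accuracies)
        return (
            f"{self.name}: mean accuracy {self.mean_accuracy:.3f} "
            f"(95% CI {self.ci_low:.3f}, {self.ci_high:.3f}; {r} splits)"
        )


@dataclass
class EnsembleSpec:
    """Majority-vote ensemble over pipelines sharing one task and inputs."""

    members: list[PipelineSpec]
    name: str

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ConfigError("an ensemble needs >= 2 members")
        tasks = {m.task for m in self.members}
        if len(tasks) != 1:
            raise ConfigError(f"ensemble members must share one task, got {tasks}")
        inputs = {tuple(sorted(m.modality_names)) for m in self.members}
        if len(inputs) != 1:
            raise ConfigError("ensemble members must share modality inputs")

    @property
    def task(self) -> str:
        return self.members[0].task


@dataclass
class ImportanceReport:
    """Permutation importances attached to raw, named input features."""

    table: pd.DataFrame  # feature, modality, mean_importance, sd, rank
    baseline_accuracy: float
    n_perm: int

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.head(k)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def _split_seed(base_seed: int, repeat: int, attempt: int = 0) -> int:
    ss = np.random.SeedSequence([int(base_seed) % (2**31), repeat, attempt])
    return int(ss.generate_state(1)[0] % (2**31))


def make_splits(plan: SplitPlan, labels) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw the plan's train/test partitions, reproducibly from base_seed.

    Stratification uses the full 3-class diagnosis so binary and multiclass
    models see the same partitions. Without stratification, a draw whose
    training set misses a class is logged and redrawn.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    classes = np.unique(labels)
    idx = np.arange(n)
    splits = []
    for r in range(plan.n_repeats):
        for attempt in range(100):
            seed = _split_seed(plan.base_seed, r, attempt)
            tr, te = train_test_split(
                idx,
                train_size=plan.train_fraction,
                random_state=seed,
                shuffle=True,
                stratify=labels if plan.stratified else None,
            )
            if plan.stratified or len(np.unique(labels[tr])) == len(classes):
                break
            logger.warning(
                "repeat %d: training split missing a class; redrawing", r
            )
        splits.append((np.sort(tr), np.sort(te)))
    return splits


# ---------------------------------------------------------------------------
# Confidence intervals and comparisons
# ---------------------------------------------------------------------------

def confidence_interval(
    accs, method: str = "normal", n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """95% CI for the mean of split accuracies, clipped to [0, 1].

    ``normal``: mean +/- 1.96 * sd / sqrt(R) with the sample sd (ddof=1).
    ``bootstrap``: percentile interval of the resampled mean.
    """
    accs = np.asarray(accs, dtype=float)
    if accs.size < 2:
        raise DataError(f"need >= 2 accuracies for a CI, got {accs.size}")
    mean = float(accs.mean())
    if method == "normal":
        sd = accs.std(ddof=1)
        half = 0.0 if sd < 1e-12 else _Z95 * sd / np.sqrt(accs.size)
        lo, hi = mean - half, mean + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = rng.choice(accs, size=(n_boot, accs.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        raise ConfigError(f"unknown CI method {method!r}")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def significantly_different(a: EvalResult, b: EvalResult) -> bool:
    """True iff the two 95% CIs do not overlap (p < 0.05 convention)."""
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low


# ---------------------------------------------------------------------------
# Repeated-split evaluation
# ---------------------------------------------------------------------------

def _aggregate(name, task, accs, plan, ci_method="normal", **extras) -> EvalResult:
    accs = np.asarray(accs, dtype=float)
    lo, hi = confidence_interval(accs, method=ci_method)
    return EvalResult(
        name=name,
        task=task,
        per_split_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        ci_low=lo,
        ci_high=hi,
        plan=plan,
        extras=extras,
    )


def repeated_split_evaluate(
    spec: PipelineSpec,
    cohort: LabeledCohort,
    plan: SplitPlan,
    splits: list | None = None,
    ci_method: str = "normal",
) -> EvalResult:
    """Fit/score one pipeline over the plan's repeated partitions."""
    if splits is None:
        splits = make_splits(plan, cohort.labels)
    y_all = code_labels(cohort.labels, spec.task)
    accs = []
    for r, (tr, te) in enumerate(splits):
        fitted = fit_pipeline(spec, cohort, tr, seed=_split_seed(spec.seed, r))
        pred = fitted.predict(cohort, te)
        accs.append(float(np.mean(pred == y_all[te])))
    return _aggregate(spec.name, spec.task, accs, plan, ci_method)


# ---------------------------------------------------------------------------
# Voting ensembles
# ---------------------------------------------------------------------------

def majority_vote(
    member_predictions: np.ndarray,
    task: str,
    train_class_counts: np.ndarray | None = None,
) -> np.ndarray:
    """Per-subject modal label over ensemble members.

    Ties are broken by training-set class prevalence (higher wins), then by
    label order (HC < MCI < AD).
    """
    preds = np.asarray(member_predictions)
    if preds.ndim != 2 or preds.shape[0] < 2:
        raise DataError("member_predictions must be (n_members >= 2) x n_subjects")
    n_classes = 2 if task == "binary" else 3
    if train_class_counts is None:
        train_class_counts = np.zeros(n_classes)
    out = np.empty(preds.shape[1], dtype=int)
    for j in range(preds.shape[1]):
        votes = np.bincount(preds[:, j], minlength=n_classes)
        best = votes.max()
        cand = np.flatnonzero(votes == best)
        if cand.size > 1:
            prev = train_class_counts[cand]
            cand = cand[prev == prev.max()]
        out[j] = int(cand[0])
    return out


def evaluate_ensemble(
    spec: EnsembleSpec,
    cohort: LabeledCohort,
    plan: SplitPlan,
    splits: list | None = None,
    ci_method: str = "normal",
) -> EvalResult:
    """Majority-vote accuracy over repeats; members share each split."""
    if splits is None:
        splits = make_splits(plan, cohort.labels)
    y_all = code_labels(cohort.labels, spec.task)
    accs = []
    split_fingerprints = []
    for r, (tr, te) in enumerate(splits):
        preds = []
        counts = None
        for member in spec.members:
            fitted = fit_pipeline(member, cohort, tr, seed=_split_seed(member.seed, r))
            preds.append(fitted.predict(cohort, te))
            counts = fitted.train_class_counts
        vote = majority_vote(np.asarray(preds), spec.task, counts)
        accs.append(float(np.mean(vote == y_all[te])))
        split_fingerprints.append(int(np.sum(tr) % (2**31)))
    return _aggregate(
        spec.name, spec.task, accs, plan, ci_method,
        split_fingerprints=split_fingerprints, n_members=len(spec.members),
    )


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_models(results: list[EvalResult], top_k: int | None = None) -> list[EvalResult]:
    """Descending mean accuracy; ties by narrower CI, then by name."""
    if not results:
        raise DataError("no results to rank")
    ranked = sorted(results, key=lambda r: (-r.mean_accuracy, r.ci_width, r.name))
    return ranked if top_k is None else ranked[:top_k]


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------

def permutation_importance(
    pipeline: FittedPipeline,
    cohort: LabeledCohort,
    test_index,
    n_perm: int = 10,
    seed: int = 0,
) -> ImportanceReport:
    """Mean test-accuracy drop from shuffling each raw feature column.

    Columns are permuted on the raw, pre-standardization inputs, so the
    importances attach to the original named features of each modality; a
    feature that never influences the fitted model scores exactly zero.
    """
    if n_perm < 1:
        raise ConfigError(f"n_perm must be >= 1, got {n_perm}")
    test_index = np.asarray(test_index)
    y = code_labels(cohort.labels, pipeline.spec.task)[test_index]
    mats = {
        m: cohort.X(m)[test_index].copy() for m in pipeline.spec.modality_names
    }
    baseline = float(np.mean(pipeline.predict_arrays(mats) == y))
    rows = []
    feat_counter = 0
    for m in pipeline.spec.modality_names:
        names = pipeline.feature_names[m]
        X = mats[m]
        for j, fname in enumerate(names):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed) % (2**31), feat_counter])
            )
            drops = []
            col = X[:, j].copy()
            for _ in range(n_perm):
                X[:, j] = col[rng.permutation(col.size)]
                acc = float(np.mean(pipeline.predict_arrays(mats) == y))
                drops.append(baseline - acc)
            X[:, j] = col
            drops = np.asarray(drops)
            rows.append(
                {
                    "feature": fname,
                    "modality": m,
                    "mean_importance": float(drops.mean()),
                    "sd": float(drops.std(ddof=1)) if n_perm > 1 else 0.0,
                }
            )
            feat_counter += 1
    table = pd.DataFrame(rows).sort_values(
        ["mean_importance", "feature"], ascending=[False, True], kind="stable"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return ImportanceReport(
        table=table.reset_index(drop=True), baseline_accuracy=baseline, n_perm=n_perm
    )


# ---------------------------------------------------------------------------
# Benchmark driver and CSV reports
# ---------------------------------------------------------------------------

def run_benchmark(
    cohort: LabeledCohort,
    specs: list[PipelineSpec],
    ensembles: list[tuple[str, list[PipelineSpec]]] | list[EnsembleSpec],
    plan: SplitPlan,
    ci_method: str = "normal",
) -> dict:
    """Evaluate a model grid plus its ensembles on shared splits.

    Every pipeline and ensemble member sees the identical partition per
    repeat, so each model is fitted once per repeat and its per-split test
    predictions are reused for the ensemble votes. Returns a dict with
    ``results`` (list of EvalResult, models then ensembles),
    ``results_frame``, ``comparisons_frame`` and ``ranked``. Deterministic
    given (cohort, specs, plan).
    """
    splits = make_splits(plan, cohort.labels)
    y_by_task = {t: code_labels(cohort.labels, t) for t in ("binary", "multiclass")}

    # fit each model once per repeat; cache test predictions for ensembles
    preds: dict[str, list[np.ndarray]] = {}
    counts: dict[str, list[np.ndarray]] = {}
    results = []
    for s in specs:
        preds[s.name], counts[s.name], accs = [], [], []
        y_all = y_by_task[s.task]
        for r, (tr, te) in enumerate(splits):
            fitted = fit_pipeline(s, cohort, tr, seed=_split_seed(s.seed, r))
            p = fitted.predict(cohort, te)
            preds[s.name].append(p)
            counts[s.name].append(fitted.train_class_counts)
            accs.append(float(np.mean(p == y_all[te])))
        results.append(_aggregate(s.name, s.task, accs, plan, ci_method))

    for ens in ensembles:
        espec = ens if isinstance(ens, EnsembleSpec) else EnsembleSpec(
            members=list(ens[1]), name=ens[0]
        )
        y_all = y_by_task[espec.task]
        accs = []
        for r, (tr, te) in enumerate(splits):
            member_preds = np.asarray([preds[m.name][r] for m in espec.members])
            vote = majority_vote(
                member_preds, espec.task, counts[espec.members[0].name][r]
            )
            accs.append(float(np.mean(vote == y_all[te])))
        results.append(
            _aggregate(espec.name, espec.task, accs, plan, ci_method,
                       n_members=len(espec.members))
        )
    return {
        "results": results,
        "results_frame": results_frame(results, specs),
        "comparisons_frame": comparisons_frame(results),
        "ranked": rank_models(results, top_k=10),
    }


def results_frame(results: list[EvalResult], specs: list[PipelineSpec] | None = None) -> pd.DataFrame:
    """One row per model: topology, DR, classifier, task, mean, CI."""
    by_name = {s.name: s for s in (specs or [])}
    rows = []
    for r in results:
        s = by_name.get(r.name)
        if s is not None:
            if s.reducers is None:
                dr = "none"
            elif hasattr(s.reducers, "method"):
                dr = s.reducers.method
            else:
                dr = next(iter(s.reducers.values())).method
            topology, classifier = s.topology, s.classifier
        else:
            topology, dr, classifier = "ensemble", "vote", "vote"
        rows.append(
            {
                "name": r.name,
                "topology": topology,
                "reducer": dr,
                "classifier": classifier,
                "task": r.task,
                "mean_accuracy": r.mean_accuracy,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
        )
    return pd.DataFrame(rows)


def comparisons_frame(results: list[EvalResult]) -> pd.DataFrame:
    """Pairwise CI non-overlap flags within each task."""
    rows = []
    for a, b in itertools.combinations(results, 2):
        if a.task != b.task:
            continue
        rows.append(
            {
                "model_a": a.name,
                "model_b": b.name,
                "task": a.task,
                "significant": significantly_different(a, b),
            }
        )
    return pd.DataFrame(rows)


def importance_frame(report: ImportanceReport) -> pd.DataFrame:
    return report.table[["feature", "modality", "mean_importance", "sd", "rank"]]
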