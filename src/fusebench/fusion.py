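"""End-to-end fusion pipelines: topology + reducer(s) + classifier.

Four topologies over one or more modality blocks:

* ``single``       — one modality, optionally reduced, then classified
                     (no reducer covers the low-dimensional degenerate case);
* ``simple``       — concatenate raw modality features, classify (no DR);
* ``early``        — concatenate raw features, fit ONE reducer on the
                     concatenation, classify its output;
* ``intermediate`` — fit one reducer per modality on that modality alone,
                     concatenate the reduced blocks, classify.

The classifier input is always re-standardized jointly (moments fitted on the
training rows) so no block's scale can dominate. Binary tasks use an
L2-regularized logistic regression; multiclass tasks use a random forest or a
feed-forward neural network. All fitting is restricted to the given training
rows; prediction applies the stored moments/reducers and never refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from ._errors import ConfigError, DataError
from .cohort import LabeledCohort, code_labels
from .dimred import FittedReducer, ReducerSpec, Standardizer, fit_reducer

TOPOLOGIES = ("single", "simple", "early", "intermediate")
CLASSIFIERS = ("logistic", "random_forest", "neural_net")
TASKS = ("binary", "multiclass")


def _child_seed(base: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(base) % (2**31), *[int(k) % (2**31) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineSpec:
    """Declarative description of one fusion pipeline.

    ``reducers`` is ``None`` (simple topology, or single without DR), a single
    :class:`ReducerSpec` (single / early; also accepted for intermediate,
    where it is replicated per modality), or a dict mapping modality name to
    its own spec (intermediate).
    """

    topology: str
    modality_names: tuple[str, ...]
    classifier: str
    task: str
    reducers: ReducerSpec | dict | None = None
    classifier_params: dict = field(default_factory=dict)
    seed: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        self.modality_names = tuple(self.modality_names)
        if self.topology not in TOPOLOGIES:
            raise ConfigError(f"unknown topology {self.topology!r}")
        if self.classifier not in CLASSIFIERS:
            raise ConfigError(f"unknown classifier {self.classifier!r}")
        if self.task not in TASKS:
            raise ConfigError(f"unknown task {self.task!r}")
        if self.task == "binary" and self.classifier != "logistic":
            raise ConfigError("binary task requires the logistic classifier")
        if self.task == "multiclass" and self.classifier == "logistic":
            raise ConfigError(
                "multiclass task requires random_forest or neural_net"
            )
        if self.topology == "single" and len(self.modality_names) != 1:
            raise ConfigError("single topology takes exactly one modality")
        if self.topology in ("simple", "early") and len(self.modality_names) < 2:
            raise ConfigError(f"{self.topology} fusion needs >= 2 modalities")
        if self.topology == "intermediate" and len(self.modality_names) < 1:
            raise ConfigError("intermediate fusion needs >= 1 modality")
        if self.topology == "simple" and self.reducers is not None:
            raise ConfigError("simple fusion takes no reducer")
        if self.topology in ("early",) and not isinstance(self.reducers, ReducerSpec):
            raise ConfigError("early fusion needs exactly one ReducerSpec")
        if self.topology == "intermediate":
            if isinstance(self.reducers, ReducerSpec):
                self.reducers = {m: self.reducers for m in self.modality_names}
            if not isinstance(self.reducers, dict) or set(self.reducers) != set(
                self.modality_names
            ):
                raise ConfigError(
                    "intermediate fusion needs one ReducerSpec per modality"
                )
        if self.topology == "single" and isinstance(self.reducers, dict):
            raise ConfigError("single topology takes at most one ReducerSpec")

    @property
    def name(self) -> str:
        if self.label is not None:
            return self.label
        if self.reducers is None:
            dr = "none"
        elif isinstance(self.reducers, ReducerSpec):
            dr = self.reducers.method
        else:
            dr = next(iter(self.reducers.values())).method
        mods = "+".join(self.modality_names)
        return f"{self.topology}[{mods}]|{dr}|{self.classifier}|{self.task}"


def _make_classifier(spec: PipelineSpec, seed: int):
    params = dict(spec.classifier_params)
    if spec.classifier == "logistic":
        kw = dict(C=1.0, max_iter=5000, random_state=seed)  # ridge-penalized
        kw.update(params)
        return LogisticRegression(**kw)
    if spec.classifier == "random_forest":
        kw = dict(n_estimators=500, random_state=seed, n_jobs=1)
        kw.update(params)
        return RandomForestClassifier(**kw)
    kw = dict(
        hidden_layer_sizes=(64, 32),
        activation="relu",
        solver="adam",
        max_iter=300,
        early_stopping=True,
        validation_fraction=0.1,
        n_iter_no_change=10,
        random_state=seed,
    )
    kw.update(params)
    return MLPClassifier(**kw)


@dataclass
class FittedPipeline:
    """A fitted end-to-end predictor with its bookkeeping.

    ``feature_names`` records, per modality, the training column order (the
    contract for prediction inputs); ``block_slices`` maps each modality to
    its column range in the classifier input.
    """

    spec: PipelineSpec
    reducers: dict[str, FittedReducer | None]
    scaler: Standardizer
    classifier: object
    feature_names: dict[str, list[str]]
    block_slices: dict[str, slice]
    train_class_counts: np.ndarray

    def _assemble(self, mats: dict[str, np.ndarray]) -> np.ndarray:
        missing = [m for m in self.spec.modality_names if m not in mats]
        if missing:
            raise DataError(f"missing modalities for prediction: {missing}")
        if self.spec.topology in ("simple",):
            blocks = [np.asarray(mats[m], float) for m in self.spec.modality_names]
            return np.concatenate(blocks, axis=1)
        if self.spec.topology == "early":
            Xc = np.concatenate(
                [np.asarray(mats[m], float) for m in self.spec.modality_names], axis=1
            )
            return self.reducers["__early__"].transform(Xc)
        # single / intermediate: per-modality reduce then concatenate
        blocks = []
        for m in self.spec.modality_names:
            X = np.asarray(mats[m], float)
            red = self.reducers.get(m)
            blocks.append(X if red is None else red.transform(X))
        return np.concatenate(blocks, axis=1)

    def predict_arrays(self, mats: dict[str, np.ndarray]) -> np.ndarray:
        """Predict coded labels from raw per-modality matrices."""
        Z = self.scaler.transform(self._assemble(mats))
        return self.classifier.predict(Z)

    def predict(self, cohort: LabeledCohort, index) -> np.ndarray:
        index = np.asarray(index)
        mats = {m: cohort.X(m)[index] for m in self.spec.modality_names}
        return self.predict_arrays(mats)


def fit_pipeline(
    spec: PipelineSpec, cohort: LabeledCohort, train_index, seed: int | None = None
) -> FittedPipeline:
    """Fit a pipeline on the training rows of a cohort.

    ``seed`` overrides ``spec.seed`` (used by the repeated-split protocol to
    re-initialize the stochastic components per repeat); reducer and
    classifier seeds are derived deterministically from it.
    """
    for m in spec.modality_names:
        if m not in cohort.modalities:
            raise ConfigError(f"cohort has no modality {m!r}")
    train_index = np.asarray(train_index)
    if train_index.size == 0:
        raise DataError("empty training index")
    base = spec.seed if seed is None else seed
    y = code_labels(cohort.labels, spec.task)[train_index]
    mats = {m: cohort.X(m)[train_index] for m in spec.modality_names}

    reducers: dict[str, FittedReducer | None] = {}
    feature_names = {m: cohort.modalities[m].feature_names for m in spec.modality_names}

    if spec.topology == "early":
        Xc = np.concatenate([mats[m] for m in spec.modality_names], axis=1)
        rspec = _reseed(spec.reducers, _child_seed(base, 0))
        reducers["__early__"] = fit_reducer(rspec, Xc, y)
    elif spec.topology in ("single", "intermediate"):
        for k, m in enumerate(spec.modality_names):
            rs = spec.reducers if isinstance(spec.reducers, ReducerSpec) else (
                None if spec.reducers is None else spec.reducers[m]
            )
            if rs is None:
                reducers[m] = None
            else:
                reducers[m] = fit_reducer(_reseed(rs, _child_seed(base, k)), mats[m], y)

    # assemble training representation, then joint re-standardization
    proto = FittedPipeline(
        spec=spec, reducers=reducers, scaler=None, classifier=None,  # type: ignore
        feature_names=feature_names, block_slices={}, train_class_counts=None,  # type: ignore
    )
    Z = proto._assemble(mats)
    scaler = Standardizer.fit(Z)
    clf = _make_classifier(spec, _child_seed(base, 1000))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(scaler.transform(Z), y)

    # block bookkeeping for reports
    slices = {}
    off = 0
    if spec.topology == "early":
        slices["__early__"] = slice(0, Z.shape[1])
    else:
        for m in spec.modality_names:
            red = reducers.get(m)
            width = mats[m].shape[1] if (red is None or spec.topology == "simple") \
                else red.output_dim
            slices[m] = slice(off, off + width)
            off += width

    n_classes = 2 if spec.task == "binary" else 3
    counts = np.bincount(y, minlength=n_classes)
    return FittedPipeline(
        spec=spec,
        reducers=reducers,
        scaler=scaler,
        classifier=clf,
        feature_names=feature_names,
        block_slices=slices,
        train_class_counts=counts,
    )


def _reseed(rspec: ReducerSpec, seed: int) -> ReducerSpec:
    d = rspec.to_dict()
    d["seed"] = seed
    return ReducerSpec.from_dict(d)


# ---------------------------------------------------------------------------
# The standard benchmark grid
# ---------------------------------------------------------------------------

def standard_grid(
    modality_names: tuple[str, str] = ("clinical", "imaging"),
    lambda_grid=(),
    seed: int = 0,
    classifier_params: dict | None = None,
    reducer_overrides: dict | None = None,
):
    """Enumerate the full benchmark grid and its voting ensembles.

    Per single-modality group and per fusion group (early, intermediate):
    4 DR methods x {binary logistic, multiclass RF, multiclass NN} = 12
    models; simple fusion adds its 3 no-DR models — 51 models in total.
    Ensembles: per group a binary ensemble (the 4 DR variants) and a
    multiclass ensemble (the 8 DR x classifier variants); simple fusion has a
    single binary model, hence only its 2-member multiclass ensemble.

    Returns ``(pipeline_specs, ensemble_specs)`` where each ensemble spec is a
    ``(name, [PipelineSpec, ...])`` pair.
    """
    classifier_params = classifier_params or {}
    reducer_overrides = reducer_overrides or {}

    def make_reducer(method: str) -> ReducerSpec:
        kw = dict(reducer_overrides.get(method, {}))
        if method == "pca":
            return ReducerSpec.pca(**{"n_components": 8, **kw, "seed": seed})
        if method == "ae":
            return ReducerSpec.ae(**{**kw, "seed": seed})
        if method == "lasso":
            return ReducerSpec.lasso(lambda_grid=lambda_grid, seed=seed)
        return ReducerSpec.se(**{**kw, "seed": seed})

    tasks = [("binary", "logistic"), ("multiclass", "random_forest"),
             ("multiclass", "neural_net")]
    groups: list[tuple[str, str, tuple[str, ...]]] = [
        (m, "single", (m,)) for m in modality_names
    ] + [
        ("simple", "simple", tuple(modality_names)),
        ("early", "early", tuple(modality_names)),
        ("intermediate", "intermediate", tuple(modality_names)),
    ]
    specs: list[PipelineSpec] = []
    ensembles: list[tuple[str, list[PipelineSpec]]] = []
    for gname, topology, mods in groups:
        members_by_task: dict[str, list[PipelineSpec]] = {"binary": [], "multiclass": []}
        if topology == "simple":
            dr_list = [None]
        else:
            dr_list = ["pca", "ae", "lasso", "se"]
        for dr in dr_list:
            for task, clf in tasks:
                reducers = None if dr is None else make_reducer(dr)
                label = f"{gname}|{dr or 'none'}|{clf}|{task}"
                ps = PipelineSpec(
                    topology=topology,
                    modality_names=mods,
                    classifier=clf,
                    task=task,
                    reducers=reducers,
                    classifier_params=classifier_params.get(clf, {}),
                    seed=seed,
                    label=label,
                )
                specs.append(ps)
                members_by_task[task].append(ps)
        for task, members in members_by_task.items():
            if len(members) >= 2:
                ensembles.append((f"{gname}|ensemble|{task}", members))
    return specs, ensembles
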