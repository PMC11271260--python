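"""Four dimensionality-reduction methods under one fit/transform contract.

* **PCA** — orthonormal loadings maximizing successive projected variances on
  the standardized training matrix; transform returns the top-``q`` scores.
* **LASSO selection** — the l1-penalized regression ``(1/2n)||y - Xw||^2 +
  lambda ||w||_1`` with ``lambda`` tuned by 5-fold cross-validation on the
  training split; the transform *selects* the columns with nonzero
  coefficients (supervised feature selection), returning them unmodified.
* **Denoising autoencoder (AE)** — a five-layer ReLU network (encoder hidden
  layer, bottleneck, decoder hidden layer) trained to reconstruct the clean
  standardized matrix from Gaussian-corrupted inputs; the transform is the
  bottleneck activation. Unsupervised: labels are never consulted.
* **Supervised encoder (SE)** — a feed-forward classifier whose last hidden
  layer is a narrow bottleneck; after training, the classification head is
  discarded and the bottleneck activations are the learned supervised
  low-dimensional representation.

All methods z-score the input using moments fitted on the training split only;
held-out transforms reuse those moments and never refit anything. Network
training uses Adam with an optional early-stopping carve-out of 10% of the
training rows; all randomness is driven by the spec's seed, so repeated fits
are bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import KFold
from sklearn.decomposition import PCA as _SkPCA
from sklearn.neural_network import MLPClassifier, MLPRegressor

from ._errors import ConfigError, DataError

_SERIAL_VERSION = 1

#: Method-specific default bottleneck / component counts.
DEFAULT_COMPONENTS = {"pca": 8, "ae": 4, "se": 10}


@dataclass
class ReducerSpec:
    """Choice of DR method plus its hyperparameters.

    ``n_components`` is the number of retained scores (PCA) or the bottleneck
    width (AE / SE); it is ignored for LASSO, whose output width is the number
    of selected features. ``hidden_widths`` are the dense ReLU layers before
    the bottleneck (SE) or the single encoder/decoder hidden width (AE).
    """

    method: str = "pca"
    n_components: int = 8
    lambda_grid: tuple[float, ...] = ()
    noise_sd: float = 0.1
    hidden_widths: tuple[int, ...] = (64, 32)
    epochs: int = 200
    learning_rate: float = 1e-3
    early_stopping: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("pca", "ae", "lasso", "se"):
            raise ConfigError(f"unknown DR method {self.method!r}")
        self.lambda_grid = tuple(float(x) for x in self.lambda_grid)
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if self.method == "lasso" and not self.lambda_grid:
            self.lambda_grid = tuple(np.logspace(-3, 0, 20))
        if self.n_components < 1:
            raise ConfigError(f"n_components must be >= 1, got {self.n_components}")

    # Convenience constructors with the field's default widths.
    @classmethod
    def pca(cls, n_components: int = 8, seed: int = 0) -> "ReducerSpec":
        return cls(method="pca", n_components=n_components, seed=seed)

    @classmethod
    def lasso(cls, lambda_grid=(), seed: int = 0) -> "ReducerSpec":
        return cls(method="lasso", n_components=1, lambda_grid=tuple(lambda_grid),
                   seed=seed)

    @classmethod
    def ae(cls, n_components: int = 4, hidden: int = 32, noise_sd: float = 0.1,
           epochs: int = 200, learning_rate: float = 1e-3, early_stopping: bool = True,
           seed: int = 0) -> "ReducerSpec":
        return cls(method="ae", n_components=n_components, hidden_widths=(hidden,),
                   noise_sd=noise_sd, epochs=epochs, learning_rate=learning_rate,
                   early_stopping=early_stopping, seed=seed)

    @classmethod
    def se(cls, n_components: int = 10, hidden_widths=(64, 32), epochs: int = 200,
           learning_rate: float = 1e-3, early_stopping: bool = True,
           seed: int = 0) -> "ReducerSpec":
        return cls(method="se", n_components=n_components,
                   hidden_widths=tuple(hidden_widths), epochs=epochs,
                   learning_rate=learning_rate, early_stopping=early_stopping,
                   seed=seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReducerSpec":
        return cls(**d)


@dataclass
class Standardizer:
    """Per-column z-scoring moments fitted on training data.

    Constant training columns get a unit divisor so they map to exactly zero.
    """

    mean_: np.ndarray
    scale_: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        return cls(mean_=mean, scale_=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


@dataclass
class FittedReducer:
    """A fitted DR transform with a fixed output dimension.

    ``params`` is method-specific: PCA loadings and spectra, the LASSO
    selected-index set and coefficients, or the encoder weight stack for the
    neural methods. ``transform`` maps an ``n x p`` matrix (same features and
    order as training) to ``n x output_dim``.
    """

    method: str
    spec: ReducerSpec
    n_features_in: int
    output_dim: int
    scaler: Standardizer
    params: dict = field(default_factory=dict)

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim != 2 or X_new.shape[1] != self.n_features_in:
            raise DataError(
                f"{self.method} reducer expects {self.n_features_in} features, "
                f"got shape {X_new.shape}"
            )
        if self.method == "lasso":
            # selection semantics: raw columns, untouched
            return X_new[:, self.params["selected"]]
        Z = self.scaler.transform(X_new)
        if self.method == "pca":
            return Z @ self.params["components"].T
        # neural encoders: ReLU forward pass through the stored stack
        A = Z
        for W, b in zip(self.params["weights"], self.params["biases"]):
            A = np.maximum(A @ W + b, 0.0)
        return A

    # -- serialization --------------------------------------------------------
    def save(self, path) -> None:
        def enc(v):
            if isinstance(v, np.ndarray):
                return {"__nd__": True, "data": v.tolist(), "shape": list(v.shape)}
            if isinstance(v, list):
                return [enc(x) for x in v]
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            return v

        payload = {
            "version": _SERIAL_VERSION,
            "method": self.method,
            "spec": self.spec.to_dict(),
            "n_features_in": self.n_features_in,
            "output_dim": self.output_dim,
            "scaler": {"mean": enc(self.scaler.mean_), "scale": enc(self.scaler.scale_)},
            "params": {k: enc(v) for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "FittedReducer":
        payload = json.loads(Path(path).read_text())
        if payload.get("version") != _SERIAL_VERSION:
            raise DataError(
                f"unsupported reducer file version {payload.get('version')!r}"
            )

        def dec(v):
            if isinstance(v, dict) and v.get("__nd__"):
                return np.asarray(v["data"], dtype=float).reshape(v["shape"])
            if isinstance(v, list):
                return [dec(x) for x in v]
            return v

        params = {k: dec(v) for k, v in payload["params"].items()}
        if "selected" in params:
            params["selected"] = np.asarray(params["selected"], dtype=int)
        return cls(
            method=payload["method"],
            spec=ReducerSpec.from_dict(payload["spec"]),
            n_features_in=payload["n_features_in"],
            output_dim=payload["output_dim"],
            scaler=Standardizer(
                mean_=dec(payload["scaler"]["mean"]),
                scale_=dec(payload["scaler"]["scale"]),
            ),
            params=params,
        )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading positive."""
    out = components.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] *= -1.0
    return out


def fit_pca(X: np.ndarray, q: int = 8, seed: int = 0) -> FittedReducer:
    """Principal components of the standardized training matrix.

    Loadings are mutually orthonormal; the k-th score ``X w_k`` has the k-th
    largest projected variance. Explained-variance ratios are exposed in
    ``params["explained_variance_ratio"]`` for scree/knee inspection.
    """
    X = np.asarray(X, dtype=float)
    scaler = Standardizer.fit(X)
    Z = scaler.transform(X)
    rank = np.linalg.matrix_rank(Z)
    if q > rank:
        raise DataError(f"q={q} exceeds the rank of the training matrix ({rank})")
    pca = _SkPCA(n_components=q, svd_solver="full")
    pca.fit(Z)
    components = _fix_signs(pca.components_)
    return FittedReducer(
        method="pca",
        spec=ReducerSpec.pca(n_components=q, seed=seed),
        n_features_in=X.shape[1],
        output_dim=q,
        scaler=scaler,
        params={
            "components": components,
            "explained_variance": pca.explained_variance_.copy(),
            "explained_variance_ratio": pca.explained_variance_ratio_.copy(),
        },
    )


def choose_components_knee(explained_variance_ratios) -> int:
    """Knee of the cumulative explained-variance curve.

    Maximum perpendicular distance to the chord joining the origin (zero
    components explain zero variance) to the curve's last point — the
    scree-plot elbow rule. Degenerate flat curves, which lie exactly on the
    chord, return 1 by convention. Result is clipped to [1, len(ratios)].
    """
    r = np.asarray(explained_variance_ratios, dtype=float)
    if r.size == 0:
        raise DataError("empty ratio sequence")
    if r.size == 1:
        return 1
    c = np.cumsum(r)
    x = np.arange(1, r.size + 1, dtype=float)
    # chord anchored at the origin (zero components explain zero variance)
    x1, y1 = x[-1], c[-1]
    denom = np.hypot(x1, y1)
    if denom < 1e-15:
        return 1
    d = np.abs(y1 * x - x1 * c) / denom
    if np.max(d) < 1e-12:
        return 1
    return int(np.argmax(d)) + 1


# ---------------------------------------------------------------------------
# LASSO selection
# ---------------------------------------------------------------------------

def fit_lasso(X: np.ndarray, y: np.ndarray, spec: ReducerSpec) -> FittedReducer:
    """l1-penalized selection: minimize (1/2n)||y - Xw||^2 + lambda ||w||_1.

    ``lambda`` is chosen from ``spec.lambda_grid`` by 5-fold cross-validation
    on the training data (single-value grids skip the CV); ``lambda = 0``
    degenerates to ordinary least squares. The fitted transform keeps exactly
    the columns with nonzero coefficients.
    """
    if spec.method != "lasso":
        raise ConfigError(f"spec.method must be 'lasso', got {spec.method!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    scaler = Standardizer.fit(X)
    Z = scaler.transform(X)
    grid = spec.lambda_grid
    if len(grid) == 1:
        lam = grid[0]
    else:
        positive = [g for g in grid if g > 0]
        if len(positive) < len(grid):
            raise ConfigError("multi-value lambda_grid must be strictly positive")
        cv = KFold(n_splits=5, shuffle=True, random_state=spec.seed % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = LassoCV(alphas=np.sort(positive)[::-1], cv=cv, max_iter=50_000)
            model.fit(Z, y)
        lam = float(model.alpha_)
    if lam == 0.0:
        coef = LinearRegression().fit(Z, y).coef_
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            coef = Lasso(alpha=lam, max_iter=50_000).fit(Z, y).coef_
    selected = np.flatnonzero(coef != 0.0)
    if selected.size == 0:
        raise DataError(
            f"LASSO selected no features at lambda={lam:g}; "
            "retry with a smaller lambda grid"
        )
    return FittedReducer(
        method="lasso",
        spec=spec,
        n_features_in=X.shape[1],
        output_dim=int(selected.size),
        scaler=scaler,
        params={"selected": selected, "coef": coef, "lambda": lam},
    )


# ---------------------------------------------------------------------------
# Neural encoders
# ---------------------------------------------------------------------------

def _encoder_stack(net, n_layers: int) -> tuple[list[np.ndarray], list[np.ndarray]]:
    return (
        [net.coefs_[i].copy() for i in range(n_layers)],
        [net.intercepts_[i].copy() for i in range(n_layers)],
    )


def fit_denoising_ae(X: np.ndarray, spec: ReducerSpec) -> FittedReducer:
    """Denoising autoencoder; transform = bottleneck activations.

    Architecture (node layers): input -> hidden -> bottleneck -> hidden ->
    output, i.e. two weight layers each for the encoder and decoder. Inputs
    are corrupted with additive N(0, noise_sd^2) noise; the target is the
    clean standardized matrix. Labels are never consulted.
    """
    if spec.method != "ae":
        raise ConfigError(f"spec.method must be 'ae', got {spec.method!r}")
    if spec.epochs < 1:
        raise ConfigError(f"epochs must be >= 1, got {spec.epochs}")
    X = np.asarray(X, dtype=float)
    scaler = Standardizer.fit(X)
    Z = scaler.transform(X)
    rng = np.random.default_rng(spec.seed)
    Zn = Z + rng.normal(0.0, spec.noise_sd, size=Z.shape)
    hidden = spec.hidden_widths[0]
    net = MLPRegressor(
        hidden_layer_sizes=(hidden, spec.n_components, hidden),
        activation="relu",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        max_iter=spec.epochs,
        early_stopping=spec.early_stopping,
        validation_fraction=0.1,
        n_iter_no_change=10,
        random_state=spec.seed % (2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(Zn, Z)
    weights, biases = _encoder_stack(net, 2)
    return FittedReducer(
        method="ae",
        spec=spec,
        n_features_in=X.shape[1],
        output_dim=spec.n_components,
        scaler=scaler,
        params={
            "weights": weights,
            "biases": biases,
            "loss_curve": list(map(float, net.loss_curve_)),
        },
    )


def fit_supervised_encoder(X: np.ndarray, y: np.ndarray, spec: ReducerSpec) -> FittedReducer:
    """Supervised encoder: bottleneck features of a trained classifier.

    A feed-forward classifier with hidden layers ``hidden_widths`` followed by
    an ``n_components``-node bottleneck (the last hidden layer) and a softmax
    head. After training, the head is discarded; transform returns the
    bottleneck activations.
    """
    if spec.method != "se":
        raise ConfigError(f"spec.method must be 'se', got {spec.method!r}")
    if spec.epochs < 1:
        raise ConfigError(f"epochs must be >= 1, got {spec.epochs}")
    X = np.asarray(X, dtype=float)
    if spec.n_components >= X.shape[1]:
        raise ConfigError(
            f"n_components={spec.n_components} is not a reduction of p={X.shape[1]}"
        )
    scaler = Standardizer.fit(X)
    Z = scaler.transform(X)
    layers = tuple(spec.hidden_widths) + (spec.n_components,)
    net = MLPClassifier(
        hidden_layer_sizes=layers,
        activation="relu",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        max_iter=spec.epochs,
        early_stopping=spec.early_stopping,
        validation_fraction=0.1,
        n_iter_no_change=10,
        random_state=spec.seed % (2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(Z, np.asarray(y))
    weights, biases = _encoder_stack(net, len(layers))
    return FittedReducer(
        method="se",
        spec=spec,
        n_features_in=X.shape[1],
        output_dim=spec.n_components,
        scaler=scaler,
        params={
            "weights": weights,
            "biases": biases,
            "loss_curve": list(map(float, net.loss_curve_)),
        },
    )


def untrained_encoder(X: np.ndarray, spec: ReducerSpec) -> FittedReducer:
    """A randomly initialized (never trained) encoder with the SE architecture.

    Glorot-uniform weights, zero biases. Serves as the no-learning baseline
    when probing what information a trained bottleneck has actually extracted.
    """
    X = np.asarray(X, dtype=float)
    scaler = Standardizer.fit(X)
    dims = [X.shape[1], *spec.hidden_widths, spec.n_components]
    rng = np.random.default_rng(spec.seed)
    weights = [
        rng.uniform(-1.0, 1.0, size=(a, b)) * np.sqrt(6.0 / (a + b))
        for a, b in zip(dims[:-1], dims[1:])
    ]
    biases = [np.zeros(b) for b in dims[1:]]
    return FittedReducer(
        method="se",
        spec=spec,
        n_features_in=X.shape[1],
        output_dim=spec.n_components,
        scaler=scaler,
        params={"weights": weights, "biases": biases, "loss_curve": []},
    )


def fit_reducer(spec: ReducerSpec, X: np.ndarray, y: np.ndarray | None = None) -> FittedReducer:
    """Dispatch on ``spec.method``; supervised methods require ``y``."""
    if spec.method == "pca":
        return fit_pca(X, q=spec.n_components, seed=spec.seed)
    if spec.method == "ae":
        return fit_denoising_ae(X, spec)
    if y is None:
        raise DataError(f"method {spec.method!r} requires targets y")
    if spec.method == "lasso":
        return fit_lasso(X, y, spec)
    return fit_supervised_encoder(X, y, spec)
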