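"""Penalized autoencoder family, training, and the closed-form linear oracle.

All architectures are small multilayer perceptrons trained to reconstruct
z-scored region volumes through a 15-unit bottleneck. Implemented directly in
NumPy (manual backprop + RMSprop): problem sizes are tiny (<= a few dozen
inputs), so this keeps the artifact dependency-light and bit-reproducible.

The canonical configurations:

===============  ==========  ========  ==================  ====
name             activation  penalty   latent layers       tied
===============  ==========  ========  ==================  ====
baseline         identity    none      [15]                no
l1               identity    l1        [15]                no
l2               identity    l2        [15]                no
xcov             identity    xcov      [15]                no
tied_relu        relu        none      [15]                yes
deep3            relu        none      [25, 15, 25]        no
deep5            relu        none      [25, 20, 15, 20, 25] no
===============  ==========  ========  ==================  ====
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DivergenceError, RankError, ShapeMismatchError, SpecError

PENALTIES = ("none", "l1", "l2", "xcov")
DEFAULT_LAMBDA_GRID = (1e-4, 1e-3, 1e-2, 1e-1)


@dataclass
class AutoencoderSpec:
    name: str = "baseline"
    activation: str = "identity"  # or "relu"
    latent_layers: tuple[int, ...] = (15,)
    tied_weights: bool = False
    penalty: str = "none"
    penalty_coefficient: float = 0.0
    learning_rate: float = 1e-3
    optimizer: str = "rmsprop"  # or "sgd"
    max_epochs: int = 500
    batch_size: int = 128
    patience: int = 20
    seed: int = 0

    def __post_init__(self):
        self.latent_layers = tuple(int(w) for w in self.latent_layers)
        if not self.latent_layers or min(self.latent_layers) < 1:
            raise SpecError("latent_layers must be nonempty positive widths")
        if self.activation not in ("identity", "relu"):
            raise SpecError(f"unknown activation {self.activation!r}")
        if self.penalty not in PENALTIES:
            raise SpecError(f"unknown penalty {self.penalty!r}")
        if self.penalty_coefficient < 0:
            raise SpecError("penalty coefficient must be nonnegative")
        if self.optimizer not in ("rmsprop", "sgd"):
            raise SpecError(f"unknown optimizer {self.optimizer!r}")
        if self.tied_weights and self.latent_layers != self.latent_layers[::-1]:
            raise SpecError("tied weights require a symmetric latent layer plan")

    @property
    def bottleneck_width(self) -> int:
        return min(self.latent_layers)

    @property
    def bottleneck_layer(self) -> int:
        """Index (into weight matrices) of the layer whose output is the bottleneck."""
        return int(np.argmin(self.latent_layers))


def canonical_specs(latent_dim: int = 15, lam: float = 1e-3, **kwargs) -> dict[str, AutoencoderSpec]:
    """The seven canonical architecture configurations."""
    d = latent_dim
    make = lambda **kw: AutoencoderSpec(**{**kw, **kwargs})
    return {
        "baseline": make(name="baseline", activation="identity", latent_layers=(d,)),
        "l1": make(name="l1", activation="identity", latent_layers=(d,),
                   penalty="l1", penalty_coefficient=lam),
        "l2": make(name="l2", activation="identity", latent_layers=(d,),
                   penalty="l2", penalty_coefficient=lam),
        "xcov": make(name="xcov", activation="identity", latent_layers=(d,),
                     penalty="xcov", penalty_coefficient=lam),
        "tied_relu": make(name="tied_relu", activation="relu", latent_layers=(d,),
                          tied_weights=True),
        "deep3": make(name="deep3", activation="relu", latent_layers=(d + 10, d, d + 10)),
        "deep5": make(name="deep5", activation="relu",
                      latent_layers=(d + 10, d + 5, d, d + 5, d + 10)),
    }


# ---------------------------------------------------------------------------
# metrics

def reconstruction_mae(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean absolute error over all entries."""
    x, xhat = np.asarray(x, dtype=float), np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ShapeMismatchError(f"shapes differ: {x.shape} vs {xhat.shape}")
    return float(np.mean(np.abs(x - xhat)))


def explained_variance_score(x: np.ndarray, xhat: np.ndarray) -> float:
    """1 - MAE on z-scored data; 1 means perfect reconstruction."""
    return 1.0 - reconstruction_mae(x, xhat)


# ---------------------------------------------------------------------------
# model

class AutoencoderModel:
    """Weights/biases for one architecture, plus training provenance."""

    def __init__(self, spec: AutoencoderSpec, n_regions: int):
        self.spec = spec
        self.n_regions = int(n_regions)
        self.widths = [self.n_regions, *spec.latent_layers, self.n_regions]
        rng = np.random.default_rng(spec.seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.widths[:-1], self.widths[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        if spec.tied_weights:
            self._retie()
        self.training_log: list[dict] = []
        self.bottleneck_means: np.ndarray | None = None

    # -- structure -----------------------------------------------------------
    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def bottleneck_layer(self) -> int:
        return self.spec.bottleneck_layer

    @property
    def n_parameters(self) -> int:
        n = sum(b.size for b in self.biases)
        if self.spec.tied_weights:
            m = self.n_layers
            for i in range((m + 1) // 2):
                n += self.weights[i].size
        else:
            n += sum(w.size for w in self.weights)
        return n

    def _retie(self) -> None:
        m = self.n_layers
        for i in range(m // 2):
            self.weights[m - 1 - i] = self.weights[i].T.copy()
        if m % 2 == 1:
            mid = m // 2
            self.weights[mid] = (self.weights[mid] + self.weights[mid].T) / 2.0

    # -- forward -------------------------------------------------------------
    def _activate(self, a: np.ndarray) -> np.ndarray:
        return np.maximum(a, 0.0) if self.spec.activation == "relu" else a

    def _forward(self, x: np.ndarray):
        """Return (pre-activations, post-activations) per layer; h[0] = x."""
        h = [np.asarray(x, dtype=float)]
        pre = []
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            a = h[-1] @ w + b
            pre.append(a)
            h.append(a if i == self.n_layers - 1 else self._activate(a))
        return pre, h

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Bottleneck activations for each row of x."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_regions:
            raise ShapeMismatchError(f"expected (n, {self.n_regions}) input, got {x.shape}")
        h = x
        for i in range(self.bottleneck_layer + 1):
            a = h @ self.weights[i] + self.biases[i]
            h = a if i == self.n_layers - 1 else self._activate(a)
        return h

    def decode(self, latent: np.ndarray) -> np.ndarray:
        """Reconstruction from bottleneck activations."""
        h = np.asarray(latent, dtype=float)
        for i in range(self.bottleneck_layer + 1, self.n_layers):
            a = h @ self.weights[i] + self.biases[i]
            h = a if i == self.n_layers - 1 else self._activate(a)
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self._forward(x)[1][-1]

    def score(self, x: np.ndarray) -> float:
        return explained_variance_score(x, self.reconstruct(x))

    # -- serialization -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": 1,
            "spec": {**self.spec.__dict__, "latent_layers": list(self.spec.latent_layers)},
            "n_regions": self.n_regions,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "bottleneck_means": None if self.bottleneck_means is None
            else self.bottleneck_means.tolist(),
            "training_log": self.training_log,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "AutoencoderModel":
        payload = json.loads(Path(path).read_text())
        spec = AutoencoderSpec(**payload["spec"])
        model = cls(spec, payload["n_regions"])
        model.weights = [np.array(w, dtype=float) for w in payload["weights"]]
        model.biases = [np.array(b, dtype=float) for b in payload["biases"]]
        if payload["bottleneck_means"] is not None:
            model.bottleneck_means = np.array(payload["bottleneck_means"], dtype=float)
        model.training_log = payload["training_log"]
        return model


def build_autoencoder(spec: AutoencoderSpec, n_regions: int) -> AutoencoderModel:
    """Seeded, shape-checked initialization of an untrained model."""
    return AutoencoderModel(spec, n_regions)


# ---------------------------------------------------------------------------
# loss and training

def _weight_penalty(model: AutoencoderModel) -> float:
    if model.spec.penalty == "l1":
        return float(sum(np.abs(w).sum() for w in model.weights))
    if model.spec.penalty == "l2":
        return float(sum((w**2).sum() for w in model.weights))
    return 0.0


def xcov_penalty(latent: np.ndarray) -> float:
    """0.5 * sum of squared off-diagonal covariances of latent activations."""
    hc = latent - latent.mean(axis=0)
    cov = hc.T @ hc / latent.shape[0]
    off = cov - np.diag(np.diag(cov))
    return 0.5 * float((off**2).sum())


def _xcov_grad(latent: np.ndarray) -> np.ndarray:
    """d(xcov_penalty)/d(latent), including the centering term."""
    n = latent.shape[0]
    hc = latent - latent.mean(axis=0)
    cov = hc.T @ hc / n
    off = cov - np.diag(np.diag(cov))
    g = (2.0 / n) * hc @ off
    return g - g.mean(axis=0)


def training_loss(model: AutoencoderModel, x: np.ndarray) -> float:
    """Reconstruction MSE plus the lambda-weighted penalty term."""
    pre, h = model._forward(x)
    recon = float(np.mean((h[-1] - x) ** 2))
    lam = model.spec.penalty_coefficient
    if model.spec.penalty == "none" or lam == 0.0:
        return recon
    if model.spec.penalty == "xcov":
        return recon + lam * xcov_penalty(h[model.bottleneck_layer + 1])
    return recon + lam * _weight_penalty(model)


def _backward(model: AutoencoderModel, x: np.ndarray):
    """Gradients of training_loss wrt weights and biases for one batch."""
    spec = model.spec
    pre, h = model._forward(x)
    m, r = x.shape
    lam = spec.penalty_coefficient
    grads_w = [None] * model.n_layers
    grads_b = [None] * model.n_layers
    delta = 2.0 * (h[-1] - x) / (m * r)
    for i in range(model.n_layers - 1, -1, -1):
        grads_w[i] = h[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if spec.penalty == "l1" and lam:
            grads_w[i] = grads_w[i] + lam * np.sign(model.weights[i])
        elif spec.penalty == "l2" and lam:
            grads_w[i] = grads_w[i] + lam * 2.0 * model.weights[i]
        if i > 0:
            delta = delta @ model.weights[i].T
            if spec.penalty == "xcov" and lam and i - 1 == model.bottleneck_layer:
                delta = delta + lam * _xcov_grad(h[i])
            if spec.activation == "relu":
                delta = delta * (pre[i - 1] > 0)
    if spec.tied_weights:
        mm = model.n_layers
        for i in range(mm // 2):
            shared = grads_w[i] + grads_w[mm - 1 - i].T
            grads_w[i] = shared
            grads_w[mm - 1 - i] = shared.T
        if mm % 2 == 1:
            mid = mm // 2
            grads_w[mid] = (grads_w[mid] + grads_w[mid].T) / 2.0
    return grads_w, grads_b


def train_autoencoder(
    spec: AutoencoderSpec,
    x_train: np.ndarray,
    x_val: np.ndarray | None = None,
) -> AutoencoderModel:
    """Minibatch training with RMSprop (or SGD) and early stopping.

    Early stopping monitors validation reconstruction MSE; the best-epoch
    parameters are restored. With tied weights the decoder equals the
    transposed encoder at every step (gradients are shared).
    """
    x_train = np.asarray(x_train, dtype=float)
    if x_val is None:
        x_val = x_train
    model = build_autoencoder(spec, x_train.shape[1])
    rng = np.random.default_rng([spec.seed, 17])
    cache_w = [np.zeros_like(w) for w in model.weights]
    cache_b = [np.zeros_like(b) for b in model.biases]
    rho, eps = 0.9, 1e-8
    best_val = np.inf
    best = None
    stale = 0
    n = x_train.shape[0]
    for epoch in range(spec.max_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, spec.batch_size):
            batch = x_train[perm[start:start + spec.batch_size]]
            grads_w, grads_b = _backward(model, batch)
            for i in range(model.n_layers):
                if spec.optimizer == "rmsprop":
                    cache_w[i] = rho * cache_w[i] + (1 - rho) * grads_w[i] ** 2
                    cache_b[i] = rho * cache_b[i] + (1 - rho) * grads_b[i] ** 2
                    model.weights[i] -= spec.learning_rate * grads_w[i] / (np.sqrt(cache_w[i]) + eps)
                    model.biases[i] -= spec.learning_rate * grads_b[i] / (np.sqrt(cache_b[i]) + eps)
                else:
                    model.weights[i] -= spec.learning_rate * grads_w[i]
                    model.biases[i] -= spec.learning_rate * grads_b[i]
            if spec.tied_weights:
                model._retie()
            batch_loss = training_loss(model, batch)
            if not np.isfinite(batch_loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            epoch_loss += batch_loss
            n_batches += 1
        val_loss = float(np.mean((model.reconstruct(x_val) - x_val) ** 2))
        model.training_log.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best = ([w.copy() for w in model.weights], [b.copy() for b in model.biases])
            stale = 0
        else:
            stale += 1
            if stale >= spec.patience:
                break
    if best is not None:
        model.weights, model.biases = best
    if spec.tied_weights:
        model._retie()
    model.bottleneck_means = model.encode(x_train).mean(axis=0)
    return model


# ---------------------------------------------------------------------------
# closed-form oracle

def closed_form_linear_ae(x: np.ndarray, k: int) -> AutoencoderModel:
    """Optimal rank-k linear autoencoder: top-k principal axes of x.

    Squared-error-optimal among all rank-k linear reconstructions; used as
    the performance oracle against which trained linear models are checked.
    """
    x = np.asarray(x, dtype=float)
    n, r = x.shape
    if n <= k:
        raise RankError(f"need more than k={k} rows, got {n}")
    mu = x.mean(axis=0)
    cov = np.cov(x - mu, rowvar=False, ddof=0)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(evals[0], 1e-300) * 1e-10))
    if rank < k:
        raise RankError(f"covariance rank {rank} < k={k}")
    v = evecs[:, :k]
    # deterministic sign: largest-|.| entry of each axis positive
    signs = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(k)])
    v = v * signs
    spec = AutoencoderSpec(name=f"pca_oracle_k{k}", activation="identity",
                           latent_layers=(k,), tied_weights=False)
    model = AutoencoderModel(spec, r)
    model.weights = [v.copy(), v.T.copy()]
    model.biases = [-(mu @ v), mu.copy()]
    model.bottleneck_means = model.encode(x).mean(axis=0)
    return model


def encode(model: AutoencoderModel, x: np.ndarray) -> np.ndarray:
    """Deterministic forward pass to the bottleneck (functional alias)."""
    return model.encode(x)


def canonicalize_latents(model: AutoencoderModel, x: np.ndarray) -> AutoencoderModel:
    """Re-parameterize the bottleneck as principal axes of the reconstruction.

    A purely linear bottleneck is only identified up to an invertible latent
    transform: two equally good trained models can carry arbitrarily mixed
    latent bases, which defeats unit-wise comparison across runs. This maps
    the latents to principal-component scores of the model's own
    reconstructed data (descending variance, orthonormal decoder rows,
    deterministic signs) without changing the input->output map. Requires a
    single-latent-layer identity-activation model.
    """
    if model.spec.activation != "identity" or model.n_layers != 2:
        raise SpecError(
            "latent canonicalization requires a single-latent-layer identity model"
        )
    if model.widths[1] > model.n_regions:
        raise SpecError(
            f"bottleneck width {model.widths[1]} exceeds {model.n_regions} regions; "
            "the reconstruction covariance cannot supply a full basis"
        )
    x = np.asarray(x, dtype=float)
    xhat = model.reconstruct(x)
    mu = xhat.mean(axis=0)
    cov = np.cov(xhat - mu, rowvar=False, ddof=0)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    k = model.widths[1]
    basis = evecs[:, order[:k]]
    signs = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(k)])
    basis = basis * signs
    w0, w1 = model.weights
    b0, b1 = model.biases
    out = copy.deepcopy(model)
    out.weights = [w0 @ (w1 @ basis), basis.T.copy()]
    out.biases = [(b0 @ w1 + b1 - mu) @ basis, mu.copy()]
    out.spec = replace(out.spec, tied_weights=False)
    out.bottleneck_means = out.encode(x).mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# nested-CV architecture comparison

@dataclass
class CVPlan:
    outer_folds: int = 5
    inner_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2:
            raise SpecError("need at least 2 outer folds")
        if self.inner_folds < 2:
            raise SpecError("need at least 2 inner folds")


@dataclass
class FitReport:
    table: pd.DataFrame  # one row per architecture
    winner: str
    per_fold: pd.DataFrame  # long format: spec, fold, score, mae, chosen lambda

    def row(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _kfold_indices(n: int, k: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    return [(np.setdiff1d(idx, fold, assume_unique=False), fold)
            for fold in np.array_split(idx, k)]


def compare_architectures(
    specs: Sequence[AutoencoderSpec],
    x: np.ndarray,
    cv_plan: CVPlan | None = None,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    max_inner_evals: int = 3,
) -> FitReport:
    """Nested-CV comparison: inner folds tune lambda, outer folds score.

    ``max_inner_evals`` caps how many of the inner folds are actually fit per
    candidate (hyperparameter selection averages over those), which keeps
    desk-scale runs inside sane budgets while preserving the nesting.
    """
    cv_plan = cv_plan or CVPlan()
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng([cv_plan.seed, 29])
    outer = _kfold_indices(x.shape[0], cv_plan.outer_folds, rng)
    records = []
    for spec in specs:
        grid = list(lambda_grid) if spec.penalty != "none" else [0.0]
        for fold_i, (train_idx, test_idx) in enumerate(outer):
            x_tr, x_te = x[train_idx], x[test_idx]
            inner_rng = np.random.default_rng([cv_plan.seed, 31, fold_i])
            inner = _kfold_indices(x_tr.shape[0], cv_plan.inner_folds, inner_rng)
            inner = inner[:max_inner_evals]
            if len(grid) > 1:
                lam_scores = []
                for lam in grid:
                    cand = replace(spec, penalty_coefficient=lam,
                                   seed=spec.seed + 1000 * fold_i)
                    vals = [train_autoencoder(cand, x_tr[itr], x_tr[iva]).score(x_tr[iva])
                            for itr, iva in inner]
                    lam_scores.append(np.mean(vals))
                lam = grid[int(np.argmax(lam_scores))]
            else:
                lam = grid[0]
            final = replace(spec, penalty_coefficient=lam, seed=spec.seed + 1000 * fold_i)
            itr, iva = inner[0]
            model = train_autoencoder(final, x_tr[itr], x_tr[iva])
            mae = reconstruction_mae(x_te, model.reconstruct(x_te))
            records.append({"spec": spec.name, "fold": fold_i, "score": 1.0 - mae,
                            "mae": mae, "lambda": lam,
                            "n_params": model.n_parameters})
    per_fold = pd.DataFrame.from_records(records)
    table = (per_fold.groupby("spec", sort=False)
             .agg(mean_score=("score", "mean"), sd_score=("score", "std"),
                  mean_mae=("mae", "mean"), sd_mae=("mae", "std"),
                  n_params=("n_params", "first"))
             .fillna(0.0))
    best = table["mean_score"].max()
    contenders = table[table["mean_score"] >= best - 1e-12]
    winner = contenders.sort_values(["n_params"]).index[0]
    return FitReport(table=table, winner=str(winner), per_fold=per_fold)
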