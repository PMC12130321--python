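"""Matched linear/nonlinear multilayer perceptrons for polygenic prediction.

The nonlinearity test at the heart of this package compares two networks
of identical architecture trained from scratch: one with activation
functions (softplus) between its fully-connected layers, one without.
An activation-free stack

    Y = (((X W1) W2) ... Wk) = X (W1 W2 ... Wk) = X W_all

is algebraically a single linear map, so any performance advantage of the
activated network over its deactivated twin estimates the nonlinearity
(gene-gene / gene-environment interaction signal, or LD joint-tagging
artefacts) the network could exploit.  ``collapse_to_linear`` performs
that reduction explicitly, composing layer affine maps with the
inference-time affine form of batch normalisation, and is verified
against the network's own forward pass.

Everything here is plain numpy with hand-written backpropagation: batch
normalisation, inverted dropout, softplus, mini-batch SGD, early stopping
on validation r^2 with weight restore, a single halved-learning-rate
retrain when the best epoch is the first, and 50:50 case/control
oversampling for binary traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import _fast_train as _fast
from .genotype_sim import GenotypePanel
from .phenotype_sim import CovariateTable
from .pgs_baseline import PgsWeightSet, aligned_weight_vector

__all__ = [
    "NnConfig",
    "ModelInput",
    "TrainedNetwork",
    "LARGE_HIDDEN",
    "SMALL_HIDDEN",
    "build_design_matrix",
    "build_network",
    "collapse_to_linear",
    "train_network",
    "select_network",
    "predict",
    "parameter_count",
]

LARGE_HIDDEN = (100, 50, 25)
SMALL_HIDDEN = (24, 12, 6)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class NnConfig:
    """Hyperparameters of one perceptron variant.

    Defaults are the fixed training protocol used throughout: batch size
    32, dropout 0.3, learning rate 0.001, batch normalisation on,
    softplus activation, plain SGD, early-stopping patience 12 epochs.
    ``nonlinear`` switches the activation functions on or off; everything
    else is shared so the two variants are matched.
    """

    hidden_sizes: tuple[int, ...] = LARGE_HIDDEN
    nonlinear: bool = True
    activation: str = "softplus"
    dropout_rate: float = 0.3
    learning_rate: float = 0.001
    batch_size: int = 32
    batch_norm: bool = True
    optimizer: str = "sgd"
    patience_epochs: int = 12
    max_epochs: int = 200
    oversample_binary: bool = False
    binary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.activation != "softplus":
            raise ValueError("only the softplus activation is supported")
        if self.optimizer != "sgd":
            raise ValueError("only plain SGD is supported")


@dataclass
class ModelInput:
    """Design matrix with per-column provenance tags.

    ``column_kinds`` tags each column as weighted_snp / raw_snp / pgs /
    numeric_cov / onehot_cov.  Standardisation statistics for pgs and
    numeric covariate columns are computed on the training split only and
    baked into the matrix.
    """

    matrix: np.ndarray
    column_names: list[str]
    column_kinds: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.sample_ids), len(self.column_names)):
            raise ValueError("design matrix shape mismatch")
        if len(self.column_kinds) != len(self.column_names):
            raise ValueError("column metadata length mismatch")

    def rows(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.matrix[[pos[s] for s in sample_ids]]


@dataclass
class TrainedNetwork:
    """Perceptron weights plus training provenance."""

    weights: list[np.ndarray]  # k+1 matrices, input -> hidden... -> 1
    biases: list[np.ndarray]
    bn_gamma: list[np.ndarray]  # one per hidden layer ([] if batch_norm off)
    bn_beta: list[np.ndarray]
    bn_mean: list[np.ndarray]
    bn_var: list[np.ndarray]
    config: NnConfig
    best_epoch: int = 0
    val_r2_history: list[float] = field(default_factory=list)
    train_loss_history: list[float] = field(default_factory=list)
    case_fraction_history: list[float] = field(default_factory=list)
    column_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        dims = [self.weights[0].shape[0]]
        for W in self.weights:
            if W.shape[0] != dims[-1]:
                raise ValueError("layer shapes do not chain")
            dims.append(W.shape[1])
        if dims[-1] != 1:
            raise ValueError("output layer must have width 1")

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def copy_params(self) -> list[np.ndarray]:
        return [a.copy() for a in self.weights + self.biases + self.bn_gamma
                + self.bn_beta + self.bn_mean + self.bn_var]

    def restore_params(self, params: list[np.ndarray]) -> None:
        groups = [self.weights, self.biases, self.bn_gamma, self.bn_beta,
                  self.bn_mean, self.bn_var]
        it = iter(params)
        for group in groups:
            for i in range(len(group)):
                group[i] = next(it).copy()


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def build_design_matrix(
    panel: GenotypePanel,
    weights: Optional[PgsWeightSet] = None,
    covariates: Optional[CovariateTable] = None,
    pgs_scores: Optional[np.ndarray] = None,
    weighting_enabled: bool = False,
    train_ids: Optional[list[str]] = None,
    snp_subset: Optional[list[str]] = None,
) -> ModelInput:
    """Assemble the network input: [SNP block | PGS | covariates].

    SNP dosages enter raw, or multiplied by their per-SNP score weights
    when ``weighting_enabled`` (the joint-tagging mitigation; swapped
    effect alleles contribute weight x (2 - dosage)).  The PGS column and
    numeric covariates are z-scored with training-split statistics;
    multi-level factors are expanded to full one-hot (no reference level
    dropped) with an explicit level for missing values; missing numerics
    are imputed to the training mean.
    """
    if weighting_enabled and weights is None:
        raise ValueError("weighting_enabled requires a PgsWeightSet")
    if train_ids is None:
        train_ids = list(panel.sample_ids)
    train_rows = panel.sample_rows(train_ids)

    if snp_subset is not None:
        sub = set(snp_subset)
        keep = [j for j, s in enumerate(panel.snp_ids) if s in sub]
    else:
        keep = list(range(panel.n_snps))
    D = panel.dosages[:, keep].astype(float)
    snp_names = [panel.snp_ids[j] for j in keep]

    if weighting_enabled:
        w_full, flipped_full, _ = aligned_weight_vector(panel, weights)
        w = w_full[keep]
        flipped = flipped_full[keep]
        eff = np.where(flipped, 2.0 - D, D)
        snp_block = eff * w
        snp_kind = "weighted_snp"
    else:
        snp_block = D
        snp_kind = "raw_snp"

    blocks = [snp_block]
    names = list(snp_names)
    kinds = [snp_kind] * len(snp_names)

    def zscore_train(col: np.ndarray, label: str) -> Optional[np.ndarray]:
        tr = col[train_rows]
        mu, sd = np.nanmean(tr), np.nanstd(tr)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"constant column {label} dropped (z-score undefined)")
            return None
        filled = np.where(np.isnan(col), mu, col)
        return (filled - mu) / sd

    if pgs_scores is not None:
        z = zscore_train(np.asarray(pgs_scores, dtype=float), "PGS")
        if z is not None:
            blocks.append(z[:, None])
            names.append("PGS")
            kinds.append("pgs")

    if covariates is not None:
        cov = covariates.aligned_to(panel.sample_ids)
        for name, kind in cov.column_types.items():
            col = cov.data[name]
            if kind == "factor":
                filled = col.astype(object).where(col.notna(), "__missing__")
                levels = sorted(map(str, pd.unique(filled.astype(str))))
                for lev in levels:  # full one-hot, no reference drop
                    blocks.append(
                        (filled.astype(str) == lev).to_numpy(dtype=float)[:, None]
                    )
                    names.append(f"{name}={lev}")
                    kinds.append("onehot_cov")
            else:
                z = zscore_train(pd.to_numeric(col, errors="coerce").to_numpy(dtype=float), name)
                if z is not None:
                    blocks.append(z[:, None])
                    names.append(name)
                    kinds.append("numeric_cov")

    matrix = np.concatenate(blocks, axis=1)
    return ModelInput(matrix, names, kinds, list(panel.sample_ids))


# ---------------------------------------------------------------------------
# Network construction and forward/backward passes
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def build_network(input_dim: int, config: NnConfig) -> TrainedNetwork:
    """Fully-connected stack input_dim -> hidden_sizes -> 1, seeded init.

    Dropout and batch normalisation are present in both the linear and
    nonlinear variants (batch norm is affine at inference and dropout is
    inactive, so the linear variant remains exactly linear); only the
    activations between layers depend on ``config.nonlinear``.
    """
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    dims = [input_dim, *config.hidden_sizes, 1]
    weights = [_glorot(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
    biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
    n_hidden = len(config.hidden_sizes)
    if config.batch_norm:
        gamma = [np.ones(h) for h in config.hidden_sizes]
        beta = [np.zeros(h) for h in config.hidden_sizes]
        mean = [np.zeros(h) for h in config.hidden_sizes]
        var = [np.ones(h) for h in config.hidden_sizes]
    else:
        gamma = beta = mean = var = []
    return TrainedNetwork(weights, biases, gamma, beta, mean, var, config)


def parameter_count(net: TrainedNetwork) -> int:
    """Number of trainable parameters (weights, biases, batch-norm affine)."""
    n = sum(W.size for W in net.weights) + sum(b.size for b in net.biases)
    n += sum(g.size for g in net.bn_gamma) + sum(b.size for b in net.bn_beta)
    return n


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _forward_train(
    net: TrainedNetwork,
    X: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    masks: Optional[list[Optional[np.ndarray]]] = None,
) -> tuple[np.ndarray, dict]:
    """Training-mode forward pass; returns output and a backprop cache.

    Dropout masks may be supplied precomputed (inverted-dropout scale
    already applied); otherwise they are drawn from ``rng``.
    """
    cfg = net.config
    cache: dict = {"inputs": [], "pre_bn": [], "bn": {}, "act_in": [], "masks": []}
    h = X
    n_hidden = len(cfg.hidden_sizes)
    for li in range(n_hidden):
        cache["inputs"].append(h)
        a = h @ net.weights[li] + net.biases[li]
        cache["pre_bn"].append(a)
        if cfg.batch_norm:
            mu = a.mean(axis=0)
            var = a.var(axis=0)
            inv = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (a - mu) * inv
            a = net.bn_gamma[li] * xhat + net.bn_beta[li]
            cache["bn"][li] = (xhat, inv)
            net.bn_mean[li] = (1 - _BN_MOMENTUM) * net.bn_mean[li] + _BN_MOMENTUM * mu
            net.bn_var[li] = (1 - _BN_MOMENTUM) * net.bn_var[li] + _BN_MOMENTUM * var
        cache["act_in"].append(a)
        if cfg.nonlinear:
            a = _softplus(a)
        if cfg.dropout_rate > 0:
            if masks is not None:
                mask = masks[li]
            else:
                mask = (rng.random(a.shape) >= cfg.dropout_rate) / (1.0 - cfg.dropout_rate)
            a = a * mask
            cache["masks"].append(mask)
        else:
            cache["masks"].append(None)
        h = a
    cache["inputs"].append(h)
    out = h @ net.weights[-1] + net.biases[-1]
    return out[:, 0], cache


def _backward(
    net: TrainedNetwork, cache: dict, dout: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Gradients for all trainable parameters given d(loss)/d(output)."""
    cfg = net.config
    n_hidden = len(cfg.hidden_sizes)
    dW = [None] * (n_hidden + 1)
    db = [None] * (n_hidden + 1)
    dgamma = [None] * n_hidden if cfg.batch_norm else []
    dbeta = [None] * n_hidden if cfg.batch_norm else []

    g = dout[:, None]
    dW[-1] = cache["inputs"][-1].T @ g
    db[-1] = g.sum(axis=0)
    g = g @ net.weights[-1].T

    for li in range(n_hidden - 1, -1, -1):
        if cache["masks"][li] is not None:
            g = g * cache["masks"][li]
        if cfg.nonlinear:
            g = g * _sigmoid(cache["act_in"][li])
        if cfg.batch_norm:
            xhat, inv = cache["bn"][li]
            m = g.shape[0]
            dgamma[li] = (g * xhat).sum(axis=0)
            dbeta[li] = g.sum(axis=0)
            gx = g * net.bn_gamma[li]
            # standard batch-norm backward
            g = (inv / m) * (
                m * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0)
            )
        dW[li] = cache["inputs"][li].T @ g
        db[li] = g.sum(axis=0)
        g = g @ net.weights[li].T
    return dW, db, dgamma, dbeta


def predict(net: TrainedNetwork, inputs: ModelInput | np.ndarray) -> np.ndarray:
    """Deterministic inference forward pass.

    Dropout is off, batch normalisation uses its running statistics.  For
    binary networks the output is the predicted case probability.
    """
    if isinstance(inputs, ModelInput):
        if net.column_names is not None and inputs.column_names != net.column_names:
            extra = set(inputs.column_names) - set(net.column_names or [])
            miss = set(net.column_names or []) - set(inputs.column_names)
            raise ValueError(
                f"input columns do not match training metadata "
                f"(missing {sorted(miss)[:5]}, unexpected {sorted(extra)[:5]})"
            )
        X = inputs.matrix
    else:
        X = np.asarray(inputs, dtype=float)
    cfg = net.config
    h = X
    for li in range(len(cfg.hidden_sizes)):
        a = h @ net.weights[li] + net.biases[li]
        if cfg.batch_norm:
            inv = 1.0 / np.sqrt(net.bn_var[li] + _BN_EPS)
            a = net.bn_gamma[li] * (a - net.bn_mean[li]) * inv + net.bn_beta[li]
        if cfg.nonlinear:
            a = _softplus(a)
        h = a
    out = (h @ net.weights[-1] + net.biases[-1])[:, 0]
    if cfg.binary:
        out = _sigmoid(out)
    return out


def collapse_to_linear(net: TrainedNetwork) -> tuple[np.ndarray, float]:
    """Collapse an activation-free network to one affine map.

    Composes each layer's affine transform with batch normalisation's
    inference-time affine form, yielding W_all and an intercept such that
    predictions equal X @ W_all + intercept exactly (up to float error).
    """
    if net.config.nonlinear:
        raise ValueError("collapse_to_linear requires an activation-free network")
    # running affine x -> x @ A + c; c has the width of the current layer
    A = np.eye(net.input_dim)
    c = np.zeros(net.input_dim)
    cfg = net.config
    for li in range(len(cfg.hidden_sizes)):
        W, b = net.weights[li], net.biases[li]
        A, c = A @ W, c @ W + b
        if cfg.batch_norm:
            s = net.bn_gamma[li] / np.sqrt(net.bn_var[li] + _BN_EPS)
            t = net.bn_beta[li] - net.bn_mean[li] * s
            A, c = A * s, c * s + t
    W, b = net.weights[-1], net.biases[-1]
    A, c = A @ W, c @ W + b
    return A[:, 0], float(c[0])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _epoch_batches(
    rng: np.random.Generator,
    n_train: int,
    batch_size: int,
    labels: Optional[np.ndarray],
    oversample: bool,
) -> list[np.ndarray]:
    """Mini-batch index lists for one epoch.

    With oversampling, each example slot is a fair coin between the case
    and control pools (sampling with replacement within the epoch),
    giving a 50:50 expected case:control presentation regardless of
    prevalence.  Otherwise a plain seeded shuffle.
    """
    if oversample:
        if labels is None:
            raise ValueError("oversampling requires labels")
        cases = np.nonzero(labels == 1)[0]
        controls = np.nonzero(labels == 0)[0]
        if len(cases) == 0 or len(controls) == 0:
            raise ValueError("oversampling requires both cases and controls")
        pick_case = rng.random(n_train) < 0.5
        idx = np.where(
            pick_case,
            rng.choice(cases, size=n_train, replace=True),
            rng.choice(controls, size=n_train, replace=True),
        )
    else:
        idx = rng.permutation(n_train)
    batches = [idx[i : i + batch_size] for i in range(0, n_train, batch_size)]
    # batch norm needs >= 2 rows; fold a trailing singleton into its neighbour
    if len(batches) > 1 and len(batches[-1]) < 2:
        batches[-2] = np.concatenate([batches[-2], batches[-1]])
        batches.pop()
    return batches


def _val_metric(pred: np.ndarray, y: np.ndarray) -> float:
    """Validation r^2: squared Pearson correlation (also for binary traits,
    between predicted probability and label)."""
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1] ** 2)


def _sgd_step(net: TrainedNetwork, grads, lr: float, batch_size: int) -> None:
    dW, db, dgamma, dbeta = grads
    for li in range(len(net.weights)):
        net.weights[li] -= lr * dW[li] / batch_size
        net.biases[li] -= lr * db[li] / batch_size
    for li in range(len(net.bn_gamma)):
        net.bn_gamma[li] -= lr * dgamma[li] / batch_size
        net.bn_beta[li] -= lr * dbeta[li] / batch_size


def train_network(
    net: TrainedNetwork,
    inputs: ModelInput,
    y: np.ndarray,
    splits: dict[str, list[str]],
    config: Optional[NnConfig] = None,
) -> TrainedNetwork:
    """Train with mini-batch SGD, early stopping and best-weight restore.

    Loss is mean squared error for continuous traits and sigmoid
    cross-entropy for binary ones.  After each epoch the validation r^2
    is recorded; training stops when it has not improved for
    ``patience_epochs`` epochs (or at ``max_epochs``) and the best-epoch
    weights are restored.  A network whose best epoch is its first is
    retrained once from scratch with the learning rate halved.  For
    binary traits with oversampling enabled, the realized per-epoch case
    fraction is logged in ``case_fraction_history``.
    """
    cfg = config or net.config
    y = np.asarray(y, dtype=float)
    if len(y) != len(inputs.sample_ids):
        raise ValueError("phenotype not aligned with design matrix")
    pos = {s: i for i, s in enumerate(inputs.sample_ids)}
    tr = np.array([pos[s] for s in splits["train"]])
    va = np.array([pos[s] for s in splits["validation"]])
    Xtr, ytr = inputs.matrix[tr], y[tr]
    Xva, yva = inputs.matrix[va], y[va]
    if ytr.std() == 0:
        raise ValueError("zero-variance training phenotype")

    fast_ok = (
        _fast.NUMBA_AVAILABLE
        and len(cfg.hidden_sizes) == 3
        and cfg.batch_norm
    )

    def run(lr: float, seed_offset: int) -> TrainedNetwork:
        model = build_network(net.input_dim, replace(cfg, seed=cfg.seed + seed_offset))
        model.column_names = list(inputs.column_names)
        rng = np.random.default_rng(cfg.seed + 17 + seed_offset)
        best_params = model.copy_params()
        best_r2, best_epoch = -np.inf, 0
        labels = ytr if cfg.binary else None
        oversample = cfg.binary and cfg.oversample_binary
        Xc = np.ascontiguousarray(Xtr)
        for epoch in range(1, cfg.max_epochs + 1):
            batches = _epoch_batches(rng, len(ytr), cfg.batch_size, labels, oversample)
            idx = np.concatenate(batches)
            bounds = np.zeros(len(batches) + 1, dtype=np.int64)
            np.cumsum([len(b) for b in batches], out=bounds[1:])
            # one dropout-mask draw per layer per epoch, row-aligned to idx
            if cfg.dropout_rate > 0:
                masks = [
                    (rng.random((len(idx), h)) >= cfg.dropout_rate)
                    / (1.0 - cfg.dropout_rate)
                    for h in cfg.hidden_sizes
                ]
            else:
                masks = [np.ones((len(idx), h)) for h in cfg.hidden_sizes]

            if fast_ok:
                loss_sum, n_seen, case_sum = _fast.run_epoch(
                    Xc, ytr, idx.astype(np.int64), bounds,
                    model.weights[0], model.biases[0],
                    model.weights[1], model.biases[1],
                    model.weights[2], model.biases[2],
                    model.weights[3], model.biases[3],
                    model.bn_gamma[0], model.bn_beta[0], model.bn_mean[0], model.bn_var[0],
                    model.bn_gamma[1], model.bn_beta[1], model.bn_mean[1], model.bn_var[1],
                    model.bn_gamma[2], model.bn_beta[2], model.bn_mean[2], model.bn_var[2],
                    masks[0], masks[1], masks[2],
                    lr, cfg.nonlinear, cfg.binary, _BN_MOMENTUM, _BN_EPS,
                )
                if not np.isfinite(loss_sum):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}; training diverged"
                    )
                epoch_loss, n_cases = float(loss_sum), int(case_sum)
            else:
                epoch_loss, n_seen, n_cases = 0.0, 0, 0
                for bi in range(len(batches)):
                    lo, hi = bounds[bi], bounds[bi + 1]
                    bidx = idx[lo:hi]
                    Xb, yb = Xtr[bidx], ytr[bidx]
                    bmasks = [mk[lo:hi] for mk in masks] if cfg.dropout_rate > 0 else None
                    out, cache = _forward_train(model, Xb, masks=bmasks)
                    if cfg.binary:
                        p = _sigmoid(out)
                        p = np.clip(p, 1e-12, 1 - 1e-12)
                        loss = float(-np.mean(yb * np.log(p) + (1 - yb) * np.log(1 - p)))
                        dout = p - yb  # d(CE)/d(logit)
                    else:
                        resid = out - yb
                        loss = float(np.mean(resid**2))
                        dout = 2.0 * resid
                    if not np.isfinite(loss):
                        raise FloatingPointError(
                            f"non-finite loss at epoch {epoch}; training diverged"
                        )
                    grads = _backward(model, cache, dout)
                    _sgd_step(model, grads, lr, len(bidx))
                    epoch_loss += loss * len(bidx)
                    n_seen += len(bidx)
                    if cfg.binary:
                        n_cases += int(yb.sum())
            model.train_loss_history.append(epoch_loss / n_seen)
            if cfg.binary:
                model.case_fraction_history.append(n_cases / n_seen)
            val_r2 = _val_metric(predict(model, Xva), yva)
            model.val_r2_history.append(val_r2)
            if val_r2 > best_r2:
                best_r2, best_epoch = val_r2, epoch
                best_params = model.copy_params()
            elif epoch - best_epoch >= cfg.patience_epochs:
                break
        model.restore_params(best_params)
        model.best_epoch = best_epoch
        return model

    trained = run(cfg.learning_rate, 0)
    if trained.best_epoch == 1:
        # best performance in the very first epoch: one retrain at half LR
        trained = run(cfg.learning_rate / 2.0, 1)
    return trained


def select_network(
    large: TrainedNetwork,
    small: TrainedNetwork,
    inputs: ModelInput,
    y: np.ndarray,
    validation_ids: list[str],
) -> TrainedNetwork:
    """Pick the large or small variant by validation r^2 (tie -> small)."""
    if large.column_names != small.column_names:
        raise ValueError("networks were trained on different input columns")
    pos = {s: i for i, s in enumerate(inputs.sample_ids)}
    va = np.array([pos[s] for s in validation_ids])
    y = np.asarray(y, dtype=float)
    r2_large = _val_metric(predict(large, inputs.matrix[va]), y[va])
    r2_small = _val_metric(predict(small, inputs.matrix[va]), y[va])
    return large if r2_large > r2_small else small


def save_checkpoint(net: TrainedNetwork, path: str) -> None:
    """Serialize weights, config and column metadata to one .npz archive."""
    import dataclasses as _dc
    import json as _json

    arrays: dict[str, np.ndarray] = {}
    for group, name in [
        (net.weights, "W"), (net.biases, "b"), (net.bn_gamma, "g"),
        (net.bn_beta, "be"), (net.bn_mean, "rm"), (net.bn_var, "rv"),
    ]:
        for i, arr in enumerate(group):
            arrays[f"{name}{i}"] = arr
    meta = {
        "config": _dc.asdict(net.config),
        "best_epoch": net.best_epoch,
        "val_r2_history": net.val_r2_history,
        "train_loss_history": net.train_loss_history,
        "case_fraction_history": net.case_fraction_history,
        "column_names": net.column_names,
        "n_layers": len(net.weights),
        "n_bn": len(net.bn_gamma),
    }
    arrays["meta_json"] = np.frombuffer(
        _json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> TrainedNetwork:
    """Restore a network saved by :func:`save_checkpoint`."""
    import json as _json

    with np.load(path) as data:
        meta = _json.loads(bytes(data["meta_json"].tobytes()).decode())
        cfg_d = meta["config"]
        cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
        cfg = NnConfig(**cfg_d)
        k, nb = meta["n_layers"], meta["n_bn"]
        net = TrainedNetwork(
            weights=[data[f"W{i}"] for i in range(k)],
            biases=[data[f"b{i}"] for i in range(k)],
            bn_gamma=[data[f"g{i}"] for i in range(nb)],
            bn_beta=[data[f"be{i}"] for i in range(nb)],
            bn_mean=[data[f"rm{i}"] for i in range(nb)],
            bn_var=[data[f"rv{i}"] for i in range(nb)],
            config=cfg,
            best_epoch=meta["best_epoch"],
            val_r2_history=meta["val_r2_history"],
            train_loss_history=meta["train_loss_history"],
            case_fraction_history=meta["case_fraction_history"],
            column_names=meta["column_names"],
        )
    return net


def write_training_log(net: TrainedNetwork, path: str) -> None:
    """Training trajectory as TSV (epoch, train loss, validation r^2)."""
    df = pd.DataFrame(
        {
            "epoch": np.arange(1, len(net.val_r2_history) + 1),
            "train_loss": net.train_loss_history,
            "val_r2": net.val_r2_history,
        }
    )
    if net.case_fraction_history:
        df["case_fraction"] = net.case_fraction_history
    df.to_csv(path, sep="\t", index=False)
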