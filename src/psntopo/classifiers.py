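"""Classifier training: stratified splits, class weights, DNN/SVM/RF grids.

The cohort is partitioned 50/25/25 into training, evaluation and validation
sets by stratified sampling with largest-remainder rounding (498 samples give
exactly 249/125/124). Training uses per-sample class weights inversely
proportional to class frequencies, normalized so the mean weight is 1.

The DNN is a small fully connected multilayer perceptron written in numpy:
1-4 hidden layers of 2/4/8 ReLU units, softmax output, class-weighted
cross-entropy loss, inverted dropout, mini-batches of 32, 1000 epochs with an
evaluation-set balanced accuracy computed every 10 epochs. Optimizers: adam,
adadelta, adagrad and proximal adagrad (adagrad with optional L1/L2
regularisation). Each configuration is run with several replicate seeds; the
checkpoint with the best evaluation bACC is kept by default.

SVM (cost/gamma on a 2^(2p), p in [-4, 4] grid) and random forests
(100-10,000 trees, ten seeded runs) are the baselines, fitted with
scikit-learn under the same class weighting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from psntopo.evaluation import EvalRecord, balanced_accuracy
from psntopo.io_formats import OutcomeTable
from psntopo.topology import TopoFeatureMatrix

WIDTHS = (2, 4, 8)
OPTIMIZERS = ("adam", "adadelta", "adagrad", "proximal_adagrad")
SVM_P_RANGE = range(-4, 5)
RF_TREE_RANGE = (100, 10_000)


# ---------------------------------------------------------------------------
# splitting and weighting
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    train_ids: list[str]
    eval_ids: list[str]
    valid_ids: list[str]
    fractions: tuple[float, float, float]
    seed: int

    def partitions(self) -> dict[str, list[str]]:
        return {"train": self.train_ids, "eval": self.eval_ids,
                "valid": self.valid_ids}


def _largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    quotas = [total * f for f in fractions]
    sizes = [math.floor(q) for q in quotas]
    rem = total - sum(sizes)
    order = sorted(range(len(fractions)),
                   key=lambda j: (-(quotas[j] - sizes[j]), j))
    for j in order[:rem]:
        sizes[j] += 1
    return sizes


def stratified_split(
    outcomes: OutcomeTable,
    outcome_name: str,
    fractions: tuple[float, float, float] = (0.50, 0.25, 0.25),
    seed: int = 0,
) -> SplitAssignment:
    """Stratified train/eval/valid partition with largest-remainder rounding.

    Global partition sizes are the largest-remainder rounding of
    n * fractions; within each class, quotas are also rounded by largest
    remainder, subject to the global column totals, so per-class proportions
    stay within one sample of the cohort prevalence in every partition.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    y = outcomes.labels(outcome_name)
    ids = np.asarray(outcomes.sample_ids)
    n = len(ids)
    n_parts = len(fractions)
    sizes = _largest_remainder(n, fractions)
    classes = np.unique(y)
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(
                f"class {c} has too few samples to stratify (need >= 2)")

    # per-class quota floors, then leftover units assigned by largest
    # fractional remainder subject to column capacities
    alloc = {}
    col_used = [0] * n_parts
    leftovers = []
    for c in classes:
        nc = int((y == c).sum())
        quotas = [nc * f for f in fractions]
        base = [math.floor(q) for q in quotas]
        alloc[c] = base
        for j in range(n_parts):
            col_used[j] += base[j]
        for _ in range(nc - sum(base)):
            leftovers.append(c)
    cells = sorted(
        ((c, j) for c in classes for j in range(n_parts)),
        key=lambda cj: (-(len(ids) and ((y == cj[0]).sum() * fractions[cj[1]])
                          % 1), cj[1], cj[0]),
    )
    need = {c: leftovers.count(c) for c in classes}
    for c, j in cells:
        if need[c] > 0 and col_used[j] < sizes[j]:
            alloc[c][j] += 1
            col_used[j] += 1
            need[c] -= 1

    rng = np.random.default_rng(seed)
    parts: list[list[str]] = [[] for _ in range(n_parts)]
    for c in classes:
        members = ids[y == c].tolist()
        rng.shuffle(members)
        start = 0
        for j in range(n_parts):
            parts[j].extend(members[start:start + alloc[c][j]])
            start += alloc[c][j]
    return SplitAssignment(parts[0], parts[1], parts[2], tuple(fractions), seed)


def class_weights(y: np.ndarray) -> dict[int, float]:
    """Per-class weights inversely proportional to class frequencies,
    normalized so the mean per-sample weight is 1."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both classes present")
    n, k = y.size, classes.size
    return {int(c): n / (k * int(cnt)) for c, cnt in zip(classes, counts)}


def enumerate_architectures(
    depths: Iterable[int] = range(1, 5),
    widths: Sequence[int] = WIDTHS,
    constraint: str = "non_increasing",
) -> list[tuple[int, ...]]:
    """All hidden-layer size sequences for the architecture grid.

    'non_increasing' yields only non-increasing width sequences (34 for
    depths 1-4 and widths {2,4,8}); 'all' yields every sequence (120).
    """
    archs: list[tuple[int, ...]] = []
    ws = sorted(widths, reverse=True)
    for depth in depths:
        if constraint == "non_increasing":
            archs.extend(itertools.combinations_with_replacement(ws, depth))
        elif constraint == "all":
            archs.extend(itertools.product(ws, repeat=depth))
        else:
            raise ValueError(f"unknown constraint '{constraint}'")
    return archs


# ---------------------------------------------------------------------------
# model specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DnnSpec:
    hidden_sizes: tuple[int, ...] = (8, 4)
    dropout: float = 0.30
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 1000
    eval_every: int = 10
    seed: int = 0
    checkpoint: str = "best"  # keep best-evaluation or final parameters
    l1: float = 0.0  # proximal-adagrad regularisation terms
    l2: float = 0.0

    def __post_init__(self) -> None:
        hs = tuple(self.hidden_sizes)
        if not 1 <= len(hs) <= 4 or any(h not in WIDTHS for h in hs):
            raise ValueError(f"hidden_sizes must be 1-4 layers from {WIDTHS}")
        if not 0.15 <= self.dropout <= 0.40:
            raise ValueError("dropout must lie in [0.15, 0.40]")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        if not 1e-4 <= self.learning_rate <= 5e-2:
            raise ValueError("learning_rate must lie in [1e-4, 5e-2]")
        if self.checkpoint not in ("best", "final"):
            raise ValueError("checkpoint must be 'best' or 'final'")

    def summary(self) -> str:
        return (f"arch={list(self.hidden_sizes)} opt={self.optimizer} "
                f"lr={self.learning_rate:g} d={self.dropout:g}")

    def complexity(self) -> tuple:
        return (len(self.hidden_sizes), sum(self.hidden_sizes))


@dataclass(frozen=True)
class SvmSpec:
    kernel: str = "rbf"
    cost_p: int = 0   # cost = 2 ** (2 * cost_p)
    gamma_p: int = 0  # gamma = 2 ** (2 * gamma_p)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        for p in (self.cost_p, self.gamma_p):
            if p not in SVM_P_RANGE:
                raise ValueError("cost_p/gamma_p must be integers in [-4, 4]")

    @property
    def cost(self) -> float:
        return 2.0 ** (2 * self.cost_p)

    @property
    def gamma(self) -> float:
        return 2.0 ** (2 * self.gamma_p)

    def summary(self) -> str:
        return f"kernel={self.kernel} c={self.cost:g} g={self.gamma:g}"

    def complexity(self) -> tuple:
        return (abs(self.cost_p), abs(self.gamma_p))


@dataclass(frozen=True)
class RfSpec:
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not RF_TREE_RANGE[0] <= self.n_trees <= RF_TREE_RANGE[1]:
            raise ValueError(f"n_trees must lie in {RF_TREE_RANGE}")

    def summary(self) -> str:
        return f"n_trees={self.n_trees}"

    def complexity(self) -> tuple:
        return (self.n_trees,)


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reapply it frozen."""

    family: str
    spec: object
    params: object = field(repr=False)  # MLP weight list or sklearn estimator
    feature_names: list[str] = field(default_factory=list)
    training_log: list[dict] = field(default_factory=list, repr=False)
    scaler: object = None  # frozen preprocessing for external validation

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.family == "dnn":
            return _mlp_forward(self.params, X).argmax(axis=1)
        return self.params.predict(X)

    def param_hash(self) -> str:
        """Content hash of the fitted parameters (frozen-model contract)."""
        import hashlib
        import pickle

        h = hashlib.sha256()
        if self.family == "dnn":
            for Wb in self.params:
                h.update(np.ascontiguousarray(Wb).tobytes())
        else:
            h.update(pickle.dumps(self.params))
        return h.hexdigest()


# ---------------------------------------------------------------------------
# numpy MLP
# ---------------------------------------------------------------------------

def _mlp_init(sizes: Sequence[int], rng: np.random.Generator) -> list[np.ndarray]:
    """He-normal weights and zero biases; params = [W1, b1, W2, b2, ...]."""
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        params.append(rng.standard_normal((fan_in, fan_out))
                      * np.sqrt(2.0 / fan_in))
        params.append(np.zeros(fan_out))
    return params


def _mlp_forward(params: list[np.ndarray], X: np.ndarray,
                 dropout: float = 0.0,
                 rng: np.random.Generator | None = None):
    """Softmax-output forward pass; returns probabilities (and the per-layer
    cache when training with dropout)."""
    h = X
    cache = [h]
    n_layers = len(params) // 2
    masks = []
    for layer in range(n_layers):
        W, b = params[2 * layer], params[2 * layer + 1]
        z = h @ W + b
        if layer < n_layers - 1:
            h = np.maximum(z, 0.0)
            if dropout > 0 and rng is not None:
                mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
        else:
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            h = e / e.sum(axis=1, keepdims=True)
        cache.append(h)
    if rng is None and dropout == 0.0:
        return h
    return h, cache, masks


def _mlp_backward(params, cache, masks, probs, y_onehot, sample_w):
    """Gradients of the weighted cross-entropy (mean over the batch)."""
    nb = probs.shape[0]
    grads = [None] * len(params)
    delta = (probs - y_onehot) * sample_w[:, None] / nb
    n_layers = len(params) // 2
    for layer in range(n_layers - 1, -1, -1):
        h_in = cache[layer]
        grads[2 * layer] = h_in.T @ delta
        grads[2 * layer + 1] = delta.sum(axis=0)
        if layer > 0:
            delta = delta @ params[2 * layer].T
            delta = delta * (cache[layer] > 0)
            if masks[layer - 1] is not None:
                delta = delta * masks[layer - 1]
    return grads


class _Optimizer:
    """adam / adadelta / adagrad / proximal_adagrad update rules."""

    def __init__(self, name: str, lr: float, shapes, l1=0.0, l2=0.0):
        self.name, self.lr, self.l1, self.l2 = name, lr, l1, l2
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        if name == "adagrad" or name == "proximal_adagrad":
            # small positive accumulator start avoids a huge first step
            self.v = [np.full(s, 0.1) for s in shapes]

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            if self.name == "adam":
                b1, b2, eps = 0.9, 0.999, 1e-8
                self.m[i] = b1 * self.m[i] + (1 - b1) * g
                self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
                mhat = self.m[i] / (1 - b1 ** self.t)
                vhat = self.v[i] / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
            elif self.name == "adadelta":
                rho, eps = 0.95, 1e-6
                self.v[i] = rho * self.v[i] + (1 - rho) * g * g
                upd = (np.sqrt(self.m[i] + eps) / np.sqrt(self.v[i] + eps)) * g
                self.m[i] = rho * self.m[i] + (1 - rho) * upd * upd
                p -= self.lr * upd
            else:  # adagrad / proximal_adagrad
                eps = 1e-8
                self.v[i] += g * g
                step = self.lr / (np.sqrt(self.v[i]) + eps)
                p -= step * g
                if self.name == "proximal_adagrad" and (self.l1 or self.l2):
                    p /= (1.0 + step * self.l2)
                    if self.l1:
                        p[:] = np.sign(p) * np.maximum(np.abs(p) - step * self.l1, 0.0)


def _rows(features: TopoFeatureMatrix, ids: Sequence[str]) -> np.ndarray:
    pos = {s: i for i, s in enumerate(features.sample_ids)}
    return features.values[[pos[s] for s in ids]]


def _labels_for(outcomes_y: np.ndarray, all_ids: Sequence[str],
                ids: Sequence[str]) -> np.ndarray:
    pos = {s: i for i, s in enumerate(all_ids)}
    return np.asarray(outcomes_y)[[pos[s] for s in ids]]


def train_dnn(features: TopoFeatureMatrix, y: np.ndarray,
              split: SplitAssignment, spec: DnnSpec) -> TrainedModel:
    """Train the MLP on the training partition with class-weighted
    cross-entropy; evaluation-set bACC is logged every ``eval_every`` epochs
    and (by default) the best-evaluation checkpoint is returned.

    ``y`` is the label vector aligned with ``features.sample_ids``. The
    validation partition is never touched here.
    """
    if not features.standardized:
        raise ValueError("features must be standardized before training")
    Xtr = _rows(features, split.train_ids)
    ytr = _labels_for(y, features.sample_ids, split.train_ids)
    Xev = _rows(features, split.eval_ids)
    yev = _labels_for(y, features.sample_ids, split.eval_ids)

    cw = class_weights(ytr)
    w_tr = np.array([cw[int(c)] for c in ytr])
    onehot = np.zeros((ytr.size, 2))
    onehot[np.arange(ytr.size), ytr] = 1.0

    rng = np.random.default_rng(spec.seed)
    sizes = [Xtr.shape[1], *spec.hidden_sizes, 2]
    params = _mlp_init(sizes, rng)
    opt = _Optimizer(spec.optimizer, spec.learning_rate,
                     [p.shape for p in params], spec.l1, spec.l2)

    log: list[dict] = []
    best_bacc, best_params = -1.0, [p.copy() for p in params]
    n = Xtr.shape[0]
    for epoch in range(1, spec.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            probs, cache, masks = _mlp_forward(params, Xtr[idx], spec.dropout, rng)
            pt = np.clip(probs[np.arange(idx.size), ytr[idx]], 1e-12, None)
            loss = float(-(w_tr[idx] * np.log(pt)).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN loss at epoch {epoch} (lr={spec.learning_rate})")
            epoch_loss += loss * idx.size / n
            grads = _mlp_backward(params, cache, masks, probs,
                                  onehot[idx], w_tr[idx])
            opt.step(params, grads)
        if epoch % spec.eval_every == 0 or epoch == spec.epochs:
            pred = _mlp_forward(params, Xev).argmax(axis=1)
            bacc = balanced_accuracy(yev, pred)
            log.append({"epoch": epoch, "loss": epoch_loss, "eval_bacc": bacc})
            if bacc > best_bacc:
                best_bacc = bacc
                best_params = [p.copy() for p in params]
    final = best_params if spec.checkpoint == "best" else params
    return TrainedModel("dnn", spec, final, list(features.feature_names), log)


def train_svm(features: TopoFeatureMatrix, y: np.ndarray,
              split: SplitAssignment, spec: SvmSpec) -> TrainedModel:
    """Support vector machine baseline (scikit-learn), class-weighted like
    the DNN; the optimization problem is convex so one run suffices."""
    from sklearn.svm import SVC

    Xtr = _rows(features, split.train_ids)
    ytr = _labels_for(y, features.sample_ids, split.train_ids)
    cw = class_weights(ytr)
    kwargs = dict(C=spec.cost, class_weight=cw, random_state=spec.seed)
    if spec.kernel == "rbf":
        kwargs["gamma"] = spec.gamma
    clf = SVC(kernel=spec.kernel, **kwargs).fit(Xtr, ytr)
    return TrainedModel("svm", spec, clf, list(features.feature_names))


def train_rf(features: TopoFeatureMatrix, y: np.ndarray,
             split: SplitAssignment, spec: RfSpec) -> TrainedModel:
    """Random forest baseline (scikit-learn); training is stochastic, so the
    grid-search layer runs each configuration with ten replicate seeds."""
    from sklearn.ensemble import RandomForestClassifier

    Xtr = _rows(features, split.train_ids)
    ytr = _labels_for(y, features.sample_ids, split.train_ids)
    cw = class_weights(ytr)
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees, class_weight=cw, random_state=spec.seed,
        n_jobs=1,
    ).fit(Xtr, ytr)
    return TrainedModel("rf", spec, clf, list(features.feature_names))


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

_TRAINERS = {"dnn": train_dnn, "svm": train_svm, "rf": train_rf}


def _replicate_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def grid_search(
    family: str,
    features: TopoFeatureMatrix,
    y: np.ndarray,
    split: SplitAssignment,
    grid: Sequence[DnnSpec | SvmSpec | RfSpec],
    replicates: int = 10,
    master_seed: int = 0,
    dataset_tag: str = "",
    keep_models: bool = True,
) -> list[EvalRecord]:
    """One EvalRecord per (configuration, replicate).

    DNN and RF are stochastic and honour ``replicates`` with seeds derived
    deterministically from ``master_seed``; the SVM problem is convex, so
    each grid point is run exactly once. Records carry both evaluation- and
    validation-partition balanced accuracies.
    """
    if family not in _TRAINERS:
        raise ValueError(f"unknown family '{family}'")
    if not grid:
        raise ValueError("empty grid")
    trainer = _TRAINERS[family]
    n_rep = 1 if family == "svm" else replicates
    seeds = _replicate_seeds(master_seed, n_rep)
    Xev = _rows(features, split.eval_ids)
    yev = _labels_for(y, features.sample_ids, split.eval_ids)
    Xva = _rows(features, split.valid_ids)
    yva = _labels_for(y, features.sample_ids, split.valid_ids)
    records: list[EvalRecord] = []
    for spec in grid:
        for rep, seed in enumerate(seeds):
            spec_run = replace(spec, seed=seed)
            model = trainer(features, y, split, spec_run)
            bacc_ev = balanced_accuracy(yev, model.predict(Xev))
            bacc_va = balanced_accuracy(yva, model.predict(Xva))
            records.append(EvalRecord(
                family=family, config=spec_run.summary(), seed=seed,
                partition="valid", bacc=bacc_va, eval_bacc=bacc_ev,
                dataset_tag=dataset_tag, feature_set=features.feature_set,
                complexity=spec_run.complexity(),
                model=model if keep_models else None,
            ))
    return records
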