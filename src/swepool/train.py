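"""ERM training, hyperparameter selection and evaluation protocols.

The pooler and head are trained jointly by mini-batch gradient descent on
the task loss; the residue-level embeddings are frozen inputs (they stand
for the output of a frozen language model backbone).  Selection follows
the grid protocol: every (m, freeze) configuration is trained, the
configuration with the best validation metric across all epochs wins, and
the winner is re-trained and evaluated over several seeds, reporting mean
and standard deviation of the test metric.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .baselines import avg_pool, default_kmax_k, kmax_pool, max_pool, softmax_pool
from .core import (MATCH_D, SWEPoolerParams, TokenEmbeddingSet, init_swe_params,
                   swe_pool, swe_pool_with_grad)
from .heads import DTIHeadParams, ECHeadParams, MulticlassHeadParams
from .metrics import (MetricReport, UndefinedMetricError, accuracy_top1,
                      make_metric_report, metric_binary_curves, metric_fmax,
                      metric_pcc)
from .synthetic import SyntheticDataset

__all__ = [
    "RunConfig", "GridResult", "TrainedModel", "DivergedRunError",
    "train_erm", "grid_search_select", "select_best", "evaluate_seeds",
    "predict_scores", "compute_metric", "length_stratified_gains",
    "ScoredResult", "quartile_bins",
]

TASKS = ("dti", "affinity", "scl", "ec")
POOLERS = ("swe", "swe_simple", "avg", "max", "kmax", "softmax")
VALIDATION_METRIC = {"dti": "AUPR", "affinity": "PCC", "scl": "accuracy", "ec": "Fmax"}
DEFAULT_SEEDS = (0, 1, 2, 3, 4)


class DivergedRunError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class RunConfig:
    """One training run: task, pooler and optimization hyperparameters."""

    task: str = "ec"
    pooler: str = "swe"
    m: int = 16
    freeze: bool = False
    L: int | str = MATCH_D
    epochs: int = 50
    seeds: tuple = DEFAULT_SEEDS
    learning_rate: float = 1e-3
    batch_size: int = 64
    D: int = 1024
    kmax_K: int | None = None

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.pooler not in POOLERS:
            raise ValueError(f"unknown pooler {self.pooler!r}")
        if self.pooler == "swe_simple" and not self.freeze:
            # SWE_Simple is by definition the frozen variant
            object.__setattr__(self, "freeze", True)
        if self.m < 1 or self.epochs < 0 or self.batch_size < 1:
            raise ValueError("m and batch_size must be positive, epochs non-negative")
        object.__setattr__(self, "seeds", tuple(int(s) for s in self.seeds))


@dataclass
class TrainedModel:
    """Trained pooler + head with enough context to score new proteins."""

    config: RunConfig
    pooler_params: SWEPoolerParams | None
    head: object
    d: int

    def pool(self, X: TokenEmbeddingSet) -> np.ndarray:
        kind = self.config.pooler
        if kind in ("swe", "swe_simple"):
            return swe_pool(X, self.pooler_params).vector
        if kind == "avg":
            return avg_pool(X)
        if kind == "max":
            return max_pool(X)
        if kind == "kmax":
            K = self.config.kmax_K or default_kmax_k(X.n)
            return kmax_pool(X, K)
        return softmax_pool(X)

    def score(self, X: TokenEmbeddingSet, drug=None) -> float:
        """Task score for one protein: probability, affinity, or handled per task."""
        v = self.pool(X)
        task = self.config.task
        if task == "dti":
            return self.head.predict_interaction(drug, v)
        if task == "affinity":
            return self.head.predict_affinity(drug, v)
        if task == "ec":
            return self.head.prob_positive(v)
        raise ValueError("use logits() for the multiclass task")

    def logits(self, X: TokenEmbeddingSet) -> np.ndarray:
        return self.head.logits(self.pool(X))


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam over a flat dict of parameter arrays."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# model assembly and per-sample gradients

def _build_model(config: RunConfig, data: SyntheticDataset, seed: int) -> TrainedModel:
    d = data.proteins[0].d
    rng = np.random.default_rng(seed)
    pooler_seed = int(rng.integers(2 ** 31))
    pooler_params = None
    if config.pooler in ("swe", "swe_simple"):
        pooler_params = init_swe_params(d, config.m, config.L,
                                        freeze=config.freeze, seed=pooler_seed)
    L_out = pooler_params.L if pooler_params is not None else d
    task = config.task
    if task in ("dti", "affinity"):
        if data.drugs is None:
            raise ValueError(f"task {task!r} needs drug fingerprints in the dataset")
        head = DTIHeadParams.init(c=data.drugs.shape[1], d=L_out, D=config.D, rng=rng)
    elif task == "scl":
        head = MulticlassHeadParams.init(L_out, rng=rng)
    else:
        head = ECHeadParams.init(L_out, rng=rng)
    return TrainedModel(config=config, pooler_params=pooler_params, head=head, d=d)


def _trainable(model: TrainedModel) -> dict:
    """Flat name -> array view of every trainable parameter."""
    params = {}
    pp = model.pooler_params
    if pp is not None:
        params["pool.combiner"] = pp.combiner
        if not pp.freeze_ref_and_slicers:
            params["pool.slicers"] = pp.slicers
            params["pool.ref_slices"] = pp.ref_slices
    head = model.head
    if isinstance(head, DTIHeadParams):
        params["head.drug_proj"] = head.drug_proj
        params["head.target_proj"] = head.target_proj
    elif isinstance(head, MulticlassHeadParams):
        params["head.class_matrix"] = head.class_matrix
    else:
        for name in ("layer1", "bias1", "layer2", "bias2"):
            params[f"head.{name}"] = getattr(head, name)
    return params


def _head_loss(model: TrainedModel, v, drug, y):
    task = model.config.task
    if task == "dti":
        return model.head.loss_and_grads(v, drug, int(y), mode="interaction")
    if task == "affinity":
        return model.head.loss_and_grads(v, drug, float(y), mode="affinity")
    if task == "scl":
        return model.head.loss_and_grads(v, int(y))
    return model.head.loss_and_grads(v, int(y))


def sample_gradients(model: TrainedModel, X: TokenEmbeddingSet, y, drug=None):
    """Loss and flat gradient dict for one sample (pooler + head jointly)."""
    if model.pooler_params is not None:
        pooled, backward = swe_pool_with_grad(X, model.pooler_params)
        v = pooled.vector
    else:
        v, backward = model.pool(X), None
    loss, head_grads, dv = _head_loss(model, v, drug, y)
    grads = {f"head.{k}": g for k, g in head_grads.items()}
    if backward is not None:
        pg = backward(dv)
        grads["pool.combiner"] = pg.combiner
        if pg.slicers is not None:
            grads["pool.slicers"] = pg.slicers
            grads["pool.ref_slices"] = pg.ref_slices
    return loss, grads


# ---------------------------------------------------------------------------
# scoring and metrics

def predict_scores(model: TrainedModel, data: SyntheticDataset, indices) -> np.ndarray:
    """Scores for the given protein indices (probability / affinity / logits)."""
    indices = np.asarray(indices)
    if model.config.task == "scl":
        return np.stack([model.logits(data.proteins[i]) for i in indices])
    drugs = data.drugs
    return np.array([
        model.score(data.proteins[i], None if drugs is None else drugs[i])
        for i in indices
    ])


def compute_metric(task: str, scores, labels, metric: str | None = None) -> float:
    """The task's metric (or an explicit one) from scores and ground truth."""
    metric = metric or VALIDATION_METRIC[task]
    if metric == "AUPR":
        return metric_binary_curves(scores, labels)[0]
    if metric == "AUROC":
        return metric_binary_curves(scores, labels)[1]
    if metric == "PCC":
        return metric_pcc(scores, labels)
    if metric == "accuracy":
        if task == "scl":
            return accuracy_top1(scores, labels)
        return metric_binary_curves(scores, labels)[2]
    if metric == "Fmax":
        return metric_fmax(scores, labels)
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# training

def train_erm(config: RunConfig, data: SyntheticDataset, seed: int):
    """Minimize the mean task loss over the train split; track validation per epoch.

    Returns (model, history).  ``model`` carries the parameters of the
    epoch with the best validation metric (final parameters if no epoch
    improved or epochs == 0); ``history`` has per-epoch train loss and
    validation metric plus the index of the best epoch.  A fixed seed
    reproduces the run bit-for-bit.
    """
    model = _build_model(config, data, seed)
    params = _trainable(model)
    history = {"train_loss": [], "val_metric": [], "best_epoch": None}
    if config.epochs == 0:
        return model, history

    rng = np.random.default_rng(seed + 1)
    opt = Adam(params, lr=config.learning_rate)
    train_idx = data.split["train"]
    val_idx = data.split["val"]
    val_labels = data.labels[val_idx]
    drugs = data.drugs

    best_val = -np.inf
    best_snapshot = None
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, order.size, config.batch_size):
            batch = order[start:start + config.batch_size]
            acc: dict = {}
            for i in batch:
                drug = None if drugs is None else drugs[i]
                loss, grads = sample_gradients(model, data.proteins[i],
                                               data.labels[i], drug)
                losses.append(loss)
                for k, g in grads.items():
                    if k in acc:
                        acc[k] += g
                    else:
                        acc[k] = g.copy()
            for k in acc:
                acc[k] /= batch.size
            opt.step(acc)
        mean_loss = float(np.mean(losses))
        if not np.isfinite(mean_loss):
            raise DivergedRunError(epoch)
        try:
            val = compute_metric(config.task,
                                 predict_scores(model, data, val_idx), val_labels)
        except UndefinedMetricError:
            val = np.nan
        history["train_loss"].append(mean_loss)
        history["val_metric"].append(float(val))
        if np.isfinite(val) and val > best_val:
            best_val = val
            best_snapshot = {k: v.copy() for k, v in params.items()}
            history["best_epoch"] = epoch

    if best_snapshot is not None:
        for k, v in best_snapshot.items():
            params[k][...] = v
    return model, history


def evaluate_seeds(config: RunConfig, data: SyntheticDataset,
                   metric: str | None = None) -> MetricReport:
    """Train once per seed, evaluate on the test split, report mean and std."""
    if not config.seeds:
        raise ValueError("need at least one seed")
    metric = metric or VALIDATION_METRIC[config.task]
    test_idx = data.split["test"]
    test_labels = data.labels[test_idx]
    vals = []
    for seed in config.seeds:
        model, _ = train_erm(config, data, seed)
        vals.append(compute_metric(config.task,
                                   predict_scores(model, data, test_idx),
                                   test_labels, metric))
    return make_metric_report(metric, vals)


# ---------------------------------------------------------------------------
# grid selection

@dataclass(frozen=True)
class GridResult:
    per_config: tuple            # (m, freeze, best validation value)
    selected: tuple              # (m, freeze)
    test_report: MetricReport


def select_best(entries) -> tuple:
    """Argmax over (m, freeze, value) rows; ties prefer smaller m, then frozen.

    The deterministic tie-break keeps grid selection reproducible.
    """
    entries = list(entries)
    if not entries:
        raise ValueError("empty validation table")
    best = max(entries, key=lambda e: (e[2], -e[0], bool(e[1])))
    return (best[0], bool(best[1]))


def grid_search_select(configs, data: SyntheticDataset,
                       metric: str | None = None) -> GridResult:
    """Train every configuration, pick the best validation value over all epochs,
    then evaluate the winner over its seeds on the test split."""
    configs = list(configs)
    if not configs:
        raise ValueError("empty configuration list")
    table = []
    by_key = {}
    for cfg in configs:
        _, history = train_erm(cfg, data, cfg.seeds[0])
        vals = [v for v in history["val_metric"] if np.isfinite(v)]
        best_val = max(vals) if vals else -np.inf
        table.append((cfg.m, cfg.freeze, best_val))
        by_key[(cfg.m, cfg.freeze)] = cfg
    selected = select_best(table)
    report = evaluate_seeds(by_key[selected], data, metric)
    return GridResult(per_config=tuple(table), selected=selected, test_report=report)


# ---------------------------------------------------------------------------
# length-stratified gains

@dataclass(frozen=True)
class ScoredResult:
    """Per-protein scores and labels of one method, with sequence lengths."""

    scores: np.ndarray
    labels: np.ndarray
    lengths: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.float64)
        l = np.asarray(self.labels)
        n = np.asarray(self.lengths)
        if not (s.size == l.size == n.size):
            raise ValueError("scores, labels and lengths must align")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", l)
        object.__setattr__(self, "lengths", n)


def quartile_bins(lengths) -> list:
    """Four half-open length bins at the quartiles (last bin closed at the max)."""
    lengths = np.asarray(lengths)
    qs = np.quantile(lengths, [0.0, 0.25, 0.5, 0.75, 1.0])
    return [(float(qs[i]), float(qs[i + 1])) for i in range(4)]


def length_stratified_gains(results_a: ScoredResult, results_b: ScoredResult,
                            bins=None, metric: str = "AUPR") -> list:
    """Per-length-bin metric for two methods and their difference (a minus b).

    Bins follow the quartiles of the length distribution unless given.
    A bin whose labels contain a single class is flagged undefined and its
    delta is NaN.
    """
    if not np.array_equal(results_a.lengths, results_b.lengths) or \
            not np.array_equal(results_a.labels, results_b.labels):
        raise ValueError("both result sets must cover the same proteins")
    if bins is None:
        bins = quartile_bins(results_a.lengths)
    lengths = results_a.lengths
    out = []
    for j, (lo, hi) in enumerate(bins):
        last = j == len(bins) - 1
        mask = (lengths >= lo) & ((lengths <= hi) if last else (lengths < hi))
        row = {"bin": (lo, hi), "n": int(mask.sum()), "defined": False,
               "metric_a": np.nan, "metric_b": np.nan, "delta": np.nan}
        if mask.sum() >= 2:
            labels = results_a.labels[mask]
            try:
                ma = compute_metric("ec", results_a.scores[mask], labels, metric)
                mb = compute_metric("ec", results_b.scores[mask], labels, metric)
                row.update(defined=True, metric_a=float(ma), metric_b=float(mb),
                           delta=float(ma - mb))
            except UndefinedMetricError:
                pass
        out.append(row)
    return out
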