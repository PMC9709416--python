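"""Class-incremental learning: task splits, sequential training, forgetting.

Tasks partition the label set (``disjoint``: 2 tasks x half the classes;
``split``: tasks of 2 consecutive classes).  Training visits tasks strictly
in order with no access to earlier tasks' data; a single shared classifier
head over all classes is used throughout, and every task is evaluated on
its own held-out split after each task (the evaluation matrix) and after
each epoch (learning curves).

The learning-rate schedule divides the rate by 3 after five consecutive
epochs without validation-loss improvement, floored at 1e-4.  Optional
consolidation: elastic weight consolidation (diagonal-Fisher quadratic
anchor added to each layer's local update) and mean/mode parameter merging
of per-task snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import core
from .errors import ConfigurationError, StructureError
from .network import NetworkSpec, copy_params, init_params
from .training import TrainConfig, accuracy, mean_loss, train_epoch

METHODS = ("sgd", "ewc", "imm_mean", "imm_mode")


@dataclass
class Task:
    classes: tuple
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class TaskSequence:
    tasks: list
    scheme: str

    def __len__(self):
        return len(self.tasks)


@dataclass
class ScheduleState:
    """Reduce-on-plateau state: lr /= 3 after ``patience`` flat epochs."""

    lr: float
    best: float = np.inf
    since: int = 0
    floor: float = 1e-4
    patience: int = 5
    factor: float = 1.0 / 3.0


def plateau_schedule(state: ScheduleState, val_loss: float) -> ScheduleState:
    """Advance the schedule by one epoch given the new validation loss."""
    s = replace(state)
    if val_loss < s.best:
        s.best = val_loss
        s.since = 0
        return s
    s.since += 1
    if s.since >= s.patience:
        s.lr = max(s.lr * s.factor, s.floor)
        s.since = 0
    return s


def build_task_sequence(train_labels, test_labels, scheme="split", seed=0,
                        quota_per_class=None) -> TaskSequence:
    """Partition the classes into ordered tasks and collect their indices.

    ``disjoint`` puts the first half of the (sorted) classes in task 1 and
    the rest in task 2; ``split`` makes tasks of 2 consecutive classes.
    ``quota_per_class`` optionally subsamples the training indices of each
    class (seeded, uniform), mirroring a fixed per-task training budget.
    """
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    classes = np.unique(train_labels)
    if scheme == "disjoint":
        per_task = len(classes) // 2
        if len(classes) % 2:
            raise ConfigurationError("disjoint scheme needs an even class count")
    elif scheme == "split":
        per_task = 2
        if len(classes) % 2:
            raise ConfigurationError("split scheme needs an even class count")
    else:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    tasks = []
    for start in range(0, len(classes), per_task):
        group = tuple(int(c) for c in classes[start:start + per_task])
        tr = np.flatnonzero(np.isin(train_labels, group))
        if quota_per_class is not None:
            keep = []
            for c in group:
                idx = np.flatnonzero(train_labels == c)
                take = min(quota_per_class, len(idx))
                keep.append(rng.choice(idx, size=take, replace=False))
            tr = np.sort(np.concatenate(keep))
        te = np.flatnonzero(np.isin(test_labels, group))
        if len(tr) == 0 or len(te) == 0:
            raise ConfigurationError(f"task {group} has no data")
        tasks.append(Task(group, tr, te))
    return TaskSequence(tasks, scheme)


# ---------------------------------------------------------------------------
# consolidation

@dataclass
class EWCPenalty:
    """Quadratic anchor lam/2 * sum_k F_k (theta - theta*_k)^2."""

    anchors: list = field(default_factory=list)  # (params*, fisher) pairs
    lam: float = 100.0

    def grad_hook(self, params, grads: core.GradientSet):
        """Subtract the penalty gradient from each layer's local increment."""
        for anchor, fisher in self.anchors:
            for i, g in enumerate(grads.layers):
                for k in g:
                    g[k] = g[k] - self.lam * fisher[i][k] * (params[i][k] - anchor[i][k])


def estimate_fisher(spec, params, X, y, objective, n_samples=200, seed=0):
    """Diagonal Fisher: mean squared per-sample objective gradient."""
    rng = np.random.default_rng(seed)
    take = rng.choice(len(X), size=min(n_samples, len(X)), replace=False)
    fisher = None
    for j in take:
        g = core.bp_gradient(spec, params, X[j:j + 1], np.asarray(y)[j:j + 1],
                             objective)
        if fisher is None:
            fisher = [{k: v ** 2 for k, v in layer.items()} for layer in g.layers]
        else:
            for fi, gi in zip(fisher, g.layers):
                for k in fi:
                    fi[k] += gi[k] ** 2
    for fi in fisher:
        for k in fi:
            fi[k] /= len(take)
    return fisher


def ewc_consolidate(penalty: EWCPenalty, spec, params, X, y, objective,
                    n_samples=200, seed=0) -> EWCPenalty:
    """Anchor the current parameters with their estimated Fisher."""
    if penalty.lam < 0:
        raise ConfigurationError("EWC lambda must be nonnegative")
    fisher = estimate_fisher(spec, params, X, y, objective,
                             n_samples=n_samples, seed=seed)
    penalty.anchors.append((copy_params(params), fisher))
    return penalty


def imm_merge(snapshots, mode="mean", fishers=None):
    """Merge per-task parameter snapshots.

    ``mean`` is the unweighted average; ``mode`` weights each snapshot by
    its diagonal Fisher (precision-weighted average).
    """
    if len(snapshots) < 2:
        raise ConfigurationError("imm_merge needs at least 2 snapshots")
    for s in snapshots[1:]:
        for a, b in zip(snapshots[0], s):
            for k in a:
                if a[k].shape != b[k].shape:
                    raise StructureError("snapshot shapes differ")
    if mode == "mean":
        out = copy_params(snapshots[0])
        for s in snapshots[1:]:
            for o, p in zip(out, s):
                for k in o:
                    o[k] = o[k] + p[k]
        for o in out:
            for k in o:
                o[k] = o[k] / len(snapshots)
        return out
    if mode != "mode":
        raise ConfigurationError(f"unknown merge mode {mode!r}")
    if fishers is None or len(fishers) != len(snapshots):
        raise ConfigurationError("mode merging needs one Fisher per snapshot")
    eps = 1e-12
    out = copy_params(snapshots[0])
    for o in out:
        for k in o:
            o[k] = np.zeros_like(o[k])
    for o_idx, o in enumerate(out):
        for k in o:
            total = sum(f[o_idx][k] for f in fishers) + eps
            for s, f in zip(snapshots, fishers):
                o[k] = o[k] + f[o_idx][k] * s[o_idx][k]
            o[k] = o[k] / total
    return out


# ---------------------------------------------------------------------------
# sequential training

@dataclass
class IncrementalConfig:
    """Defaults follow the incremental protocol of the study this package
    reproduces: batch 64, BP lr 0.05 / PC weight lr 0.1 with the /3 plateau
    schedule floored at 1e-4, 20 fixed-prediction inference iterations."""

    train: TrainConfig = field(default_factory=TrainConfig)
    lr0: float | None = None          # initial lr; defaults per algorithm
    epochs_per_task: int = 20
    val_fraction: float = 0.1
    patience: int = 5
    lr_floor: float = 1e-4
    ewc_lambda: float = 100.0
    fisher_samples: int = 200


def default_config(algorithm, **overrides) -> IncrementalConfig:
    """Protocol defaults: weight lr 0.1 (PC) / 0.05 (BP), batch 64, both
    trained on softmax cross-entropy (coupled through the output error node
    under PC) so the comparison isolates the learning algorithm."""
    if algorithm == "pc":
        train = TrainConfig(algorithm="pc", objective="cross_entropy",
                            eta_theta=0.1, batch_size=64)
        lr0 = 0.1
    else:
        train = TrainConfig(algorithm="bp", objective="cross_entropy",
                            eta_theta=0.05, batch_size=64)
        lr0 = 0.05
    cfg = IncrementalConfig(train=train, lr0=lr0)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def evaluate_all_tasks(spec, params, X_test, y_test, task_seq: TaskSequence,
                       up_to_task, masked=True) -> list:
    """Accuracy (%) on each seen task's held-out split.

    The classifier head is shared over all classes; with ``masked=True``
    (the reporting convention of the benchmark tables this package mirrors)
    the argmax for task t is restricted to task t's own classes, so a fully
    forgotten binary task reads ~50%, not ~0%.  ``masked=False`` gives the
    strict class-incremental argmax over every class.
    """
    from .training import predict_logits

    row = []
    for t in range(up_to_task):
        task = task_seq.tasks[t]
        idx = task.test_idx
        if masked:
            logits = predict_logits(spec, params, X_test[idx])
            cls = np.asarray(task.classes)
            pred = cls[logits[:, cls].argmax(axis=1)]
            row.append(100.0 * float((pred == y_test[idx]).mean()))
        else:
            row.append(accuracy(spec, params, X_test[idx], y_test[idx]))
    return row


def average_accuracy(row) -> float:
    """Unweighted mean of a final evaluation row, 2 decimals (half-up)."""
    from .reporting import round2
    row = list(row)
    if not row:
        raise ConfigurationError("empty evaluation row")
    return round2(float(np.mean(row)))


def forgetting(matrix) -> float:
    """Drop of task-1 accuracy from its diagonal value to the final row."""
    return matrix[0][0] - matrix[-1][0]


def train_sequential(spec: NetworkSpec, X_train, y_train, X_test, y_test,
                     task_seq: TaskSequence, algorithm="pc", method="sgd",
                     config: IncrementalConfig | None = None, seeds=(0,),
                     record_history=True, masked=True, _touched=None):
    """Train the task sequence in order for each seed.

    Returns a dict with per-seed evaluation matrices (rows after each task,
    computed with the best-validation model of that task), per-epoch
    histories, and the final parameters of the last seed.  ``_touched``
    (a list) collects the training indices each task actually used, for
    data-isolation audits.
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}")
    cfg = config if config is not None else default_config(algorithm)
    tcfg = replace(cfg.train, algorithm=algorithm)
    results = {"matrices": [], "histories": [], "seeds": list(seeds)}
    final_params = None
    for seed in seeds:
        rng = np.random.default_rng(seed)
        params = init_params(spec, seed=seed)
        matrix = []
        history = []
        snapshots = []
        fishers = []
        penalty = EWCPenalty(lam=cfg.ewc_lambda) if method == "ewc" else None
        for t, task in enumerate(task_seq.tasks):
            idx = task.train_idx.copy()
            rng.shuffle(idx)
            n_val = max(1, int(round(cfg.val_fraction * len(idx))))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            if _touched is not None:
                _touched.append((t, tr_idx.copy(), val_idx.copy()))
            Xtr, ytr = X_train[tr_idx], y_train[tr_idx]
            Xval, yval = X_train[val_idx], y_train[val_idx]
            sched = ScheduleState(lr=cfg.lr0 if cfg.lr0 is not None
                                  else tcfg.eta_theta,
                                  floor=cfg.lr_floor, patience=cfg.patience)
            hook = penalty.grad_hook if penalty and penalty.anchors else None
            best_acc, best_params = -1.0, copy_params(params)
            for epoch in range(cfg.epochs_per_task):
                params, tr_loss = train_epoch(spec, params, Xtr, ytr, tcfg,
                                              rng, lr=sched.lr, grad_hook=hook)
                val_loss = mean_loss(spec, params, Xval, yval, tcfg.objective)
                val_acc = accuracy(spec, params, Xval, yval)
                if val_acc > best_acc:
                    best_acc, best_params = val_acc, copy_params(params)
                stop = (sched.lr <= cfg.lr_floor)  # early stop at the lr floor
                if record_history:
                    history.append({
                        "seed": seed, "task": t + 1, "epoch": epoch + 1,
                        "lr": sched.lr, "train_loss": tr_loss,
                        "val_loss": val_loss, "val_acc": val_acc,
                        "seen_task_acc": evaluate_all_tasks(
                            spec, params, X_test, y_test, task_seq, t + 1,
                            masked=masked)})
                sched = plateau_schedule(sched, val_loss)
                if stop:
                    break
            params = best_params  # continue from the best-validation model
            if method == "ewc":
                penalty = ewc_consolidate(
                    penalty, spec, params, Xtr, ytr, tcfg.objective,
                    n_samples=cfg.fisher_samples, seed=seed + t)
            if method in ("imm_mean", "imm_mode"):
                snapshots.append(copy_params(params))
                if method == "imm_mode":
                    fishers.append(estimate_fisher(
                        spec, params, Xtr, ytr, tcfg.objective,
                        n_samples=cfg.fisher_samples, seed=seed + t))
            eval_params = params
            if method in ("imm_mean", "imm_mode") and len(snapshots) >= 2:
                eval_params = imm_merge(
                    snapshots, mode="mean" if method == "imm_mean" else "mode",
                    fishers=fishers if method == "imm_mode" else None)
            matrix.append(evaluate_all_tasks(spec, eval_params, X_test,
                                             y_test, task_seq, t + 1,
                                             masked=masked))
        if method in ("imm_mean", "imm_mode") and len(snapshots) >= 2:
            params = imm_merge(snapshots,
                               mode="mean" if method == "imm_mean" else "mode",
                               fishers=fishers if method == "imm_mode" else None)
        results["matrices"].append(matrix)
        results["histories"].append(history)
        final_params = params
    results["final_params"] = final_params
    return results


def results_to_frame(results, algorithm, method):
    """Tidy frame: seed, algorithm, method, task_trained, task_evaluated, accuracy."""
    import pandas as pd

    rows = []
    for seed, matrix in zip(results["seeds"], results["matrices"]):
        for t_trained, row in enumerate(matrix, 1):
            for t_eval, acc in enumerate(row, 1):
                rows.append({"seed": seed, "algorithm": algorithm,
                             "method": method, "task_trained": t_trained,
                             "task_evaluated": t_eval, "accuracy": acc})
    return pd.DataFrame(rows)
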