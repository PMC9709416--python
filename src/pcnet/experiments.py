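"""Canonical experiment drivers shared by the CLI, tests and scripts.

The synthetic study conditions live here so every entry point runs the same
suites:

* ``equivalence``   — fixed-prediction PC weight updates vs chain-rule
  gradients on random small networks.
* ``energy descent`` — free-energy monotonicity with re-evaluated
  predictions.
* ``incremental``   — the 5-task split suite: 10 synthetic classes, 8x8
  single-channel templates, 200 train / 100 test per class, noise sigma
  chosen so a single task trains to roughly 90% accuracy, PC vs BP over
  5 seeds with the published learning rates.
* ``stability sweep`` — the same suite across a BP learning-rate grid.
* ``fewshot calibration`` — untrained prototypical encoder vs chance on a
  synthetic character bank.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import core, fewshot, incremental, longtail, synthdata
from .architectures import make_mlp3, make_protonet4
from .network import NetworkSpec, LayerSpec, init_params
from .objectives import ObjectiveConfig, one_hot

# --- frozen synthetic study conditions -------------------------------------
INC_CLASSES = 10
INC_IMAGE_SHAPE = (1, 8, 8)
INC_TRAIN_PER_CLASS = 200
INC_TEST_PER_CLASS = 100
INC_SIGMA = 3.5          # calibrated for ~90% single-task accuracy
INC_HIDDEN = 64
INC_EPOCHS_PER_TASK = 20
INC_SEEDS = (0, 1, 2, 3, 4)

LT_SIGMA = 1.5           # long-tail suite: near-ceiling base difficulty
LT_EPOCHS = 100

FS_CLASSES = 50
FS_VARIANTS = 20
FS_IMAGE_SHAPE = (1, 16, 16)
FS_SIGMA = 1.0
FS_CHANNELS = 16


def _rel_err(a, b):
    na = float(np.linalg.norm(np.asarray(a).ravel() - np.asarray(b).ravel()))
    return na / max(float(np.linalg.norm(np.asarray(b).ravel())), 1e-12)


def gradset_rel_err(pc_grads: core.GradientSet, bp_grads: core.GradientSet):
    """Max layerwise relative error between PC increments and -BP gradients."""
    worst = 0.0
    for gpc, gbp in zip(pc_grads.layers, bp_grads.layers):
        for k in gbp:
            worst = max(worst, _rel_err(gpc[k], -gbp[k]))
    return worst


def random_mlp_spec(rng, max_layers=3, max_units=32, min_layers=2):
    n_layers = int(rng.integers(min_layers, max_layers + 1))
    dims = [int(rng.integers(2, max_units + 1)) for _ in range(n_layers + 1)]
    layers = []
    for i in range(n_layers):
        nl = "relu" if i < n_layers - 1 else "identity"
        layers.append(LayerSpec("affine", (dims[i],), (dims[i + 1],), nl))
    return NetworkSpec(tuple(layers))


def pc_equilibrium_gradients(spec, params, x, y, objective, eta_v=0.5,
                             max_iters=2000, tol=1e-10):
    """Fixed-prediction inference to tolerance, then local weight updates."""
    state = core.forward_pass(spec, params, x)
    n_out = int(np.prod(spec.out_shape))
    target = one_hot(y, n_out) if objective == "squared_error" else y
    core.clamp_target(state, target, objective)
    state, trace = core.run_inference(state, spec, params, eta_v=eta_v,
                                      max_iters=max_iters, tol=tol,
                                      fixed_predictions=True)
    return core.weight_gradient(state, spec, params), trace


def run_equivalence(n_networks=50, seed=0, objectives=("squared_error",
                                                       "cross_entropy")):
    """Max relative error between PC and BP weight updates over random nets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    per_objective = {}
    for obj in objectives:
        obj_worst = 0.0
        for _ in range(n_networks):
            spec = random_mlp_spec(rng)
            params = init_params(spec, seed=int(rng.integers(2 ** 31)))
            B = int(rng.integers(1, 5))
            x = rng.standard_normal((B,) + spec.in_shape)
            y = rng.integers(0, int(np.prod(spec.out_shape)), size=B)
            pc_grads, _ = pc_equilibrium_gradients(spec, params, x, y, obj)
            n_out = int(np.prod(spec.out_shape))
            target = one_hot(y, n_out) if obj == "squared_error" else y
            bp = core.bp_gradient(spec, params, x, target, obj)
            obj_worst = max(obj_worst, gradset_rel_err(pc_grads, bp))
        per_objective[obj] = obj_worst
        worst = max(worst, obj_worst)
    return {"max_rel_err": worst, "per_objective": per_objective,
            "n_networks": n_networks * len(objectives)}


def run_energy_descent(n_instances=100, seed=0, eta_v=0.05, n_iters=20):
    """Fraction of random instances with non-increasing free energy when
    predictions are re-evaluated each inference step."""
    rng = np.random.default_rng(seed)
    monotone = 0
    max_violation = 0.0
    for _ in range(n_instances):
        spec = random_mlp_spec(rng, max_units=16)
        params = init_params(spec, seed=int(rng.integers(2 ** 31)))
        B = int(rng.integers(1, 5))
        x = rng.standard_normal((B,) + spec.in_shape)
        y = rng.standard_normal((B,) + spec.out_shape)
        state = core.forward_pass(spec, params, x)
        core.clamp_target(state, y, "squared_error")
        f_prev = core.free_energy(state)
        ok = True
        for t in range(n_iters):
            state = core.inference_step(state, spec, params, eta_v,
                                        fixed_predictions=False)
            f = core.free_energy(state)
            if f > f_prev + 1e-10:
                ok = False
                max_violation = max(max_violation, f - f_prev)
            f_prev = f
        monotone += ok
    return {"fraction_monotone": monotone / n_instances,
            "max_violation": max_violation, "n_instances": n_instances}


def run_fd_check(n_networks=10, seed=0, h=1e-6):
    """Central finite differences vs the chain-rule backward pass."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_networks):
        spec = random_mlp_spec(rng, max_units=8)
        params = init_params(spec, seed=int(rng.integers(2 ** 31)))
        B = 3
        x = rng.standard_normal((B,) + spec.in_shape)
        n_out = int(np.prod(spec.out_shape))
        y = rng.integers(0, n_out, size=B)
        obj = "cross_entropy" if rng.random() < 0.5 else "squared_error"
        target = one_hot(y, n_out) if obj == "squared_error" else y
        grads = core.bp_gradient(spec, params, x, target, obj)
        from .training import mean_loss
        for li, layer_g in enumerate(grads.layers):
            for key, g in layer_g.items():
                flat_idx = rng.integers(0, g.size, size=min(5, g.size))
                for fi in flat_idx:
                    idx = np.unravel_index(fi, g.shape)
                    orig = params[li][key][idx]
                    params[li][key][idx] = orig + h
                    lp = mean_loss(spec, params, x, target, obj)
                    params[li][key][idx] = orig - h
                    lm = mean_loss(spec, params, x, target, obj)
                    params[li][key][idx] = orig
                    fd = (lp - lm) / (2 * h)
                    denom = max(abs(fd), abs(g[idx]), 1e-6)
                    worst = max(worst, abs(fd - g[idx]) / denom)
    return {"max_rel_err": worst, "n_networks": n_networks}


# ---------------------------------------------------------------------------
# incremental suite

def incremental_suite(seed=0):
    """The synthetic 5-task split suite (shared by tests and the CLI)."""
    bank = synthdata.make_templates(INC_CLASSES, INC_IMAGE_SHAPE, seed=seed)
    train_counts = np.full(INC_CLASSES, INC_TRAIN_PER_CLASS)
    test_counts = np.full(INC_CLASSES, INC_TEST_PER_CLASS)
    X_train, y_train = synthdata.sample_dataset(bank, train_counts,
                                                sigma=INC_SIGMA, seed=seed + 1)
    X_test, y_test = synthdata.sample_dataset(bank, test_counts,
                                              sigma=INC_SIGMA, seed=seed + 2)
    task_seq = incremental.build_task_sequence(y_train, y_test, "split",
                                               seed=seed)
    spec = make_mlp3(input_dim=int(np.prod(INC_IMAGE_SHAPE)),
                     hidden_width=INC_HIDDEN, classes=INC_CLASSES)
    return {"spec": spec, "X_train": X_train, "y_train": y_train,
            "X_test": X_test, "y_test": y_test, "task_seq": task_seq,
            "bank": bank}


def run_incremental_comparison(seeds=INC_SEEDS, seed=0, method="sgd",
                               epochs_per_task=INC_EPOCHS_PER_TASK,
                               record_history=False):
    """PC-SGD vs BP-SGD on the synthetic split suite.

    Returns final average accuracy and task-1 forgetting per algorithm,
    with per-seed values for paired comparisons.
    """
    suite = incremental_suite(seed=seed)
    out = {"suite_seed": seed, "seeds": list(seeds)}
    for algo in ("pc", "bp"):
        cfg = incremental.default_config(algo)
        cfg.epochs_per_task = epochs_per_task
        res = incremental.train_sequential(
            suite["spec"], suite["X_train"], suite["y_train"],
            suite["X_test"], suite["y_test"], suite["task_seq"],
            algorithm=algo, method=method, config=cfg, seeds=seeds,
            record_history=record_history)
        finals = [np.mean(m[-1]) for m in res["matrices"]]
        forgets = [incremental.forgetting(m) for m in res["matrices"]]
        out[algo] = {"matrices": res["matrices"],
                     "avg_final_acc": float(np.mean(finals)),
                     "avg_final_per_seed": [float(f) for f in finals],
                     "forgetting": float(np.mean(forgets)),
                     "forgetting_per_seed": [float(f) for f in forgets],
                     "histories": res["histories"]}
    return out


def run_stability_sweep(lrs=(0.01, 0.001, 0.0001), seeds=INC_SEEDS, seed=0,
                        algorithm="bp", epochs_per_task=INC_EPOCHS_PER_TASK,
                        masked=False):
    """Incremental suite across a learning-rate grid; forgetting vs plasticity.

    Uses the strict class-incremental (unmasked, shared-head) evaluation by
    default: forgetting there is dominated by the drift of the shared head,
    which is exactly the component the learning rate grades.
    """
    if len(lrs) == 0:
        raise ValueError("learning-rate grid must not be empty")
    suite = incremental_suite(seed=seed)
    out = {"lrs": list(lrs), "algorithm": algorithm, "results": []}
    for lr in lrs:
        cfg = incremental.default_config(algorithm)
        cfg.lr0 = lr
        cfg.train = replace(cfg.train, eta_theta=lr)
        cfg.epochs_per_task = epochs_per_task
        res = incremental.train_sequential(
            suite["spec"], suite["X_train"], suite["y_train"],
            suite["X_test"], suite["y_test"], suite["task_seq"],
            algorithm=algorithm, method="sgd", config=cfg, seeds=seeds,
            record_history=False, masked=masked)
        forgets = [incremental.forgetting(m) for m in res["matrices"]]
        final_task = [m[-1][-1] for m in res["matrices"]]
        avg_final = [np.mean(m[-1]) for m in res["matrices"]]
        out["results"].append({
            "lr": lr,
            "forgetting": float(np.mean(forgets)),
            "final_task_acc": float(np.mean(final_task)),
            "avg_final_acc": float(np.mean(avg_final)),
            "matrices": res["matrices"]})
    return out


# ---------------------------------------------------------------------------
# few-shot suite

def fewshot_suite(seed=0):
    bank = synthdata.make_fewshot_bank(FS_CLASSES, FS_VARIANTS,
                                       FS_IMAGE_SHAPE, sigma=FS_SIGMA,
                                       seed=seed)
    spec = make_protonet4(input_shape=FS_IMAGE_SHAPE, channels=FS_CHANNELS)
    return {"bank": bank, "spec": spec}


def run_fewshot_calibration(Ns=(5, 10, 20, 30), ks=(1, 5), episodes=1000,
                            seed=0):
    """Few-shot evaluation calibration on the synthetic character bank.

    Two measurements per (N, k) cell:

    * ``encoder`` — the untrained (random-init) prototypical encoder.  Its
      accuracy is far above chance (random convolutional features preserve
      input similarity) but must be monotone: non-increasing in N,
      non-decreasing in k.
    * ``uninformative`` — input-independent random embeddings, the control
      for which episode accuracy must sit at chance (100/N %) within
      sampling error; this validates that the episode machinery is
      unbiased.
    """
    suite = fewshot_suite(seed=seed)
    params = init_params(suite["spec"], seed=seed)
    grid = {}
    blind_grid = {}
    for N in Ns:
        for k in ks:
            grid[(N, k)] = fewshot.evaluate_fewshot(
                suite["spec"], params, suite["bank"], N, k,
                episodes=episodes, seed=seed + 17 * N + k)
            blind_grid[(N, k)] = fewshot.chance_calibration(
                N, k, episodes=episodes, seed=seed + 31 * N + k)
    return {"grid": grid, "uninformative": blind_grid, "episodes": episodes}


# ---------------------------------------------------------------------------
# long-tailed suite

def run_longtail_experiment(gamma=100, objective="cross_entropy", n_max=200,
                            epochs=LT_EPOCHS, algorithms=("pc", "bp"), seed=0,
                            hidden=64, bp_grid=None, sigma=LT_SIGMA):
    """Scaled long-tailed comparison on synthetic 10-class data.

    BP picks its learning rate from the configured grid (best overall
    balanced accuracy, the reference protocol); PC uses its fixed rate.
    """
    bank = synthdata.make_templates(INC_CLASSES, INC_IMAGE_SHAPE, seed=seed)
    profile = longtail.longtail_counts(n_max, gamma, INC_CLASSES)
    balanced = np.full(INC_CLASSES, n_max)
    X_all, y_all = synthdata.sample_dataset(bank, balanced, sigma=sigma,
                                            seed=seed + 1)
    X_tr, y_tr = longtail.subsample_to_profile(X_all, y_all, profile,
                                               seed=seed + 2)
    X_te, y_te = synthdata.sample_dataset(
        bank, np.full(INC_CLASSES, INC_TEST_PER_CLASS), sigma=sigma,
        seed=seed + 3)
    spec = make_mlp3(input_dim=int(np.prod(INC_IMAGE_SHAPE)),
                     hidden_width=hidden, classes=INC_CLASSES)
    obj = objective if isinstance(objective, ObjectiveConfig) \
        else ObjectiveConfig(name=objective)
    cfg = longtail.LongtailConfig(objective=obj, epochs=epochs, batch_size=64)
    if bp_grid is not None:
        cfg.bp_lr_grid = tuple(bp_grid)
    out = {"gamma": gamma, "profile": profile.counts.tolist()}
    for algo in algorithms:
        # both algorithms search the same weight-learning-rate grid at this
        # scale (the tiny suite has ~60x fewer steps than the benchmark the
        # published fixed rates were chosen for)
        best = None
        for lr in cfg.bp_lr_grid:
            c = replace(cfg, bp_lr=lr, pc_eta_theta=lr)
            res = longtail.train_longtail(spec, X_tr, y_tr, X_te, y_te,
                                          algorithm=algo, config=c, seed=seed)
            if best is None or res["overall"] > best[1]["overall"]:
                best = (lr, res)
        lr, res = best
        out[f"{algo}_lr"] = lr
        out[algo] = {"overall": res["overall"],
                     "per_class": res["per_class"].tolist()}
    return out
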