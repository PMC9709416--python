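"""Class-incremental learning: task builders, schedule, consolidation."""

import numpy as np
import pytest

from dataclasses import replace

from pcnet import incremental, synthdata
from pcnet.architectures import make_mlp3
from pcnet.errors import ConfigurationError
from pcnet.incremental import (EWCPenalty, ScheduleState, average_accuracy,
                               build_task_sequence, default_config,
                               estimate_fisher, forgetting,
                               imm_merge, plateau_schedule, train_sequential)
from pcnet.network import copy_params, init_params


@pytest.fixture(scope="module")
def tiny_suite():
    """Small 10-class dataset + MLP used across the training tests."""
    bank = synthdata.make_templates(10, (1, 6, 6), seed=0)
    Xtr, ytr = synthdata.sample_dataset(bank, np.full(10, 40), sigma=1.0, seed=1)
    Xte, yte = synthdata.sample_dataset(bank, np.full(10, 20), sigma=1.0, seed=2)
    spec = make_mlp3(input_dim=36, hidden_width=24, classes=10)
    return spec, Xtr, ytr, Xte, yte


class TestTaskBuilders:
    def test_disjoint_two_tasks_in_label_order(self):
        y = np.repeat(np.arange(10), 5)
        ts = build_task_sequence(y, y, "disjoint")
        assert [t.classes for t in ts.tasks] == [(0, 1, 2, 3, 4),
                                                 (5, 6, 7, 8, 9)]

    def test_split_five_tasks_of_two(self):
        y = np.repeat(np.arange(10), 5)
        ts = build_task_sequence(y, y, "split")
        assert len(ts) == 5
        assert [t.classes for t in ts.tasks] == [(0, 1), (2, 3), (4, 5),
                                                 (6, 7), (8, 9)]

    def test_split_task_sizes(self):
        y = np.repeat(np.arange(10), 100)
        ts = build_task_sequence(y, y, "split")
        assert all(len(t.train_idx) == 200 for t in ts.tasks)

    def test_quota_subsampling(self):
        y = np.repeat(np.arange(10), 100)
        ts = build_task_sequence(y, y, "split", seed=1, quota_per_class=30)
        assert all(len(t.train_idx) == 60 for t in ts.tasks)

    def test_odd_class_count_rejected(self):
        y = np.repeat(np.arange(9), 5)
        with pytest.raises(ConfigurationError):
            build_task_sequence(y, y, "split")


class TestPlateauSchedule:
    def test_improving_losses_keep_lr(self):
        s = ScheduleState(lr=0.05)
        for loss in (1.0, 0.9, 0.8, 0.7, 0.6, 0.5):
            s = plateau_schedule(s, loss)
        assert s.lr == 0.05

    def test_five_flat_epochs_divide_by_three(self):
        s = ScheduleState(lr=0.05)
        s = plateau_schedule(s, 1.0)
        for _ in range(5):
            s = plateau_schedule(s, 1.0)
        assert s.lr == pytest.approx(0.05 / 3)

    def test_lr_never_below_floor(self):
        s = ScheduleState(lr=0.05)
        for _ in range(200):
            s = plateau_schedule(s, 1.0)
        assert s.lr == pytest.approx(1e-4)


class TestReporting:
    def test_average_of_published_split_row(self):
        assert average_accuracy([99.89, 97.09, 99.28, 99.39, 98.37]) == 98.80

    def test_average_of_published_disjoint_row(self):
        assert average_accuracy([75.68, 97.11]) == 86.40

    def test_identical_entries(self):
        assert average_accuracy([88.8, 88.8, 88.8]) == 88.80

    def test_empty_row_rejected(self):
        with pytest.raises(ConfigurationError):
            average_accuracy([])


class TestSequentialTraining:
    def test_single_task_degenerates_to_ordinary_training(self, tiny_suite):
        spec, Xtr, ytr, Xte, yte = tiny_suite
        ts = build_task_sequence(ytr, yte, "disjoint")
        single = incremental.TaskSequence([ts.tasks[0]], "disjoint")
        cfg = default_config("bp")
        cfg.epochs_per_task = 10
        cfg.train = replace(cfg.train, batch_size=16)
        res = train_sequential(spec, Xtr, ytr, Xte, yte, single,
                               algorithm="bp", config=cfg, seeds=(0,),
                               record_history=False)
        assert len(res["matrices"][0]) == 1
        assert res["matrices"][0][0][0] > 60.0  # well above chance

    def test_eval_row_length_matches_tasks_seen(self, tiny_suite):
        spec, Xtr, ytr, Xte, yte = tiny_suite
        ts = build_task_sequence(ytr, yte, "split")
        cfg = default_config("pc")
        cfg.epochs_per_task = 2
        res = train_sequential(spec, Xtr, ytr, Xte, yte, ts, algorithm="pc",
                               config=cfg, seeds=(0,), record_history=False)
        for t, row in enumerate(res["matrices"][0], 1):
            assert len(row) == t

    def test_data_isolation(self, tiny_suite):
        """Training on task t only ever touches task t's own indices."""
        spec, Xtr, ytr, Xte, yte = tiny_suite
        ts = build_task_sequence(ytr, yte, "split")
        cfg = default_config("bp")
        cfg.epochs_per_task = 2
        touched = []
        train_sequential(spec, Xtr, ytr, Xte, yte, ts, algorithm="bp",
                         config=cfg, seeds=(0,), record_history=False,
                         _touched=touched)
        for t, tr_idx, val_idx in touched:
            allowed = set(ts.tasks[t].train_idx)
            assert set(tr_idx) <= allowed and set(val_idx) <= allowed
            assert not (set(tr_idx) & set(val_idx))

    def test_repeated_task_does_not_degrade(self, tiny_suite):
        """Re-training the same task leaves its accuracy intact."""
        spec, Xtr, ytr, Xte, yte = tiny_suite
        ts = build_task_sequence(ytr, yte, "disjoint")
        twice = incremental.TaskSequence([ts.tasks[0], ts.tasks[0]],
                                         "disjoint")
        cfg = default_config("bp")
        cfg.epochs_per_task = 6
        cfg.train = replace(cfg.train, batch_size=16)
        res = train_sequential(spec, Xtr, ytr, Xte, yte, twice,
                               algorithm="bp", config=cfg, seeds=(0, 1, 2),
                               record_history=False)
        for m in res["matrices"]:
            assert m[1][0] >= m[0][0] - 6.0  # seed noise only

    def test_diagonal_beats_chance_for_both_algorithms(self, tiny_suite):
        spec, Xtr, ytr, Xte, yte = tiny_suite
        ts = build_task_sequence(ytr, yte, "split")
        for algo in ("pc", "bp"):
            cfg = default_config(algo)
            cfg.epochs_per_task = 6
            cfg.train = replace(cfg.train, batch_size=16)
            res = train_sequential(spec, Xtr, ytr, Xte, yte, ts,
                                   algorithm=algo, config=cfg, seeds=(0,),
                                   record_history=False)
            m = res["matrices"][0]
            diag = [m[t][t] for t in range(len(m))]
            assert min(diag) > 60.0, algo

    def test_forgetting_metric_from_matrix(self):
        m = [[95.0], [80.0, 96.0]]
        assert forgetting(m) == pytest.approx(15.0)


class TestEWC:
    def test_lambda_zero_matches_plain_sgd(self, tiny_suite):
        spec, Xtr, ytr, Xte, yte = tiny_suite
        ts = build_task_sequence(ytr, yte, "disjoint")
        cfg = default_config("bp")
        cfg.epochs_per_task = 2
        cfg.ewc_lambda = 0.0
        a = train_sequential(spec, Xtr, ytr, Xte, yte, ts, algorithm="bp",
                             method="ewc", config=cfg, seeds=(0,),
                             record_history=False)
        b = train_sequential(spec, Xtr, ytr, Xte, yte, ts, algorithm="bp",
                             method="sgd", config=cfg, seeds=(0,),
                             record_history=False)
        for pa, pb in zip(a["final_params"], b["final_params"]):
            np.testing.assert_allclose(pa["W"], pb["W"], rtol=1e-12)

    def test_anchor_point_has_zero_penalty_gradient(self, tiny_suite):
        spec, Xtr, ytr, _, _ = tiny_suite
        params = init_params(spec, seed=0)
        fisher = estimate_fisher(spec, params, Xtr, ytr, "cross_entropy",
                                 n_samples=20, seed=0)
        pen = EWCPenalty(lam=100.0)
        pen.anchors.append((copy_params(params), fisher))
        from pcnet.core import GradientSet
        grads = GradientSet([{k: np.zeros_like(v) for k, v in p.items()
                              if k in ("W", "b")} for p in params])
        pen.grad_hook(params, grads)
        for g in grads.layers:
            for v in g.values():
                np.testing.assert_allclose(v, 0.0)

    def test_large_lambda_trades_stability_for_plasticity(self, tiny_suite):
        spec, Xtr, ytr, Xte, yte = tiny_suite
        ts = build_task_sequence(ytr, yte, "disjoint")
        rows = {}
        for method, lam in (("sgd", 0.0), ("ewc", 100.0)):
            accs_t1, accs_t2 = [], []
            for seed in range(3):
                cfg = default_config("bp")
                cfg.epochs_per_task = 8
                cfg.ewc_lambda = lam
                cfg.train = replace(cfg.train, batch_size=16)
                res = train_sequential(spec, Xtr, ytr, Xte, yte, ts,
                                       algorithm="bp", method=method,
                                       config=cfg, seeds=(seed,),
                                       record_history=False, masked=False)
                accs_t1.append(res["matrices"][0][1][0])
                accs_t2.append(res["matrices"][0][1][1])
            rows[method] = (np.mean(accs_t1), np.mean(accs_t2))
        assert rows["ewc"][0] > rows["sgd"][0]   # retains task 1 better
        assert rows["ewc"][1] < rows["sgd"][1]   # at some cost on task 2


class TestIMM:
    def test_identical_snapshots_unchanged(self, small_params=None):
        params = [{"W": np.arange(6.0).reshape(2, 3), "b": np.zeros(2)}]
        merged = imm_merge([copy_params(params), copy_params(params)], "mean")
        np.testing.assert_allclose(merged[0]["W"], params[0]["W"])

    def test_mean_of_opposite_params_is_zero(self):
        p = [{"W": np.ones((2, 2)), "b": np.ones(2)}]
        n = [{"W": -np.ones((2, 2)), "b": -np.ones(2)}]
        merged = imm_merge([p, n], "mean")
        np.testing.assert_allclose(merged[0]["W"], 0.0)

    def test_mode_with_dominant_fisher_approaches_that_snapshot(self):
        a = [{"W": np.full((2, 2), 3.0), "b": np.zeros(2)}]
        b = [{"W": np.full((2, 2), -1.0), "b": np.zeros(2)}]
        fa = [{"W": np.full((2, 2), 1e6), "b": np.ones(2)}]
        fb = [{"W": np.full((2, 2), 1e-6), "b": np.ones(2)}]
        merged = imm_merge([a, b], "mode", fishers=[fa, fb])
        np.testing.assert_allclose(merged[0]["W"], 3.0, rtol=1e-5)

    def test_shape_mismatch_rejected(self):
        from pcnet.errors import StructureError
        a = [{"W": np.zeros((2, 2)), "b": np.zeros(2)}]
        b = [{"W": np.zeros((3, 2)), "b": np.zeros(2)}]
        with pytest.raises(StructureError):
            imm_merge([a, b], "mean")
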