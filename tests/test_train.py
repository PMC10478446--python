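"""Losses, validation metric, optimization behaviour, head isolation."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from rtlogd.featurize import mol_to_graph, scaffold_split, SplitAssignment
from rtlogd.net import ModelConfig, batch_graphs, build_model
from rtlogd.synthdata import SynthConfig, generate
from rtlogd.train import (
    Adam,
    TaskLabels,
    TrainConfig,
    _masked_batch_loss,
    avg_squared_pearson,
    check_split_leakage,
    finetune_multitask,
    masked_multitask_loss,
    pretrain_rt,
    smooth_l1,
)


class TestSmoothL1:
    @pytest.mark.parametrize("d,expected", [(0.0, 0.0), (0.5, 0.125), (2.0, 1.5),
                                            (-0.5, 0.125), (-2.0, 1.5), (1.0, 0.5)])
    def test_values(self, d, expected):
        assert smooth_l1(d, 0.0, beta=1.0) == pytest.approx(expected)

    def test_beta_scaling(self):
        assert smooth_l1(0.5, 0.0, beta=2.0) == pytest.approx(0.0625)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            smooth_l1(float("inf"), 0.0)


class TestMaskedLoss:
    def test_single_label_omits_other(self):
        lab = TaskLabels(logd=1.0)
        assert masked_multitask_loss((2.0, 99.0), lab) == pytest.approx(0.5)

    def test_dual_label_mean(self):
        # residuals chosen so the per-task losses are 0.2 and 0.4 -> mean 0.3
        d1, d2 = (2 * 0.2) ** 0.5, (2 * 0.4) ** 0.5  # quadratic branch: 0.5 d^2
        lab = TaskLabels(logd=0.0, logp=0.0)
        assert masked_multitask_loss((d1, d2), lab) == pytest.approx(0.3)

    def test_zero_residuals(self):
        assert masked_multitask_loss((1.0, 2.0), TaskLabels(logd=1.0, logp=2.0)) == 0.0

    def test_no_labels_rejected(self):
        with pytest.raises(ValueError):
            TaskLabels()

    def test_batch_loss_ignores_masked_slot_value(self):
        model = build_model(ModelConfig(hidden_dim=8, n_heads_out=2), seed=1)
        batch = batch_graphs([mol_to_graph("CCO"), mol_to_graph("CCN")])
        preds = model.forward(batch)
        mask = np.array([[1.0, 0.0], [0.0, 1.0]])
        t1 = np.array([[1.0, 123.0], [456.0, 2.0]])
        t2 = np.array([[1.0, -9.0], [0.1, 2.0]])
        a = _masked_batch_loss(preds, t1, mask, 1.0).data
        b = _masked_batch_loss(preds, t2, mask, 1.0).data
        assert a == pytest.approx(b)


class TestAvgSquaredPearson:
    def test_perfect_is_one(self):
        t = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 3.0]])
        m = np.ones_like(t)
        assert avg_squared_pearson(t.copy(), t, m) == pytest.approx(1.0)

    def test_mean_of_two_tasks(self):
        targets = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.5], [3.0, 0.7]])
        preds = targets.copy()
        preds[:, 1] = [0.3, -0.1, 0.25, 0.05]  # weakly related second task
        m = np.ones_like(targets)
        r1 = pearsonr(targets[:, 1], preds[:, 1]).statistic ** 2
        assert avg_squared_pearson(preds, targets, m) == pytest.approx((1.0 + r1) / 2)

    def test_matches_independent_pearson(self):
        rng = np.random.default_rng(0)
        targets = rng.normal(size=(40, 2))
        preds = targets + rng.normal(size=(40, 2))
        mask = (rng.random((40, 2)) < 0.8).astype(float)
        expected = np.mean([
            pearsonr(targets[mask[:, t] > 0, t], preds[mask[:, t] > 0, t]).statistic ** 2
            for t in range(2)
        ])
        assert avg_squared_pearson(preds, targets, mask) == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_rejected(self):
        t = np.array([[1.0, 1.0], [1.0, 2.0]])
        with pytest.raises(ValueError):
            avg_squared_pearson(t, t, np.ones_like(t))


@pytest.fixture(scope="module")
def tiny_dataset():
    recs = generate(SynthConfig(n_molecules=120, seed=21, label_missingness=0.2))
    smiles = [r.smiles for r in recs]
    graphs = [mol_to_graph(s) for s in smiles]
    labels = [TaskLabels(logd=r.logd_obs, logp=r.logp_obs) for r in recs]
    split = scaffold_split(smiles, (8, 1, 1), seed=21)
    return recs, graphs, labels, split


class TestPretrain:
    def test_loss_decreases_and_deterministic(self, tiny_dataset):
        recs, graphs, _, _ = tiny_dataset
        rt = np.array([r.rt_obs for r in recs])
        cfg = TrainConfig(max_epochs=8, patience=8, batch_size=32, seed=3)
        mc = ModelConfig(hidden_dim=16, n_heads_out=1)
        a = pretrain_rt(graphs, rt, mc, cfg)
        b = pretrain_rt(graphs, rt, mc, cfg)
        val = batch_graphs(graphs[:10])
        assert (a.forward(val).data == b.forward(val).data).all()
        # best-epoch model beats the untrained one on its own objective
        init = build_model(mc, seed=cfg.seed)
        y = (rt - rt.mean()) / rt.std()
        def loss(m):
            p = m.forward(batch_graphs(graphs)).data.ravel()
            return float(np.mean([smooth_l1(pi, yi) for pi, yi in zip(p, y)]))
        assert loss(a) < loss(init)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            pretrain_rt([], np.array([]), ModelConfig(hidden_dim=8), TrainConfig())


class TestFinetune:
    def test_gradient_isolation_between_heads(self):
        model = build_model(ModelConfig(hidden_dim=8, n_heads_out=2), seed=7)
        batch = batch_graphs([mol_to_graph(s) for s in ["CCO", "CCN", "CCC"]])
        targets = np.array([[1.0, 0.0], [0.5, 0.0], [2.0, 0.0]])
        mask = np.array([[1.0, 0.0]] * 3)  # logD labels only
        model.zero_grad()
        _masked_batch_loss(model.forward(batch, training=True,
                                         dropout_rng=np.random.default_rng(0)),
                           targets, mask, 1.0).backward()
        assert (model.params["head.w"].grad[:, 1] == 0).all()
        assert (model.params["head.w"].grad[:, 0] != 0).any()
        before = model.params["head.w"].data[:, 1].copy()
        Adam(model.params, lr=1e-2, weight_decay=0.0).step()
        assert (model.params["head.w"].data[:, 1] == before).all()

    def test_lr_reduced_when_pretrained(self, tiny_dataset, monkeypatch):
        recs, graphs, labels, split = tiny_dataset
        rt = np.array([r.rt_obs for r in recs])
        mc = ModelConfig(hidden_dim=8, n_heads_out=1)
        pre = pretrain_rt(graphs, rt, mc, TrainConfig(max_epochs=1, patience=1, seed=0))
        seen = {}
        import rtlogd.train as trainmod
        orig = trainmod.Adam
        def spy(params, lr, wd=0.0, **kw):
            seen["lr"] = lr
            return orig(params, lr, wd, **kw)
        monkeypatch.setattr(trainmod, "Adam", spy)
        cfg = TrainConfig(lr=1e-3, max_epochs=1, patience=1, seed=0)
        finetune_multitask(pre, graphs, labels, split, cfg)
        assert seen["lr"] == pytest.approx(1e-4)
        finetune_multitask(None, graphs, labels, split, cfg, mc)
        assert seen["lr"] == pytest.approx(1e-3)

    def test_split_leakage_hard_error(self, tiny_dataset):
        _, graphs, labels, split = tiny_dataset
        leaky = SplitAssignment(split.train, split.valid, split.train[:1],
                                split.scaffold_of)
        with pytest.raises(ValueError, match="leakage"):
            finetune_multitask(None, graphs, labels, leaky, TrainConfig(),
                               ModelConfig(hidden_dim=8))

    def test_early_stopping_patience(self, tiny_dataset, monkeypatch):
        recs, graphs, labels, split = tiny_dataset
        calls = []
        import rtlogd.train as trainmod

        def flat_score(preds, targets, mask):
            calls.append(1)
            return 0.5  # never improves after the first epoch

        monkeypatch.setattr(trainmod, "avg_squared_pearson", flat_score)
        cfg = TrainConfig(max_epochs=50, patience=3, seed=1)
        model = finetune_multitask(None, graphs, labels, split, cfg,
                                   ModelConfig(hidden_dim=8, n_heads_out=2))
        # one improving epoch + `patience` stale epochs, then stop
        assert len(calls) == 1 + cfg.patience
        assert model.training_meta["best_epoch"] == 0

    def test_end_to_end_seeded_determinism(self, tiny_dataset):
        recs, graphs, labels, split = tiny_dataset
        cfg = TrainConfig(max_epochs=3, patience=3, batch_size=32, seed=9)
        mc = ModelConfig(hidden_dim=8, n_heads_out=2)
        a = finetune_multitask(None, graphs, labels, split, cfg, mc)
        b = finetune_multitask(None, graphs, labels, split, cfg, mc)
        assert (a.predict(graphs[:10]) == b.predict(graphs[:10])).all()
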