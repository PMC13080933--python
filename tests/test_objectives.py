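"""Objectives: contrastive, matching, docking losses, mining, composition."""

import numpy as np
import pytest

from pocketformer import objectives
from pocketformer.model import ProjectionHead
from pocketformer.nn import Tensor
from pocketformer.objectives import (DockingLossConfig, LossReport,
                                     contrastive_loss, huber, inter_loss,
                                     intra_loss, matching_loss,
                                     mine_hard_negatives, similarity,
                                     total_loss)


@pytest.fixture
def head():
    return ProjectionHead(8, 4, np.random.default_rng(0), np.float64)


class TestSimilarity:
    def test_parallel_projections_give_one(self, head):
        v = Tensor(np.random.default_rng(1).normal(0, 1, 8))
        # make g_M mimic g_P so both project identically
        head.wm.data = head.wp.data.copy()
        head.bm.data = head.bp.data.copy()
        assert similarity(v, v, head).data == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_projections_give_zero(self, head):
        head.wp.data = np.zeros((8, 4))
        head.wm.data = np.zeros((8, 4))
        head.bp.data = np.array([1.0, 0, 0, 0])
        head.bm.data = np.array([0.0, 1.0, 0, 0])
        v = Tensor(np.ones(8))
        assert similarity(v, v, head).data == pytest.approx(0.0, abs=1e-12)

    def test_bounded_on_random_pairs(self, head):
        rng = np.random.default_rng(2)
        for _ in range(200):
            s = similarity(Tensor(rng.normal(0, 3, 8)),
                           Tensor(rng.normal(0, 3, 8)), head).data
            assert -1.0 - 1e-9 <= float(s) <= 1.0 + 1e-9

    def test_zero_norm_projection_rejected(self, head):
        head.wp.data = np.zeros((8, 4))
        head.bp.data = np.zeros(4)
        with pytest.raises(ValueError, match="zero-norm"):
            similarity(Tensor(np.ones(8)), Tensor(np.ones(8)), head)


class TestContrastive:
    def test_single_pair_loss_zero(self, head):
        rng = np.random.default_rng(3)
        l, _ = contrastive_loss(Tensor(rng.normal(0, 1, (1, 8))),
                                Tensor(rng.normal(0, 1, (1, 8))), head)
        assert float(l.data) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_similarities_give_log_n(self, head):
        # identical pockets and molecules -> a constant similarity matrix
        p = Tensor(np.tile(np.random.default_rng(4).normal(0, 1, 8), (4, 1)))
        m = Tensor(np.tile(np.random.default_rng(5).normal(0, 1, 8), (4, 1)))
        l, _ = contrastive_loss(p, m, head)
        assert float(l.data) == pytest.approx(np.log(4), abs=1e-6)

    def test_matches_scalar_loop_on_hand_matrix(self):
        # bypass projections: evaluate the softmax-CE composition directly
        S = np.array([[0.9, 0.1, -0.4],
                      [0.2, 0.8, 0.0],
                      [-0.3, 0.5, 0.6]])
        tau = 1.0
        l = objectives._diag_cross_entropy(Tensor(S / tau))
        lT = objectives._diag_cross_entropy(Tensor(S.T / tau))
        got = 0.5 * (float(l.data) + float(lT.data))
        expect = 0.0
        for axis in (1, 0):
            M = S if axis == 1 else S.T
            for i in range(3):
                p = np.exp(M[i] / tau) / np.exp(M[i] / tau).sum()
                expect += -np.log(p[i]) / 2
        expect /= 3
        assert got == pytest.approx(expect, abs=1e-6)

    def test_empty_batch_rejected(self, head):
        with pytest.raises(ValueError):
            contrastive_loss(Tensor(np.zeros((0, 8))),
                             Tensor(np.zeros((0, 8))), head)

    def test_permutation_invariance(self, head):
        rng = np.random.default_rng(6)
        P = Tensor(rng.normal(0, 1, (5, 8)))
        M = Tensor(rng.normal(0, 1, (5, 8)))
        l1, _ = contrastive_loss(P, M, head)
        perm = rng.permutation(5)
        l2, _ = contrastive_loss(Tensor(P.data[perm]), Tensor(M.data[perm]),
                                 head)
        assert float(l1.data) == pytest.approx(float(l2.data), abs=1e-10)

    def test_decreases_as_diagonal_strengthens(self):
        rng = np.random.default_rng(7)
        S = rng.normal(0, 0.3, (4, 4))
        losses = []
        for boost in (0.0, 0.5, 1.0, 2.0):
            M = S + boost * np.eye(4)
            l = 0.5 * (float(objectives._diag_cross_entropy(Tensor(M)).data) +
                       float(objectives._diag_cross_entropy(Tensor(M.T)).data))
            losses.append(l)
        assert np.all(np.diff(losses) < 0)


class TestMining:
    def test_single_pair_yields_nothing(self):
        assert mine_hard_negatives(np.zeros((1, 1)),
                                   np.random.default_rng(0)) == []

    def test_argmax_picks_highest_off_diagonal(self):
        S = np.array([[9.0, 0.1, 0.7],
                      [0.8, 9.0, 0.2],
                      [0.3, 0.9, 9.0]])
        out = mine_hard_negatives(S, np.random.default_rng(0),
                                  strategy="argmax")
        # pocket-side picks per row, molecule-side per column
        assert out[:3] == [(0, 2), (1, 0), (2, 1)]
        assert out[3:] == [(1, 0), (2, 1), (0, 2)]

    def test_never_returns_diagonal_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            S = rng.normal(0, 1, (5, 5))
            for i, j in mine_hard_negatives(S, rng):
                assert i != j

    def test_sampling_is_deterministic_under_seed(self):
        S = np.random.default_rng(2).normal(0, 1, (6, 6))
        a = mine_hard_negatives(S, np.random.default_rng(42))
        b = mine_hard_negatives(S, np.random.default_rng(42))
        assert a == b


class TestMatching:
    def test_saturated_logits_near_zero_loss(self):
        l = matching_loss(Tensor(np.array([[-20.0, 20.0]])), np.array([1]))
        assert float(l.data) < 1e-8

    def test_uniform_logits_give_log_two(self):
        l = matching_loss(Tensor(np.zeros((3, 2))), np.array([0, 1, 0]))
        assert float(l.data) == pytest.approx(np.log(2), abs=1e-7)

    def test_matches_scalar_loop(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(0, 2, (8, 2))
        labels = rng.integers(0, 2, 8)
        got = float(matching_loss(Tensor(logits), labels).data)
        expect = 0.0
        for row, lab in zip(logits, labels):
            p = np.exp(row - row.max())
            p /= p.sum()
            expect += -np.log(p[lab])
        assert got == pytest.approx(expect / 8, abs=1e-6)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            matching_loss(Tensor(np.zeros((1, 2))), np.array([2]))


class TestDockingLosses:
    def test_huber_branch_values(self):
        cfg = DockingLossConfig(delta=1.0)
        a = Tensor(np.array([0.5, 3.0, -3.0]))
        out = huber(a, cfg.delta).data
        np.testing.assert_allclose(out, [0.125, 2.5, 2.5], atol=1e-12)

    def test_huber_continuous_at_threshold(self):
        delta = 1.3
        below = huber(Tensor(np.array([delta - 1e-9])), delta).data[0]
        above = huber(Tensor(np.array([delta + 1e-9])), delta).data[0]
        assert below == pytest.approx(delta ** 2 / 2, abs=1e-7)
        assert above == pytest.approx(delta ** 2 / 2, abs=1e-7)

    def test_intra_zero_for_exact_prediction(self):
        coords = np.random.default_rng(0).normal(0, 2, (5, 3))
        l = intra_loss(Tensor(coords), coords, DockingLossConfig())
        assert float(l.data) == pytest.approx(0.0, abs=1e-9)

    def test_intra_single_pair_branches(self):
        cfg = DockingLossConfig(delta=1.0)
        true = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        for offset, expect in ((0.5, 0.125), (3.0, 2.5)):
            pred = np.array([[0.0, 0, 0], [1.0 + offset, 0, 0]])
            l = intra_loss(Tensor(pred), true, cfg)
            assert float(l.data) == pytest.approx(expect, abs=1e-9)

    def test_intra_single_atom_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            l = intra_loss(Tensor(np.zeros((1, 3))), np.zeros((1, 3)),
                           DockingLossConfig())
        assert float(l.data) == 0.0

    def test_inter_examples(self):
        pred = np.array([[1.0, 0, 0]])
        true = np.zeros((1, 3))
        assert float(inter_loss(Tensor(pred), true).data) == pytest.approx(1.0)
        assert float(inter_loss(Tensor(true), true).data) == 0.0

    def test_inter_matches_scalar_loop(self):
        rng = np.random.default_rng(5)
        pred, true = rng.normal(0, 2, (6, 3)), rng.normal(0, 2, (6, 3))
        got = float(inter_loss(Tensor(pred), true).data)
        expect = np.mean([((p - t) ** 2).sum() for p, t in zip(pred, true)])
        assert got == pytest.approx(expect, abs=1e-9)

    def test_inter_shape_mismatch(self):
        with pytest.raises(ValueError):
            inter_loss(Tensor(np.zeros((2, 3))), np.zeros((3, 3)))


class TestTotalLoss:
    def test_zero_components_zero_total(self):
        assert total_loss().total == 0.0

    def test_sum_of_components(self):
        rep = total_loss(1.0, 2.0, 3.0, 4.0)
        assert rep.total == 10.0

    def test_additivity_on_random_reports(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            parts = rng.uniform(0, 5, 4)
            rep = total_loss(*parts)
            assert rep.total == parts.sum()

    def test_nonfinite_component_identified(self):
        with pytest.raises(FloatingPointError, match="l_intra"):
            total_loss(1.0, 2.0, np.inf, 0.0)


class TestLossSymmetries:
    def test_losses_invariant_under_joint_rigid_motion(self, tiny_pair,
                                                       desk_model):
        from conftest import apply_rigid, random_rigid
        from pocketformer.objectives import inter_loss, intra_loss
        rng = np.random.default_rng(9)
        R, t = random_rigid(rng)
        pred = tiny_pair.true_ligand_coords + rng.normal(0, 0.5, (6, 3))
        cfg = DockingLossConfig()
        li = float(intra_loss(Tensor(pred), tiny_pair.true_ligand_coords,
                              cfg).data)
        le = float(inter_loss(Tensor(pred), tiny_pair.true_ligand_coords).data)
        pred_t = pred @ R.T + t
        truth_t = tiny_pair.true_ligand_coords @ R.T + t
        assert float(intra_loss(Tensor(pred_t), truth_t, cfg).data) == \
            pytest.approx(li, abs=1e-8)
        assert float(inter_loss(Tensor(pred_t), truth_t).data) == \
            pytest.approx(le, abs=1e-8)

    def test_gradients_finite_on_random_batch(self, desk_model, tiny_spec):
        import pocketformer as pf
        rng = np.random.default_rng(10)
        pairs = [pf.generate_complex(tiny_spec, rng, pair_id=f"g{i}")
                 for i in range(3)]
        cfg = pf.TrainConfig(
            backbone=desk_model.cfg,
            optimizer=pf.OptimizerConfig(peak_lr=1e-3, min_lr=1e-5,
                                         warmup_steps=2, total_steps=10,
                                         batch_size=3),
            seed=0)
        trainer = pf.Trainer(desk_model, cfg)
        trainer.train_step(pairs)
        for name, p in desk_model.parameters().items():
            if p.grad is not None:
                assert np.all(np.isfinite(p.grad)), name
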