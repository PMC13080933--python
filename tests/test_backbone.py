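"""Backbone: RBF pair features, pair-biased attention, heads.

Oracle tests re-implement each operation with nested scalar loops in
float64 and demand 1e-6 agreement on small instances; symmetry tests
check SE(3) invariance / equivariance and permutation consistency.
"""

import numpy as np
import pytest

from conftest import apply_rigid, random_rigid
from pocketformer import nn
from pocketformer.backbone import (AttentionBlock, BackboneConfig,
                                   CoordinateHead, EncoderOutput, rbf_encode)
from pocketformer.graphs import AtomGraph, batch as make_batch
from pocketformer.nn import Tensor


# ---------------------------------------------------------------------------
# RBF
# ---------------------------------------------------------------------------

class TestRbf:
    def test_zero_distance_gives_ones(self):
        out = rbf_encode(np.zeros((2, 2)), np.array([0.1, 1.0, 10.0]))
        np.testing.assert_array_equal(out, np.ones((2, 2, 3)))

    def test_unit_distance_unit_gamma(self):
        out = rbf_encode(np.array([[1.0]]), np.array([1.0]))
        np.testing.assert_allclose(out[0, 0, 0], np.exp(-1.0), rtol=1e-12)

    def test_strictly_decreasing_in_squared_distance(self):
        gammas = np.logspace(-2, 1, 8)
        grid = np.sort(np.random.default_rng(0).uniform(0, 50, 64))
        feats = rbf_encode(grid[None, :], gammas)[0]
        assert np.all(np.diff(feats, axis=0) < 0)
        assert np.all((feats > 0) & (feats <= 1))

    def test_negative_squared_distance_rejected(self):
        with pytest.raises(ValueError):
            rbf_encode(np.array([[-0.1]]), np.array([1.0]))


# ---------------------------------------------------------------------------
# pair initialization
# ---------------------------------------------------------------------------

class TestInitPair:
    def test_rigid_transform_leaves_q0_unchanged(self, f64_model, tiny_pair):
        enc = f64_model.mol_encoder
        rng = np.random.default_rng(0)
        g = tiny_pair.molecule
        q0 = enc.init_pair(make_batch([g])).data
        R, t = random_rigid(rng)
        q0t = enc.init_pair(make_batch([apply_rigid(g, R, t)])).data
        np.testing.assert_allclose(q0t, q0, atol=1e-6)

    def test_bonded_pair_differs_by_bond_embedding(self, f64_model):
        # two atom pairs at the same distance, one bonded
        enc = f64_model.mol_encoder
        g_bond = AtomGraph("molecule", [0, 1], [[0, 0, 0], [1.5, 0, 0]],
                           bonds=((0, 1, 2),))
        g_free = AtomGraph("molecule", [0, 1], [[0, 0, 0], [1.5, 0, 0]])
        qb = enc.init_pair(make_batch([g_bond])).data
        qf = enc.init_pair(make_batch([g_free])).data
        diff = qb[0, 0, 1] - qf[0, 0, 1]
        np.testing.assert_allclose(diff, enc.bond_embed.data[1], atol=1e-12)

    def test_hand_computed_three_atom_instance(self):
        # identity G->H projection, hand-set gammas: q0 equals the RBF values
        cfg = BackboneConfig(layers=1, heads=2, atom_dim=4, rbf_kernels=2,
                             rbf_gammas=np.array([0.5, 2.0]), ffn_dim=8,
                             dtype="float64")
        from pocketformer.backbone import Encoder
        enc = Encoder(cfg, np.random.default_rng(0))
        enc.pair_w.data = np.eye(2)
        enc.pair_b.data = np.zeros(2)
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 2.0, 0]])
        g = AtomGraph("molecule", [0, 0, 0], coords)
        q0 = enc.init_pair(make_batch([g])).data[0]
        for i in range(3):
            for j in range(3):
                d2 = ((coords[i] - coords[j]) ** 2).sum()
                np.testing.assert_allclose(
                    q0[i, j], [np.exp(-0.5 * d2), np.exp(-2.0 * d2)],
                    rtol=1e-12)


# ---------------------------------------------------------------------------
# attention + pair update vs scalar loop oracles
# ---------------------------------------------------------------------------

def oracle_block(block, x, pair, mask):
    """Nested-loop re-implementation of one attention block (float64)."""
    cfg = block.cfg
    B, n, d = x.shape
    H, dh = cfg.heads, cfg.head_dim
    y = np.empty_like(x)
    pair_next = pair.copy()
    logits_all = np.empty((B, H, n, n))
    for b in range(B):
        q = x[b] @ block.wq.data + block.bq.data
        k = x[b] @ block.wk.data + block.bk.data
        v = x[b] @ block.wv.data + block.bv.data
        ctx = np.zeros((n, d))
        for h in range(H):
            qh = q[:, h * dh:(h + 1) * dh]
            kh = k[:, h * dh:(h + 1) * dh]
            vh = v[:, h * dh:(h + 1) * dh]
            for i in range(n):
                logits = np.empty(n)
                for j in range(n):
                    logits[j] = qh[i] @ kh[j] / np.sqrt(dh) + pair[b, i, j, h]
                    pair_next[b, i, j, h] += qh[i] @ kh[j] / np.sqrt(dh)
                logits_all[b, h, i] = logits
                masked = np.where(mask[b], logits, -1e9)
                w = np.exp(masked - masked.max())
                w /= w.sum()
                ctx[i, h * dh:(h + 1) * dh] = w @ vh
        a = x[b] + ctx @ block.wo.data + block.bo.data

        def ln(z, gain, bias):
            mu = z.mean(-1, keepdims=True)
            var = ((z - mu) ** 2).mean(-1, keepdims=True)
            return (z - mu) / np.sqrt(var + 1e-5) * gain + bias

        a = ln(a, block.ln1_g.data, block.ln1_b.data)
        ff = np.maximum(a @ block.w1.data + block.b1.data, 0) \
            @ block.w2.data + block.b2.data
        y[b] = ln(a + ff, block.ln2_g.data, block.ln2_b.data)
    return y, pair_next, logits_all


@pytest.fixture
def small_instance(f64_config):
    rng = np.random.default_rng(5)
    n, d, H = 5, f64_config.atom_dim, f64_config.heads
    x = rng.normal(0, 1, (2, n, d))
    pair = rng.normal(0, 1, (2, n, n, H))
    mask = np.ones((2, n), dtype=bool)
    mask[1, -1] = False
    return x, pair, mask


class TestAttentionOracle:
    def test_block_matches_nested_loop(self, f64_config, small_instance):
        block = AttentionBlock(f64_config, np.random.default_rng(1))
        x, pair, mask = small_instance
        y, pair_next, logits = block(Tensor(x), Tensor(pair), mask)
        oy, opair, ologits = oracle_block(block, x, pair, mask)
        np.testing.assert_allclose(y.data, oy, atol=1e-6)
        np.testing.assert_allclose(pair_next.data, opair, atol=1e-6)
        np.testing.assert_allclose(logits, ologits, atol=1e-6)

    def test_uniform_attention_with_zero_bias_and_equal_keys(self, f64_config):
        block = AttentionBlock(f64_config, np.random.default_rng(1))
        n, d = 4, f64_config.atom_dim
        x = np.ones((1, n, d))  # identical tokens -> identical keys
        pair = np.zeros((1, n, n, f64_config.heads))
        mask = np.ones((1, n), dtype=bool)
        # reproduce just the softmax weights via the oracle loop
        _, _, logits = oracle_block(block, x, pair, mask)
        w = np.exp(logits - logits.max(-1, keepdims=True))
        w /= w.sum(-1, keepdims=True)
        np.testing.assert_allclose(w, 1.0 / n, atol=1e-12)

    def test_large_negative_bias_suppresses_column(self, f64_config):
        block = AttentionBlock(f64_config, np.random.default_rng(1))
        n = 4
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (1, n, f64_config.atom_dim))
        pair = np.zeros((1, n, n, f64_config.heads))
        pair[0, :, 2, :] = -1e9
        mask = np.ones((1, n), dtype=bool)
        _, _, logits = oracle_block(block, x, pair, mask)
        w = np.exp(logits - logits.max(-1, keepdims=True))
        w /= w.sum(-1, keepdims=True)
        assert np.all(w[0, :, :, 2] < 1e-12)

    def test_nan_logits_fail_fast(self, f64_config, small_instance):
        block = AttentionBlock(f64_config, np.random.default_rng(1))
        x, pair, mask = small_instance
        pair = pair.copy()
        pair[0, 0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            block(Tensor(x), Tensor(pair), mask)


class TestPairUpdate:
    def test_zero_queries_leave_pair_unchanged(self, f64_config):
        from pocketformer.backbone import pair_update
        rng = np.random.default_rng(0)
        H, dh, n = f64_config.heads, f64_config.head_dim, 4
        pair = Tensor(rng.normal(0, 1, (1, n, n, H)))
        q = Tensor(np.zeros((1, H, n, dh)))
        k = Tensor(rng.normal(0, 1, (1, H, n, dh)))
        out = pair_update(pair, q, k, dh)
        np.testing.assert_array_equal(out.data, pair.data)

    def test_increment_equals_per_head_logits(self, f64_config):
        from pocketformer.backbone import pair_update
        rng = np.random.default_rng(3)
        H, dh, n = f64_config.heads, f64_config.head_dim, 5
        pair = Tensor(rng.normal(0, 1, (1, n, n, H)))
        q = rng.normal(0, 1, (1, H, n, dh))
        k = rng.normal(0, 1, (1, H, n, dh))
        out = pair_update(pair, Tensor(q), Tensor(k), dh).data
        for h in range(H):
            for i in range(n):
                for j in range(n):
                    expect = pair.data[0, i, j, h] + \
                        q[0, h, i] @ k[0, h, j] / np.sqrt(dh)
                    np.testing.assert_allclose(out[0, i, j, h], expect,
                                               atol=1e-6)


# ---------------------------------------------------------------------------
# full encoder symmetries
# ---------------------------------------------------------------------------

class TestEncoderSymmetries:
    def test_minimal_graph_finite(self, f64_model):
        g = AtomGraph("molecule", [0], [[0.0, 0, 0]])
        enc = f64_model.encode_molecules([g])
        assert np.all(np.isfinite(enc.atom_reps.data))
        assert enc.cls_embedding is not None

    def test_rigid_transform_invariance(self, desk_model, tiny_pair):
        rng = np.random.default_rng(4)
        enc = desk_model.encode_molecules([tiny_pair.molecule])
        R, t = random_rigid(rng)
        enc_t = desk_model.encode_molecules(
            [apply_rigid(tiny_pair.molecule, R, t)])
        np.testing.assert_allclose(enc_t.atom_reps.data, enc.atom_reps.data,
                                   atol=1e-4)
        np.testing.assert_allclose(enc_t.cls_embedding.data,
                                   enc.cls_embedding.data, atol=1e-4)

    def test_permuting_atoms_permutes_outputs(self, f64_model, tiny_pair):
        g = tiny_pair.molecule
        rng = np.random.default_rng(1)
        perm = rng.permutation(g.n_atoms)
        inv = {int(o): n for n, o in enumerate(perm)}
        remap = tuple(sorted(
            (min(inv[i], inv[j]), max(inv[i], inv[j]), c)
            for i, j, c in g.bonds))
        gp = AtomGraph("molecule", g.atom_types[perm], g.coords[perm],
                       bonds=remap)
        e1 = f64_model.encode_molecules([g])
        e2 = f64_model.encode_molecules([gp])
        np.testing.assert_allclose(e2.atom_reps.data[0, :g.n_atoms],
                                   e1.atom_reps.data[0, perm], atol=1e-9)
        np.testing.assert_allclose(e2.cls_embedding.data,
                                   e1.cls_embedding.data, atol=1e-9)

    def test_padding_independence(self, desk_model, tiny_pair, tiny_spec):
        import pocketformer as pf
        other = pf.generate_complex(tiny_spec, np.random.default_rng(9))
        g = tiny_pair.molecule
        solo = desk_model.encode_molecules([g])
        duo = desk_model.encode_molecules([g, other.molecule])
        n = g.n_atoms + 1  # + CLS
        np.testing.assert_allclose(duo.atom_reps.data[0, :n],
                                   solo.atom_reps.data[0], atol=1e-5)
        np.testing.assert_allclose(duo.cls_embedding.data[0],
                                   solo.cls_embedding.data[0], atol=1e-5)


# ---------------------------------------------------------------------------
# coordinate head
# ---------------------------------------------------------------------------

def manual_head_setup():
    """A head whose coupling c_ij equals pair_final channel 0 exactly."""
    cfg = BackboneConfig(layers=1, heads=2, atom_dim=4, rbf_kernels=2,
                         ffn_dim=8, dtype="float64")
    head = CoordinateHead(cfg, np.random.default_rng(0), hidden=1)
    head.u.data = np.array([[1.0], [0.0]])
    head.w.data = np.array([[1.0]])
    return cfg, head


def two_atom_enc(c12):
    g = AtomGraph("molecule", [0, 0], [[0.0, 0, 0], [2.0, 0, 0]])
    gb = make_batch([g])
    H = 2
    q0 = Tensor(np.zeros((1, 2, 2, H)))
    qL = np.zeros((1, 2, 2, H))
    qL[0, 0, 1, 0] = c12
    return gb, EncoderOutput(atom_reps=Tensor(np.zeros((1, 2, 4))),
                             pair_initial=q0, pair_final=Tensor(qL), batch=gb)


class TestCoordinateHead:
    def test_unchanged_pair_track_proposes_no_movement(self):
        _, head = manual_head_setup()
        gb, enc = two_atom_enc(0.0)
        out = head(enc, movable_mask=gb.real_mask)
        np.testing.assert_array_equal(out.data, gb.coords)

    def test_two_atom_hand_evaluation(self):
        # c_12 = 1: x1 <- x1 + (x1 - x2)/2, x2 unchanged (c_21 = 0)
        _, head = manual_head_setup()
        gb, enc = two_atom_enc(1.0)
        out = head(enc, movable_mask=gb.real_mask).data[0]
        np.testing.assert_allclose(out[0], [-1.0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(out[1], [2.0, 0, 0], atol=1e-12)

    def test_se3_equivariance(self, desk_model, tiny_pair):
        rng = np.random.default_rng(8)
        pred = _joint_coords(desk_model, tiny_pair.pocket, tiny_pair.molecule)
        R, t = random_rigid(rng)
        pred_t = _joint_coords(desk_model,
                               apply_rigid(tiny_pair.pocket, R, t),
                               apply_rigid(tiny_pair.molecule, R, t))
        np.testing.assert_allclose(pred_t, pred @ R.T + t, atol=1e-4)

    def test_non_movable_atoms_returned_unchanged(self, desk_model, tiny_pair):
        enc = desk_model.encode_joint([(tiny_pair.pocket, tiny_pair.molecule)])
        out = desk_model.predict_coords(enc).data[0]
        pocket_rows = enc.batch.segments[0] == 0
        expect = enc.batch.coords[0][pocket_rows].astype(out.dtype)
        np.testing.assert_array_equal(out[pocket_rows], expect)


def _joint_coords(model, pocket, molecule):
    enc = model.encode_joint([(pocket, molecule)])
    return model.predict_coords(enc).data[0]


# ---------------------------------------------------------------------------
# distance head
# ---------------------------------------------------------------------------

class TestDistanceHead:
    def test_symmetric_nonneg_zero_diagonal(self, f64_model, tiny_pair):
        enc = f64_model.encode_joint([(tiny_pair.pocket, tiny_pair.molecule)])
        d = f64_model.dist_head(enc).data[0]
        np.testing.assert_allclose(d, d.T, atol=1e-6)
        assert np.all(np.diag(d) == 0) and np.all(d >= 0)

    def test_rigid_transform_invariance(self, f64_model, tiny_pair):
        rng = np.random.default_rng(2)
        enc = f64_model.encode_joint([(tiny_pair.pocket, tiny_pair.molecule)])
        d = f64_model.dist_head(enc).data
        R, t = random_rigid(rng)
        enc_t = f64_model.encode_joint([(apply_rigid(tiny_pair.pocket, R, t),
                                         apply_rigid(tiny_pair.molecule, R, t))])
        dt = f64_model.dist_head(enc_t).data
        np.testing.assert_allclose(dt, d, atol=1e-9)

    def test_matches_scalar_loop(self, f64_model):
        g = AtomGraph("molecule", [0, 1, 2, 0],
                      np.random.default_rng(0).normal(0, 2, (4, 3)),
                      bonds=((0, 1, 1),))
        enc = f64_model.mol_encoder(make_batch([g]))
        d = f64_model.dist_head(enc).data[0]
        q = enc.pair_final.data[0]
        h = f64_model.dist_head
        n = 4
        for i in range(n):
            for j in range(n):
                sym = 0.5 * (q[i, j] + q[j, i])
                z = np.maximum(sym @ h.w1.data + h.b1.data, 0) \
                    @ h.w2.data + h.b2.data
                expect = 0.0 if i == j else np.logaddexp(0.0, z[0])
                np.testing.assert_allclose(d[i, j], expect, atol=1e-6)
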