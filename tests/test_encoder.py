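"""Encoder checks against independent dense (loop-based) oracles, plus the
structural invariants: row-stochastic attention, gate convexity,
permutation equivariance and bounded memory."""

import numpy as np
import pytest

from sarn.autodiff import Tensor
from sarn.encoder import (
    GSALayerParams,
    RecurrentUnitParams,
    SpatialEncodingTable,
    assemble_batch,
    encode_sequence,
    encode_sequence_arrays,
    gsa_layer,
    init_gsa_stack,
    init_recurrent_unit,
    init_spatial_table,
    load_checkpoint,
    recurrent_step,
    save_checkpoint,
    spatial_attention_coefficients,
    window_attention,
)
from sarn.netbuild import build_network, neighbor_mask, spatial_distance_index


# ---------------------------------------------------------------------
# straight-line reference implementations (loops, no autodiff)

def ref_attention(h, W, c, s, neigh_sets, sidx):
    n = h.shape[0]
    hW = h @ W
    d2 = W.shape[1]
    alpha = np.zeros((n, n))
    for i in range(n):
        logits = {}
        for j in neigh_sets[i]:
            logits[j] = np.tanh(
                np.concatenate([hW[i], hW[j]]) @ c + s[sidx[i, j]]
            )
        zmax = max(logits.values())
        denom = sum(np.exp(v - zmax) for v in logits.values())
        for j, v in logits.items():
            alpha[i, j] = np.exp(v - zmax) / denom
    return alpha


def ref_elu(x):
    return np.where(x > 0, x, np.exp(np.minimum(x, 0)) - 1)


def ref_gsa(h, W, c, s, neigh_sets, sidx):
    alpha = ref_attention(h, W, c, s, neigh_sets, sidx)
    return ref_elu(alpha @ (h @ W))


def ref_window_attention(Z, memory, Wq, Wk, dk):
    slots = [Z] + memory
    n, d = Z.shape
    a = np.zeros((n, len(slots)))
    ctx = np.zeros((n, d))
    for i in range(n):
        e = np.array([(Wq.T @ Z[i]) @ (Wk.T @ s[i]) / np.sqrt(dk) for s in slots])
        w = np.exp(e - e.max())
        w /= w.sum()
        a[i] = w
        ctx[i] = sum(wm * s[i] for wm, s in zip(w, slots))
    return a, ctx


def ref_recurrent_step(Z, memory, p):
    H_prev = memory[0] if memory else np.zeros_like(Z)
    _, C = ref_window_attention(Z, memory, p["W_q"], p["W_k"], p["W_q"].shape[1])
    f = 1 / (1 + np.exp(-(Z @ p["W_f"] + C @ p["U_f"] + p["b_f"])))
    Ht = np.tanh(Z @ p["W_h"] + C @ p["U_h"] + p["b_h"])
    return f * H_prev + (1 - f) * Ht


def random_instance(rng, n=4, d_in=3, d_out=3, max_dist=3):
    h = rng.standard_normal((n, d_in))
    params = GSALayerParams(
        W=Tensor(rng.standard_normal((d_in, d_out)) * 0.5, requires_grad=True),
        c=Tensor(rng.standard_normal(2 * d_out) * 0.5, requires_grad=True),
    )
    table = SpatialEncodingTable(
        s=Tensor(rng.standard_normal(max_dist + 2) * 0.3, requires_grad=True)
    )
    a = rng.standard_normal((n, n))
    adj = (a + a.T) / 2
    np.fill_diagonal(adj, 1.0)
    from sarn.netbuild import sparsify_adjacency

    sets = sparsify_adjacency(adj, min(2, n - 1))
    mask = neighbor_mask(sets)
    sidx = spatial_distance_index(sets, max_dist)
    return h, params, table, sets, mask, sidx


class TestSpatialAttention:
    def test_single_neighbor_gives_unit_weight(self, rng):
        h, params, table, _, _, sidx = random_instance(rng, n=3)
        mask = np.eye(3, dtype=bool)  # N(i) = {i}
        alpha = spatial_attention_coefficients(h, params, table, mask, sidx)
        assert np.allclose(np.diag(alpha.data), 1.0)

    def test_identical_neighbors_split_evenly(self):
        h = np.vstack([np.ones(3), np.ones(3), np.ones(3)])
        params = GSALayerParams(
            W=Tensor(np.eye(3), requires_grad=True),
            c=Tensor(np.ones(6), requires_grad=True),
        )
        table = SpatialEncodingTable(s=Tensor(np.zeros(5), requires_grad=True))
        mask = np.array([[True, True, False]] * 3)
        sidx = np.ones((3, 3), dtype=int)
        alpha = spatial_attention_coefficients(h, params, table, mask, sidx)
        assert np.allclose(alpha.data[:, :2], 0.5, atol=1e-12)

    def test_matches_dense_oracle(self, rng):
        for _ in range(5):
            h, params, table, sets, mask, sidx = random_instance(rng)
            alpha = spatial_attention_coefficients(h, params, table, mask, sidx)
            expect = ref_attention(
                h, params.W.data, params.c.data, table.s.data, sets, sidx
            )
            assert np.allclose(alpha.data, expect, atol=1e-6)

    def test_empty_neighborhood_rejected(self, rng):
        h, params, table, _, mask, sidx = random_instance(rng)
        mask = mask.copy()
        mask[1, :] = False
        with pytest.raises(ValueError):
            spatial_attention_coefficients(h, params, table, mask, sidx)


class TestGSALayer:
    def test_zero_features_fixed_point(self, rng):
        _, params, table, _, _, sidx = random_instance(rng, n=3)
        mask = np.eye(3, dtype=bool)
        out = gsa_layer(np.zeros((3, 3)), params, table, mask, sidx)
        assert np.allclose(out.data, 0.0)

    def test_matches_dense_oracle(self, rng):
        for _ in range(5):
            h, params, table, sets, mask, sidx = random_instance(rng)
            out = gsa_layer(h, params, table, mask, sidx)
            expect = ref_gsa(h, params.W.data, params.c.data, table.s.data, sets, sidx)
            assert np.allclose(out.data, expect, atol=1e-6)


class TestWindowAttention:
    def unit(self, rng, d=3, dk=2, w=3):
        return init_recurrent_unit(d, dk, w, rng)

    def test_empty_memory_returns_input(self, rng):
        unit = self.unit(rng)
        Z = Tensor(rng.standard_normal((4, 3)))
        a, ctx = window_attention(Z, [], unit)
        assert np.allclose(a.data, 1.0)
        assert np.allclose(ctx.data, Z.data)

    def test_identical_slots_uniform_attention(self, rng):
        unit = self.unit(rng)
        Z = Tensor(rng.standard_normal((4, 3)))
        a, ctx = window_attention(Z, [Z, Z], unit)
        assert np.allclose(a.data, 1 / 3, atol=1e-12)
        assert np.allclose(ctx.data, Z.data, atol=1e-12)

    def test_matches_scalar_oracle(self, rng):
        unit = self.unit(rng)
        Z = rng.standard_normal((5, 3))
        mem = [Tensor(rng.standard_normal((5, 3))) for _ in range(2)]
        a, ctx = window_attention(Tensor(Z), mem, unit)
        ea, ectx = ref_window_attention(
            Z, [m.data for m in mem], unit.W_q.data, unit.W_k.data, unit.d_k
        )
        assert np.allclose(a.data, ea, atol=1e-6)
        assert np.allclose(ctx.data, ectx, atol=1e-6)


class TestRecurrentStep:
    def test_saturated_forget_gate_keeps_previous_state(self, rng):
        unit = init_recurrent_unit(3, 2, 3, rng)
        unit.b_f.data[:] = 40.0  # f -> 1
        Z = Tensor(rng.standard_normal((4, 3)))
        H_prev = Tensor(rng.standard_normal((4, 3)))
        H, _ = recurrent_step(Z, [H_prev], unit)
        assert np.allclose(H.data, H_prev.data, atol=1e-9)

    def test_saturated_update_gate_takes_candidate(self, rng):
        unit = init_recurrent_unit(3, 2, 3, rng)
        unit.b_f.data[:] = -40.0  # f -> 0
        Z = rng.standard_normal((4, 3))
        H, _ = recurrent_step(Tensor(Z), [], unit)
        p = {k: getattr(unit, k).data for k in ("W_q", "W_k", "W_f", "U_f", "W_h", "U_h", "b_f", "b_h")}
        assert np.allclose(H.data, ref_recurrent_step(Z, [], p), atol=1e-9)

    def test_matches_elementwise_oracle(self, rng):
        unit = init_recurrent_unit(3, 2, 3, rng)
        Z = rng.standard_normal((2, 3))
        mem = [rng.standard_normal((2, 3)) for _ in range(2)]
        H, _ = recurrent_step(Tensor(Z), [Tensor(m) for m in mem], unit)
        p = {k: getattr(unit, k).data for k in ("W_q", "W_k", "W_f", "U_f", "W_h", "U_h", "b_f", "b_h")}
        assert np.allclose(H.data, ref_recurrent_step(Z, mem, p), atol=1e-6)

    def test_gate_convexity(self, rng):
        unit = init_recurrent_unit(4, 3, 3, rng)
        Z = Tensor(rng.standard_normal((5, 4)))
        H_prev = Tensor(rng.standard_normal((5, 4)))
        H, _ = recurrent_step(Z, [H_prev], unit)
        _, C = window_attention(Z, [H_prev], unit)
        from sarn.autodiff import matmul, tanh

        Ht = tanh(matmul(Z, unit.W_h) + matmul(C, unit.U_h) + unit.b_h).data
        lo = np.minimum(H_prev.data, Ht)
        hi = np.maximum(H_prev.data, Ht)
        assert np.all(H.data >= lo - 1e-12) and np.all(H.data <= hi + 1e-12)

    def test_memory_never_exceeds_window(self, rng):
        unit = init_recurrent_unit(3, 2, 3, rng)
        mem = []
        for _ in range(7):
            _, mem = recurrent_step(Tensor(rng.standard_normal((2, 3))), mem, unit)
            assert len(mem) <= 3


class TestEncodeSequence:
    def make_net(self, rng, n=6, t=16):
        from sarn.netbuild import ROITimeSeries

        ts = ROITimeSeries(
            values=rng.standard_normal((n, t)),
            region_ids=[f"R{i}" for i in range(n)],
            subject_id="s",
            label=0,
        )
        return build_network(ts, n_steps=4, k=2, max_dist=3)

    def params(self, rng, d_in):
        stack = init_gsa_stack((d_in, 5, 5, 4), rng)
        table = init_spatial_table(3)
        unit = init_recurrent_unit(4, 3, 3, rng)
        return stack, table, unit

    def test_matches_unrolled_reference(self, rng):
        net = self.make_net(rng)
        stack, table, unit = self.params(rng, d_in=net.n_regions)
        H = encode_sequence(net, stack, table, unit).data
        # straight-line reference: loop snapshots, loop layers, fold steps
        p = {k: getattr(unit, k).data for k in ("W_q", "W_k", "W_f", "U_f", "W_h", "U_h", "b_f", "b_h")}
        mem = []
        for t in range(net.n_steps):
            h = net.snapshots[t].adjacency
            for layer in stack:
                h = ref_gsa(
                    h,
                    layer.W.data,
                    layer.c.data,
                    table.s.data,
                    net.neighbor_sets[t],
                    net.spatial_index[t],
                )
            Href = ref_recurrent_step(h, mem, p)
            mem = [Href] + mem[:2]
        assert np.allclose(H, mem[0], atol=1e-6)

    def test_permutation_equivariance(self, rng):
        net = self.make_net(rng)
        n = net.n_regions
        stack, table, unit = self.params(rng, d_in=4)
        feats, masks, sidx, _ = assemble_batch([net], "signal")
        H = encode_sequence_arrays(feats, masks, sidx, stack, table, unit).data[0]
        perm = rng.permutation(n)
        fp = feats[:, :, perm, :]
        mp = masks[:, :, perm][:, :, :, perm]
        sp = sidx[:, :, perm][:, :, :, perm]
        Hp = encode_sequence_arrays(fp, mp, sp, stack, table, unit).data[0]
        assert np.allclose(Hp, H[perm], atol=1e-8)

    def test_inconsistent_region_count_rejected(self, rng):
        net_a = self.make_net(rng, n=6)
        net_b = self.make_net(rng, n=5)
        with pytest.raises(ValueError):
            assemble_batch([net_a, net_b])

    def test_no_recurrence_averages_steps(self, rng):
        net = self.make_net(rng)
        stack, table, unit = self.params(rng, d_in=net.n_regions)
        H = encode_sequence(net, stack, table, unit, use_recurrence=False).data
        per_step = []
        for t in range(net.n_steps):
            h = net.snapshots[t].adjacency
            for layer in stack:
                h = ref_gsa(
                    h, layer.W.data, layer.c.data, table.s.data,
                    net.neighbor_sets[t], net.spatial_index[t],
                )
            per_step.append(h)
        assert np.allclose(H, np.mean(per_step, axis=0), atol=1e-6)


def test_checkpoint_roundtrip(tmp_path, rng):
    stack = init_gsa_stack((4, 5, 3), rng)
    table = init_spatial_table(4)
    unit = init_recurrent_unit(3, 2, 3, rng)
    path = tmp_path / "ckpt.json"
    save_checkpoint(path, stack, table, unit, extra={"seed": 1})
    stack2, table2, unit2, extra = load_checkpoint(path)
    assert extra == {"seed": 1}
    assert np.allclose(stack2[0].W.data, stack[0].W.data)
    assert np.allclose(table2.s.data, table.s.data)
    assert np.allclose(unit2.U_h.data, unit.U_h.data)
    assert unit2.w == unit.w
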