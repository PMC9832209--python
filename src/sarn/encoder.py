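"""SARN encoder: graph spatial attention layers + sliding-window recurrence.

Per snapshot, a stack of graph spatial attention (GSA) layers embeds the
regions. Attention logits are tanh of a shared linear score over the
concatenated transformed features of a region pair, plus a learned scalar
bias ``s[psi(i, j)]`` indexed by the capped shortest-path distance between
the pair — so attention sees both signal similarity and graph position.
Across snapshots, a recurrent unit with a single forget gate updates the
hidden state; its candidate input is a per-region scaled-dot-product
attention over the current embedding and a FIFO window of the last ``w``
hidden states.

All operations act on batched arrays ``(..., N, d)`` so that many subjects
(and snapshots) are processed in one pass during training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import (
    Tensor,
    as_tensor,
    elu,
    matmul,
    sigmoid,
    softmax,
    stack,
    take,
    tanh,
    tsum,
    unsqueeze,
)
from .netbuild import DynamicBrainNetwork

__all__ = [
    "GSALayerParams",
    "SpatialEncodingTable",
    "RecurrentUnitParams",
    "init_gsa_stack",
    "init_spatial_table",
    "init_recurrent_unit",
    "spatial_attention_coefficients",
    "gsa_layer",
    "window_attention",
    "recurrent_step",
    "encode_sequence_arrays",
    "encode_sequence",
    "assemble_batch",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class GSALayerParams:
    """One GSA layer: convolutional filter W (d_in x d_out) and attention
    weight vector c of length 2*d_out."""

    W: Tensor
    c: Tensor


@dataclass
class SpatialEncodingTable:
    """Learned scalar per distance bucket 0..max_dist+1, shared by all
    layers and snapshots."""

    s: Tensor

    @property
    def n_buckets(self) -> int:
        return self.s.data.shape[0]


@dataclass
class RecurrentUnitParams:
    W_q: Tensor
    W_k: Tensor
    W_f: Tensor
    U_f: Tensor
    W_h: Tensor
    U_h: Tensor
    b_f: Tensor
    b_h: Tensor
    w: int = 3

    @property
    def d_k(self) -> int:
        return self.W_q.data.shape[1]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def init_gsa_stack(
    dims: tuple[int, ...], rng: np.random.Generator
) -> list[GSALayerParams]:
    """Build the layer stack for consecutive dims, e.g. (D, 64, 64, 32)."""
    layers = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        layers.append(
            GSALayerParams(
                W=_glorot(rng, d_in, d_out, (d_in, d_out)),
                c=_glorot(rng, 2 * d_out, 1, (2 * d_out,)),
            )
        )
    return layers


def init_spatial_table(max_dist: int) -> SpatialEncodingTable:
    # zero-initialized: spatial bias starts neutral and is learned
    return SpatialEncodingTable(s=Tensor(np.zeros(max_dist + 2), requires_grad=True))


def init_recurrent_unit(
    d: int, d_k: int, w: int, rng: np.random.Generator
) -> RecurrentUnitParams:
    return RecurrentUnitParams(
        W_q=_glorot(rng, d, d_k, (d, d_k)),
        W_k=_glorot(rng, d, d_k, (d, d_k)),
        W_f=_glorot(rng, d, d, (d, d)),
        U_f=_glorot(rng, d, d, (d, d)),
        W_h=_glorot(rng, d, d, (d, d)),
        U_h=_glorot(rng, d, d, (d, d)),
        b_f=Tensor(np.zeros(d), requires_grad=True),
        b_h=Tensor(np.zeros(d), requires_grad=True),
        w=w,
    )


# ---------------------------------------------------------------------
# graph spatial attention

def spatial_attention_coefficients(
    h,
    params: GSALayerParams,
    table: SpatialEncodingTable,
    neighbor_mask: np.ndarray,
    spatial_index: np.ndarray,
) -> Tensor:
    """Attention map alpha with support restricted to each region's N(i).

    logit(i, j) = tanh([h_i W, h_j W] . c + s[psi(i, j)]); rows are
    softmax-normalized over N(i). Accepts batched inputs (..., N, d) with
    matching (..., N, N) mask and distance index.
    """
    h = as_tensor(h)
    mask = np.asarray(neighbor_mask, dtype=bool)
    if not mask.any(axis=-1).all():
        raise ValueError("every region needs a nonempty neighborhood")
    hW = matmul(h, params.W)
    d_out = params.W.data.shape[1]
    c_src, c_dst = params.c[:d_out], params.c[d_out:]
    p = tsum(hW * c_src, axis=-1)  # contribution of the attending region i
    q = tsum(hW * c_dst, axis=-1)  # contribution of the attended region j
    s_ij = take(table.s, np.asarray(spatial_index))
    logits = tanh(unsqueeze(p, -1) + unsqueeze(q, -2) + s_ij)
    return softmax(logits, axis=-1, mask=mask)


def gsa_layer(
    h,
    params: GSALayerParams,
    table: SpatialEncodingTable,
    neighbor_mask: np.ndarray,
    spatial_index: np.ndarray,
) -> Tensor:
    """One GSA layer: ELU of the alpha-weighted aggregation of h_j W."""
    h = as_tensor(h)
    alpha = spatial_attention_coefficients(h, params, table, neighbor_mask, spatial_index)
    return elu(matmul(alpha, matmul(h, params.W)))


# ---------------------------------------------------------------------
# sliding-window attention recurrence

def window_attention(
    Z, memory: list[Tensor], params: RecurrentUnitParams
) -> tuple[Tensor, Tensor]:
    """Per-region attention of Z over the slots [Z, M^{t-1}].

    Each region's current embedding is the query; keys/values are its own
    embedding plus its hidden states in the memory window. Returns the
    attention coefficients (..., N, n_slots) and the context a.V, with the
    raw slots as values (no value projection).
    """
    Z = as_tensor(Z)
    slots = [Z] + list(memory)
    q = matmul(Z, params.W_q)
    scale = 1.0 / np.sqrt(params.d_k)
    scores = [tsum(q * matmul(slot, params.W_k), axis=-1) * scale for slot in slots]
    e = stack(scores, axis=-1)  # (..., N, n_slots)
    a = softmax(e, axis=-1)
    V = stack(slots, axis=-2)  # (..., N, n_slots, d)
    context = tsum(unsqueeze(a, -1) * V, axis=-2)
    return a, context


def recurrent_step(
    Z, memory: list[Tensor], params: RecurrentUnitParams
) -> tuple[Tensor, list[Tensor]]:
    """Forget-gate-only update of the hidden state.

    f = sigmoid(Z W_f + C U_f + b_f), Htilde = tanh(Z W_h + C U_h + b_h),
    H = f * H_prev + (1 - f) * Htilde, where C is the window-attention
    context. H_prev is the newest memory entry, or zero before the first
    step. The updated memory prepends H and evicts beyond the window.
    """
    Z = as_tensor(Z)
    H_prev = memory[0] if memory else Tensor(np.zeros_like(Z.data))
    _, C = window_attention(Z, memory, params)
    f = sigmoid(matmul(Z, params.W_f) + matmul(C, params.U_f) + params.b_f)
    H_tilde = tanh(matmul(Z, params.W_h) + matmul(C, params.U_h) + params.b_h)
    H = f * H_prev + (1.0 - f) * H_tilde
    new_memory = [H] + list(memory)[: params.w - 1]
    return H, new_memory


# ---------------------------------------------------------------------
# full sequence encoding

def encode_sequence_arrays(
    features: np.ndarray | Tensor,
    neighbor_masks: np.ndarray,
    spatial_indices: np.ndarray,
    stack_params: list[GSALayerParams],
    table: SpatialEncodingTable,
    unit: RecurrentUnitParams,
    use_recurrence: bool = True,
) -> Tensor:
    """Encode a batch of dynamic networks given as dense arrays.

    ``features`` is (T, B, N, D) — a plain array, or a Tensor when a
    differentiable input mask has been applied upstream; masks and
    distance indices are (T, B, N, N). All T snapshots of all B subjects
    run through the GSA stack in one batched pass, then the recurrence
    folds over the T steps. Returns the final hidden state (B, N, d).
    With ``use_recurrence`` False the per-step embeddings are simply
    averaged (ablation variant).
    """
    from .autodiff import reshape as treshape

    T, B, N, D = features.shape
    if isinstance(features, Tensor):
        h = treshape(features, (T * B, N, D))
    else:
        h = Tensor(features.reshape(T * B, N, D))
    m = np.asarray(neighbor_masks).reshape(T * B, N, N)
    ps = np.asarray(spatial_indices).reshape(T * B, N, N)
    for layer in stack_params:
        h = gsa_layer(h, layer, table, m, ps)
    Zs = [h[t * B : (t + 1) * B] for t in range(T)]
    if not use_recurrence:
        out = Zs[0]
        for Z in Zs[1:]:
            out = out + Z
        return out * (1.0 / T)
    memory: list[Tensor] = []
    H = Zs[0]
    for Z in Zs:
        H, memory = recurrent_step(Z, memory, unit)
    return H


def assemble_batch(
    nets: list[DynamicBrainNetwork],
    feature_mode: str = "connectivity",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack networks into (T,B,N,D) features, masks, indices and labels.

    ``feature_mode`` selects the model's node input per snapshot:
    ``"connectivity"`` (default) feeds each region's functional-connectivity
    profile, i.e. its row of the Pearson adjacency (D = N), which is stable
    in region identity across subjects; ``"signal"`` feeds the z-scored raw
    segment window (D = T/n_steps).
    """
    if not nets:
        raise ValueError("empty batch")
    if feature_mode not in ("connectivity", "signal"):
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    n = nets[0].n_regions
    t_steps = nets[0].n_steps
    for net in nets:
        if net.n_regions != n or net.n_steps != t_steps:
            raise ValueError("all networks must share N and T_steps")
    attr = "adjacency" if feature_mode == "connectivity" else "node_features"
    features = np.stack(
        [[getattr(net.snapshots[t], attr) for net in nets] for t in range(t_steps)]
    )
    masks = np.stack([[net.neighbor_masks[t] for net in nets] for t in range(t_steps)])
    sidx = np.stack([[net.spatial_index[t] for net in nets] for t in range(t_steps)])
    labels = np.array([net.label for net in nets], dtype=np.float64)
    return features, masks, sidx, labels


def encode_sequence(
    net: DynamicBrainNetwork,
    stack_params: list[GSALayerParams],
    table: SpatialEncodingTable,
    unit: RecurrentUnitParams,
    use_recurrence: bool = True,
    feature_mode: str = "connectivity",
) -> Tensor:
    """Encode a single dynamic network; returns H_final of shape (N, d)."""
    features, masks, sidx, _ = assemble_batch([net], feature_mode)
    H = encode_sequence_arrays(
        features, masks, sidx, stack_params, table, unit, use_recurrence
    )
    return H[0]


# ---------------------------------------------------------------------
# checkpointing (JSON: text-only, round-trippable)

def _params_to_lists(obj) -> dict:
    out = {}
    for name, val in vars(obj).items():
        if isinstance(val, Tensor):
            out[name] = val.data.tolist()
        else:
            out[name] = val
    return out


def save_checkpoint(
    path: str | Path,
    stack_params: list[GSALayerParams],
    table: SpatialEncodingTable,
    unit: RecurrentUnitParams,
    extra: dict | None = None,
) -> None:
    payload = {
        "stack": [_params_to_lists(l) for l in stack_params],
        "table": _params_to_lists(table),
        "unit": _params_to_lists(unit),
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(
    path: str | Path,
) -> tuple[list[GSALayerParams], SpatialEncodingTable, RecurrentUnitParams, dict]:
    payload = json.loads(Path(path).read_text())
    stack_params = [
        GSALayerParams(
            W=Tensor(np.array(l["W"]), requires_grad=True),
            c=Tensor(np.array(l["c"]), requires_grad=True),
        )
        for l in payload["stack"]
    ]
    table = SpatialEncodingTable(
        s=Tensor(np.array(payload["table"]["s"]), requires_grad=True)
    )
    u = payload["unit"]
    unit = RecurrentUnitParams(
        **{
            k: Tensor(np.array(u[k]), requires_grad=True)
            for k in ("W_q", "W_k", "W_f", "U_f", "W_h", "U_h", "b_f", "b_h")
        },
        w=int(u["w"]),
    )
    return stack_params, table, unit, payload["extra"]
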