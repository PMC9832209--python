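"""Graph-level readout, MLP classifier and the training loss.

The masked node embeddings are averaged over regions and passed through a
logistic nonlinearity (mean readout), then a one-hidden-layer MLP produces
the addiction probability. The loss is binary cross-entropy summed over
subjects plus the selector's KL sparsity penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, clip, elu, log, matmul, sigmoid, squeeze, tmean, tsum
from .selector import SelectionState, kl_sparsity

__all__ = ["MLPParams", "init_mlp", "readout", "classify", "total_loss"]

EPS = 1e-7  # probability clamp for the cross-entropy


@dataclass
class MLPParams:
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor


def init_mlp(d_in: int, hidden: int, rng: np.random.Generator) -> MLPParams:
    def glorot(fan_in, fan_out, shape):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)

    return MLPParams(
        W1=glorot(d_in, hidden, (d_in, hidden)),
        b1=Tensor(np.zeros(hidden), requires_grad=True),
        W2=glorot(hidden, 1, (hidden, 1)),
        b2=Tensor(np.zeros(1), requires_grad=True),
    )


def readout(H_masked) -> Tensor:
    """Mean over regions followed by the logistic function.

    Accepts (N, d) or batched (B, N, d); returns (d,) or (B, d)."""
    H_masked = as_tensor(H_masked)
    if H_masked.data.shape[-2] == 0:
        raise ValueError("readout needs at least one region")
    return sigmoid(tmean(H_masked, axis=-2))


def classify(g, mlp: MLPParams) -> tuple[Tensor, Tensor]:
    """MLP forward pass; returns (logit, probability).

    ``g`` is a graph embedding (d,) or a batch (B, d)."""
    g = as_tensor(g)
    single = g.ndim == 1
    if single:
        from .autodiff import unsqueeze

        g = unsqueeze(g, 0)
    if g.data.shape[-1] != mlp.W1.data.shape[0]:
        raise ValueError(
            f"embedding dim {g.data.shape[-1]} != classifier input {mlp.W1.data.shape[0]}"
        )
    hid = elu(matmul(g, mlp.W1) + mlp.b1)
    logit = squeeze(matmul(hid, mlp.W2) + mlp.b2, -1)
    if single:
        logit = squeeze(logit, 0)
    return logit, sigmoid(logit)


def total_loss(
    y_prob,
    labels: np.ndarray,
    state: SelectionState | None = None,
    kl_weight: float = 1.0,
) -> Tensor:
    """Summed BCE over subjects plus the KL sparsity penalty.

    Probabilities are clamped to [EPS, 1-EPS] before the logs."""
    y_prob = as_tensor(y_prob)
    y = np.asarray(labels, dtype=np.float64)
    if y.shape != y_prob.data.shape:
        raise ValueError("labels and predictions must have matching shapes")
    p = clip(y_prob, EPS, 1.0 - EPS)
    bce = -tsum(y * log(p) + (1.0 - y) * log(1.0 - p))
    if state is None:
        return bce
    return bce + kl_weight * kl_sparsity(state)
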