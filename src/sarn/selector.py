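"""Bayesian feature selector over brain regions.

A free logit per region defines a selection probability z = sigmoid(logit).
During training a relaxed Bernoulli mask is sampled by logistic
reparameterization with temperature r, keeping the mask differentiable in
z; a KL penalty to a sparse Bernoulli prior Ber(s) pushes most
probabilities toward s. At inference the mask is the deterministic hard
threshold b = 1[z > 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, log, sigmoid, tsum, unsqueeze

__all__ = [
    "SelectionState",
    "Mask",
    "sample_mask",
    "hard_mask",
    "expected_mask",
    "kl_sparsity",
    "apply_mask",
]


@dataclass
class SelectionState:
    """Free selection logits plus the sparsity prior s and temperature r."""

    logits: Tensor
    s: float = 0.1
    r: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.s < 1.0:
            raise ValueError("prior s must be in (0, 1)")
        if self.r <= 0.0:
            raise ValueError("temperature r must be positive")

    @classmethod
    def init(cls, n_regions: int, s: float = 0.1, r: float = 0.5) -> "SelectionState":
        # zero logits: z = 0.5, maximal uncertainty about every region
        return cls(logits=Tensor(np.zeros(n_regions), requires_grad=True), s=s, r=r)

    @property
    def z(self) -> Tensor:
        return sigmoid(self.logits)

    @property
    def n_regions(self) -> int:
        return self.logits.data.shape[0]


@dataclass
class Mask:
    """A sampled (relaxed) or thresholded (hard) region mask."""

    b: Tensor
    u: np.ndarray | None = None
    hard: bool = False


def sample_mask(state: SelectionState, u: np.ndarray) -> Mask:
    """Relaxed Bernoulli sample b = sigmoid((logit z + logit u) / r).

    ``u`` are uniforms strictly inside (0, 1): either one draw per region
    (shape (N,)) or an independent draw per subject (shape (S, N)). The
    draw is recorded on the mask for reproducibility. b is differentiable
    in the selection logits.
    """
    u = np.asarray(u, dtype=np.float64)
    if u.shape[-1] != state.n_regions or u.ndim > 2:
        raise ValueError("u must have shape (N,) or (S, N) matching the regions")
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("uniform draws must lie strictly inside (0, 1)")
    logit_u = np.log(u) - np.log(1.0 - u)
    # log z - log(1-z) is exactly the free logit parameter
    b = sigmoid((state.logits + logit_u) * (1.0 / state.r))
    return Mask(b=b, u=u, hard=False)


def hard_mask(state: SelectionState) -> Mask:
    """Deterministic selection mask: region is selected iff z > 0.5."""
    b = (state.logits.data > 0.0).astype(np.float64)
    return Mask(b=Tensor(b), u=None, hard=True)


def expected_mask(state: SelectionState) -> Mask:
    """Mean-field inference mask: the expectation z of the gate.

    Prediction uses the deterministic expectation of the mask the model
    was trained under, so there is no train/test distribution shift;
    ``hard_mask`` remains the selection semantics for biomarker reporting.
    """
    return Mask(b=Tensor(state.z.data.copy()), u=None, hard=False)


def kl_sparsity(state: SelectionState) -> Tensor:
    """KL(Ber(z) || Ber(s)) summed over regions; zero iff all z equal s."""
    z = state.z
    s = state.s
    terms = z * (log(z) - np.log(s)) + (1.0 - z) * (log(1.0 - z) - np.log(1.0 - s))
    return tsum(terms)


def apply_mask(H, mask: Mask) -> Tensor:
    """Scale region rows of H (..., N, d) by the mask entries.

    A (N,) mask broadcasts over any batch; a (S, N) mask applies one
    sampled mask per subject."""
    H = as_tensor(H)
    if mask.b.data.shape[-1] != H.data.shape[-2]:
        raise ValueError(
            f"mask length {mask.b.data.shape[-1]} != number of regions {H.data.shape[-2]}"
        )
    return H * unsqueeze(mask.b, -1)
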