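"""Gated dual-stream feature complementation.

Two mechanisms exchange information between the word-level stream h^w and
the character-level stream h^c:

* **Low level** — each stream is modulated by a sigmoid gate computed from
  the *other* stream through a small MLP, and the gated vector is
  concatenated with the un-gated stream as a residual:
  ``h̄^w = [σ(MLP(h^c)) ⊙ h^w ; h^w]`` (char-steered complement of the word
  stream, CCM) and symmetrically ``h̄^c = [σ(MLP(h^w)) ⊙ h^c ; h^c]``
  (word-induced enhancement of the char stream, WEM).

* **High level** — after per-stream multi-head self-attention, the fused
  vector h̄ = [h̄^w ; h̄^c] drives a first shared sigmoid gate H applied to
  both streams (ĥ = H ⊙ h̄), each result then gates itself a second time
  (h̃ = σ(ĥ) ⊙ ĥ), and the final per-token representation is
  ``H_i = [h̃^w ; h̄ ; h̃^c]``.

The fused vector is twice as wide as either stream, so the first gate uses
a learned linear projection down to the stream width before the sigmoid.
When an ablation leaves the two streams with different widths a shared gate
is impossible and per-stream projections are used instead.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .nn import Linear, MLP, Module

__all__ = ["LowLevelComplement", "HighLevelComplement"]


class LowLevelComplement(Module):
    """CCM + WEM gating; each direction has its own MLP parameters."""

    def __init__(self, dim_w: int, dim_c: int, rng: np.random.Generator,
                 mlp_hidden: int | None = None, use_ccm: bool = True,
                 use_wem: bool = True):
        self.use_ccm = use_ccm
        self.use_wem = use_wem
        if use_ccm:
            self.mlp_c2w = MLP(dim_c, mlp_hidden or dim_c, dim_w, rng)
        if use_wem:
            self.mlp_w2c = MLP(dim_w, mlp_hidden or dim_w, dim_c, rng)
        self.out_dim_w = 2 * dim_w if use_ccm else dim_w
        self.out_dim_c = 2 * dim_c if use_wem else dim_c

    def __call__(self, h_w: Tensor, h_c: Tensor) -> tuple[Tensor, Tensor]:
        if h_w.shape[:2] != h_c.shape[:2]:
            raise ValueError(f"stream shapes differ: {h_w.shape} vs {h_c.shape}")
        out_w, out_c = h_w, h_c
        if self.use_ccm:
            gate_w = self.mlp_c2w(h_c).sigmoid()
            out_w = concat([gate_w * h_w, h_w], axis=-1)
        if self.use_wem:
            gate_c = self.mlp_w2c(h_w).sigmoid()
            out_c = concat([gate_c * h_c, h_c], axis=-1)
        return out_w, out_c


class HighLevelComplement(Module):
    """Double sigmoid gating of both streams driven by the fused vector.

    ``printed_asymmetry`` reproduces a variant in which the second-stage
    gate of the char stream reuses the word stream's gate σ(ĥ^w) instead of
    its own σ(ĥ^c); it requires equal stream widths.
    """

    def __init__(self, dim_w: int, dim_c: int, rng: np.random.Generator,
                 printed_asymmetry: bool = False):
        self.dim_w, self.dim_c = dim_w, dim_c
        self.printed_asymmetry = printed_asymmetry
        fused = dim_w + dim_c
        self.shared_gate = dim_w == dim_c
        if self.shared_gate:
            self.proj = Linear(fused, dim_w, rng)
        else:
            if printed_asymmetry:
                raise ValueError("printed_asymmetry requires equal stream widths")
            self.proj_w = Linear(fused, dim_w, rng)
            self.proj_c = Linear(fused, dim_c, rng)
        self.out_dim = dim_w + fused + dim_c

    def __call__(self, hbar_w: Tensor, hbar_c: Tensor) -> Tensor:
        if hbar_w.shape[-1] != self.dim_w or hbar_c.shape[-1] != self.dim_c:
            raise ValueError(
                f"expected stream widths ({self.dim_w}, {self.dim_c}), "
                f"got ({hbar_w.shape[-1]}, {hbar_c.shape[-1]})")
        fused = concat([hbar_w, hbar_c], axis=-1)
        if self.shared_gate:
            H = self.proj(fused).sigmoid()
            Hw_gate = Hc_gate = H
        else:
            Hw_gate = self.proj_w(fused).sigmoid()
            Hc_gate = self.proj_c(fused).sigmoid()
        hat_w = Hw_gate * hbar_w
        hat_c = Hc_gate * hbar_c
        H_w = hat_w.sigmoid()
        H_c = hat_c.sigmoid()
        tilde_w = H_w * hat_w
        tilde_c = (H_w if self.printed_asymmetry else H_c) * hat_c
        return concat([tilde_w, fused, tilde_c], axis=-1)
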