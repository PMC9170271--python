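"""Multilevel feature extraction shared by the easy and hard classifiers.

The stages, applied to the length x 50 residue encoding:

1. four per-block linear branches (one-hot / profile / physicochemical /
   conservation) whose outputs are concatenated;
2. multiscale same-length 1-D convolutions (ReLU) over the concatenation,
   channel-concatenated into the *easy* feature ``c``;
3. a bidirectional gated recurrent pass over ``c`` giving per-position
   global contexts ``h``;
4. additive sequence attention pooling ``h`` into a per-protein summary
   ``alpha_h`` (softmax over real residues only);
5. the *hard* feature ``v = [c, h, alpha_h]`` with ``alpha_h`` tiled to
   every position.

With the default widths: c is 3*64 = 192 wide, h is 2*256 = 512, and
v is 192 + 512 + 512 = 1216.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import BiGRU, Conv1dSame, Dropout, Linear, Module, SequenceAttention, Tensor, concat

#: widths of the four input blocks: one-hot, profile, physchem, conservation
BLOCK_WIDTHS = (21, 21, 7, 1)


@dataclass
class ExtractorConfig:
    branch_hidden: tuple[int, int, int, int] = (64, 128, 32, 16)
    conv_hidden: int = 64
    conv_kernels: tuple[int, ...] = (5, 9, 13)
    recurrent_hidden: int = 256
    attention_hidden: int = 256
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.branch_hidden) or self.conv_hidden <= 0 \
                or self.recurrent_hidden <= 0 or self.attention_hidden <= 0:
            raise ValueError("all hidden sizes must be positive")
        if any(k % 2 == 0 or k <= 0 for k in self.conv_kernels):
            raise ValueError("convolution kernel sizes must be positive and odd")

    @property
    def branch_out(self) -> int:
        return sum(self.branch_hidden)

    @property
    def easy_width(self) -> int:
        return self.conv_hidden * len(self.conv_kernels)

    @property
    def context_width(self) -> int:
        return 2 * self.recurrent_hidden

    @property
    def hard_width(self) -> int:
        return self.easy_width + 2 * self.context_width

    def shape_report(self) -> dict[str, int]:
        return {
            "input": sum(BLOCK_WIDTHS),
            "branch_concat": self.branch_out,
            "easy_c": self.easy_width,
            "context_h": self.context_width,
            "attention_alpha_h": self.context_width,
            "hard_v": self.hard_width,
        }


class FeatureExtractor(Module):
    """The shared trunk; exposes each stage for testing and introspection."""

    def __init__(self, rng: np.random.Generator, config: ExtractorConfig | None = None):
        super().__init__()
        self.config = cfg = config or ExtractorConfig()
        self.branches = [
            Linear(rng, w, h) for w, h in zip(BLOCK_WIDTHS, cfg.branch_hidden)
        ]
        self.branch_dropout = Dropout(rng, cfg.dropout)
        self.convs = [
            Conv1dSame(rng, cfg.branch_out, cfg.conv_hidden, k) for k in cfg.conv_kernels
        ]
        self.gru = BiGRU(rng, cfg.easy_width, cfg.recurrent_hidden)
        self.attention = SequenceAttention(rng, cfg.context_width, cfg.attention_hidden)

    def branch_project(self, features: Tensor) -> Tensor:
        """Four per-block affine maps (with dropout when training), concatenated."""
        if features.data.shape[-1] != sum(BLOCK_WIDTHS):
            raise ValueError(
                f"expected {sum(BLOCK_WIDTHS)} input features, got {features.data.shape[-1]}"
            )
        lo = np.cumsum((0,) + BLOCK_WIDTHS)
        outs = []
        for branch, a, b in zip(self.branches, lo[:-1], lo[1:]):
            outs.append(self.branch_dropout(branch(features[..., a:b])))
        return concat(outs, axis=-1)

    def multiscale_conv(self, l: Tensor) -> Tensor:
        """Easy feature c: channel-concatenated multiscale convolutions."""
        return concat([conv(l) for conv in self.convs], axis=-1)

    def recurrent_contexts(self, c: Tensor) -> Tensor:
        """Global contexts h from the bidirectional recurrent pass."""
        return self.gru(c)

    def sequential_attention(self, h: Tensor, mask: np.ndarray):
        """(alpha_t, alpha_h): position weights and the pooled context."""
        return self.attention(h, mask)

    @staticmethod
    def hard_concat(c: Tensor, h: Tensor, alpha_h: Tensor) -> Tensor:
        """Hard feature v = [c, h, alpha_h], alpha_h tiled across positions."""
        B, T, _ = c.data.shape
        if h.data.shape[:2] != (B, T) or alpha_h.data.shape[0] != B:
            raise ValueError("inconsistent shapes for hard-feature concatenation")
        ones = Tensor(np.ones((B, T, 1)))
        tiled = ones * alpha_h.reshape(B, 1, alpha_h.data.shape[1])
        return concat([c, h, tiled], axis=-1)

    def __call__(self, features: Tensor, mask: np.ndarray):
        """Full pass; returns (c, h, alpha_t, v)."""
        l = self.branch_project(features)
        c = self.multiscale_conv(l)
        h = self.recurrent_contexts(c)
        alpha_t, alpha_h = self.sequential_attention(h, mask)
        v = self.hard_concat(c, h, alpha_h)
        return c, h, alpha_t, v
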