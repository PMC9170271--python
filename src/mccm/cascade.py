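"""Easy/hard classifier cascade with evidential difficulty routing.

Two classifier heads share the multilevel extractor trunk: a single linear
layer over the easy feature ``c`` and a multilayer perceptron (hidden sizes
512 and 1024 by default) over the hard feature ``v``.  Each head's
pre-softmax outputs are read twice:

* softmax for the cross-entropy loss;
* rectified into non-negative *evidence* ``e = relu(logits)`` that
  parameterises a Dirichlet opinion ``alpha = e + 1`` with strength
  ``S = sum(alpha)`` and expectation ``p = alpha / S``.

The Shannon entropy (base 2) of ``p`` measures how committed the opinion
is; residues whose easy-head entropy is low (and, during training, which
the easy head already labels correctly) are routed *easy*, the rest *hard*.
The combined objective adds cross-entropy and an evidential expected-Brier
loss for both heads, with the hard terms computed on hard-routed residues
only, so a hard residue accumulates extra penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .extractor import ExtractorConfig, FeatureExtractor
from .nn import MLP, Dropout, Linear, Module, Tensor


# --- Dirichlet opinions ------------------------------------------------------

@dataclass
class DirichletOpinion:
    """Per-residue Dirichlet opinion; arrays share the leading shape."""

    alpha: np.ndarray        # (..., Z), entries >= 1
    strength: np.ndarray     # (...,) S = sum alpha
    expectation: np.ndarray  # (..., Z) p = alpha / S
    entropy: np.ndarray      # (...,) bits

    @property
    def prediction(self) -> np.ndarray:
        """argmax of the expectation; ties broken toward the lowest index."""
        return np.argmax(self.expectation, axis=-1)


def information_entropy(p) -> np.ndarray:
    """Shannon entropy of a probability vector in bits, with 0*log0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative probability")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=-1)


def opinion_from_logits(logits) -> DirichletOpinion:
    """Rectify logits into evidence and form the Dirichlet opinion."""
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    evidence = np.maximum(logits, 0.0)
    alpha = evidence + 1.0
    S = alpha.sum(axis=-1)
    p = alpha / S[..., None]
    return DirichletOpinion(alpha=alpha, strength=S, expectation=p,
                            entropy=information_entropy(p))


def dirichlet_loss(y_onehot, opinion: DirichletOpinion) -> float:
    """Evidential mean-square loss: the expected Brier score under Dir(alpha).

    sum_z (y_z - p_z)^2 + p_z (1 - p_z) / (S + 1); averaged over leading
    dimensions when given a batch.
    """
    y = np.asarray(y_onehot, dtype=float)
    p = opinion.expectation
    if y.shape != p.shape:
        raise ValueError("label/opinion shape mismatch")
    S = opinion.strength[..., None]
    per = ((y - p) ** 2 + p * (1.0 - p) / (S + 1.0)).sum(axis=-1)
    return float(np.mean(per))


def dirichlet_pdf(p, alpha) -> float:
    """Density of Dir(alpha) at a point p on the simplex (oracle helper)."""
    p = np.asarray(p, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        return 0.0
    log_b = gammaln(alpha).sum() - gammaln(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        log_terms = np.where(alpha == 1.0, 0.0, (alpha - 1.0) * np.log(p))
    if np.any(np.isneginf(log_terms)):
        return 0.0
    if np.any(np.isposinf(log_terms)):
        return np.inf
    return float(np.exp(log_terms.sum() - log_b))


def cross_entropy(y_onehot, logits) -> float:
    """Softmax cross-entropy averaged over leading dimensions."""
    y = np.asarray(y_onehot, dtype=float)
    logits = np.asarray(logits, dtype=float)
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    return float(np.mean(-(y * logp).sum(axis=-1)))


# --- routing -----------------------------------------------------------------

@dataclass
class RoutingConfig:
    """How residues are assigned to the easy or hard classifier.

    mode "label": easy iff the easy head is correct (diagnostic upper bound,
    needs labels in both phases).  mode "evidential": easy iff correct AND
    entropy below the per-th percentile during training; entropy below the
    frozen threshold at test time (label-free).  mode "confidence":
    early-exit style, easy iff max softmax confidence exceeds the threshold
    (plus correctness during training).
    """

    mode: str = "evidential"
    per: float = 30.0
    confidence_threshold: float = 0.9
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("label", "evidential", "confidence"):
            raise ValueError(f"unknown routing mode {self.mode!r}")
        if not 0.0 <= self.per < 100.0:
            raise ValueError("percentile must be in [0,100)")
        if not 0.0 < self.confidence_threshold < 1.0:
            raise ValueError("confidence threshold must be in (0,1)")


@dataclass
class RoutingDecision:
    assignment: np.ndarray       # bool over residues, True = easy
    threshold_value: float       # realised entropy (or confidence) threshold

    @property
    def easy(self) -> np.ndarray:
        return self.assignment

    @property
    def hard(self) -> np.ndarray:
        return ~self.assignment


def route(
    opinions: DirichletOpinion,
    labels: np.ndarray | None,
    config: RoutingConfig,
    phase: str = "train",
    confidence: np.ndarray | None = None,
    frozen_threshold: float | None = None,
) -> RoutingDecision:
    """Partition residues into easy/hard per the configured rule.

    ``opinions`` covers masked-true residues (flat); ``labels`` are class
    indices, required whenever the rule consults correctness.  For
    evidential test-time routing a ``frozen_threshold`` (bits) is required.
    """
    if phase not in ("train", "test"):
        raise ValueError(f"phase must be train or test, got {phase!r}")
    H = opinions.entropy
    needs_labels = config.mode == "label" or (phase == "train")
    if needs_labels and labels is None:
        raise ValueError(f"mode={config.mode!r} phase={phase!r} requires labels")
    correct = None
    if labels is not None:
        correct = opinions.prediction == np.asarray(labels)

    if config.mode == "label":
        return RoutingDecision(assignment=correct.copy(), threshold_value=float("nan"))

    if config.mode == "confidence":
        conf = confidence if confidence is not None else opinions.expectation.max(axis=-1)
        easy = conf > config.confidence_threshold
        if phase == "train":
            easy = easy & correct
        return RoutingDecision(assignment=easy, threshold_value=config.confidence_threshold)

    # evidential
    if phase == "train":
        thr = float(np.percentile(H, config.per)) if H.size else float("nan")
        easy = (H < thr) & correct
    else:
        if frozen_threshold is None:
            raise ValueError("evidential test-time routing needs a frozen threshold")
        thr = float(frozen_threshold)
        easy = H < thr
    return RoutingDecision(assignment=easy, threshold_value=thr)


# --- losses ------------------------------------------------------------------

@dataclass
class LossBreakdown:
    ce_easy: float
    dir_easy: float
    ce_hard: float
    dir_hard: float
    beta: float = 1.0

    @property
    def total(self) -> float:
        return self.ce_easy + self.beta * self.dir_easy + self.ce_hard + self.beta * self.dir_hard

    @property
    def easy_only(self) -> float:
        """The part backpropagated when the hard branch is detached."""
        return self.ce_easy + self.beta * self.dir_easy

    def as_dict(self) -> dict[str, float]:
        return {
            "ce_easy": self.ce_easy, "dir_easy": self.dir_easy,
            "ce_hard": self.ce_hard, "dir_hard": self.dir_hard,
            "total": self.total,
        }


def total_loss(ce_easy: float, dir_easy: float, ce_hard: float, dir_hard: float,
               beta: float = 1.0) -> LossBreakdown:
    """Assemble the combined objective from its four components."""
    return LossBreakdown(ce_easy=ce_easy, dir_easy=dir_easy,
                         ce_hard=ce_hard, dir_hard=dir_hard, beta=beta)


def masked_cross_entropy(logits: Tensor, y_onehot: np.ndarray, weights: np.ndarray) -> Tensor:
    """Weighted-mean softmax cross-entropy as an autodiff node.

    ``weights`` are per-residue (e.g. the validity mask or a routing mask);
    the result averages over residues with positive weight.
    """
    w = np.asarray(weights, dtype=float)
    denom = max(w.sum(), 1.0)
    logp = logits.log_softmax(axis=-1)
    nll = -(logp * Tensor(y_onehot)).sum(axis=-1)
    return (nll * Tensor(w)).sum() * (1.0 / denom)


def masked_dirichlet_loss(logits: Tensor, y_onehot: np.ndarray, weights: np.ndarray) -> Tensor:
    """Weighted-mean evidential loss as an autodiff node (same algebra as
    :func:`dirichlet_loss`, differentiable through the logits)."""
    w = np.asarray(weights, dtype=float)
    denom = max(w.sum(), 1.0)
    alpha = logits.relu() + 1.0
    S = alpha.sum(axis=-1, keepdims=True)
    p = alpha / S
    y = Tensor(y_onehot)
    per = ((y - p) ** 2.0 + p * (1.0 - p) / (S + 1.0)).sum(axis=-1)
    return (per * Tensor(w)).sum() * (1.0 / denom)


# --- classifier heads and the combined model ---------------------------------

@dataclass
class ClassifierConfig:
    n_classes: int = 8
    mlp_hidden: tuple[int, int] = (512, 1024)
    dropout: float = 0.5


class EasyClassifier(Module):
    """A single linear layer over the easy feature c."""

    def __init__(self, rng, in_dim: int, n_classes: int):
        super().__init__()
        self.linear = Linear(rng, in_dim, n_classes)

    def __call__(self, c: Tensor) -> Tensor:
        return self.linear(c)


class HardClassifier(Module):
    """Multilayer perceptron over the hard feature v."""

    def __init__(self, rng, in_dim: int, config: ClassifierConfig):
        super().__init__()
        self.mlp = MLP(rng, in_dim, list(config.mlp_hidden), config.n_classes,
                       dropout=Dropout(rng, config.dropout))

    def __call__(self, v: Tensor) -> Tensor:
        return self.mlp(v)


class CascadeModel(Module):
    """Shared extractor trunk plus the two classifier heads."""

    def __init__(self, rng: np.random.Generator,
                 extractor_config: ExtractorConfig | None = None,
                 classifier_config: ClassifierConfig | None = None):
        super().__init__()
        self.extractor = FeatureExtractor(rng, extractor_config)
        self.classifier_config = classifier_config or ClassifierConfig()
        cfg = self.extractor.config
        self.easy_head = EasyClassifier(rng, cfg.easy_width, self.classifier_config.n_classes)
        self.hard_head = HardClassifier(rng, cfg.hard_width, self.classifier_config)

    @property
    def n_classes(self) -> int:
        return self.classifier_config.n_classes

    def __call__(self, features: Tensor, mask: np.ndarray):
        """Returns (easy_logits, hard_logits), each (B, T, Z)."""
        c, h, _alpha_t, v = self.extractor(features, mask)
        return self.easy_head(c), self.hard_head(v)
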