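"""Seeded training loop wiring the extractor trunk and the cascade heads.

Model variants (the ``variant`` knob):

* ``mccm``       - label-routed: easy iff the easy head is already correct;
                   both heads' losses backpropagate.  Diagnostic upper bound.
* ``mccm_easy``  - label-routed, but only the easy head's losses
                   backpropagate (the hard terms are recorded, not trained).
* ``mccm_dir``   - evidential: routing by Dirichlet-expectation entropy
                   against a percentile threshold; label-free at test time.
                   The deployable variant.
* ``mccm_conf``  - early-exit baseline: routing by softmax confidence
                   against a fixed threshold (0.9).
* ``c1``         - easy-only ablation: conv features + linear head trained
                   with plain cross-entropy; no routing, no hard branch.

Batching is by protein, padded to the longest sequence in the batch; every
loss and metric averages over masked-true residues only.  All randomness
(weight init, shuffling, dropout) flows from one seeded generator, so a run
is reproducible from its seed.  The evidential test-time entropy threshold
is the running average of the per-batch training percentiles, frozen into
the checkpoint at the end of training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cascade import (
    CascadeModel,
    ClassifierConfig,
    LossBreakdown,
    RoutingConfig,
    RoutingDecision,
    masked_cross_entropy,
    masked_dirichlet_loss,
    opinion_from_logits,
    route,
    total_loss,
)
from .encoding import Q8_TO_Q3_INDEX, ProteinRecord, assemble_features
from .extractor import ExtractorConfig
from .nn import Adam, Tensor

VARIANTS = ("mccm", "mccm_easy", "mccm_dir", "mccm_conf", "c1")
_VARIANT_MODE = {"mccm": "label", "mccm_easy": "label",
                 "mccm_dir": "evidential", "mccm_conf": "confidence"}


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    epochs: int = 10
    batch_size: int = 8           # proteins per batch
    dropout: float = 0.5
    seed: int = 0
    variant: str = "mccm_dir"
    per: float = 30.0
    beta: float = 1.0
    n_classes: int = 8            # 8 for Q8, 3 for Q3 prediction

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.n_classes not in (3, 8):
            raise ValueError("n_classes must be 3 or 8")

    def routing_config(self) -> RoutingConfig | None:
        if self.variant == "c1":
            return None
        return RoutingConfig(mode=_VARIANT_MODE[self.variant], per=self.per,
                             beta=self.beta)


@dataclass
class EpochStats:
    epoch: int
    loss: LossBreakdown
    backprop_loss: float
    train_q: float
    valid_q: float
    threshold: float


@dataclass
class TrainedModel:
    model: CascadeModel
    train_config: TrainConfig
    extractor_config: ExtractorConfig
    routing: RoutingConfig | None
    frozen_threshold: float
    seed: int


@dataclass
class PredictionResult:
    """Per-protein calls: class indices over the full length (-1 at padding)."""

    record_id: str
    q8: np.ndarray
    q3: np.ndarray
    easy_routed: np.ndarray   # bool, full length (False at padding)
    entropy: np.ndarray       # easy-head opinion entropy, nan at padding
    mask: np.ndarray


def _class_labels(record: ProteinRecord, n_classes: int) -> np.ndarray:
    return Q8_TO_Q3_INDEX[record.q8_labels] if n_classes == 3 else record.q8_labels


def _batchify(feature_list, label_list, mask_list, idx):
    T = max(feature_list[i].shape[0] for i in idx)
    B = len(idx)
    X = np.zeros((B, T, 50))
    Y = np.zeros((B, T), dtype=int)
    M = np.zeros((B, T), dtype=bool)
    for j, i in enumerate(idx):
        L = feature_list[i].shape[0]
        X[j, :L] = feature_list[i]
        Y[j, :L] = label_list[i]
        M[j, :L] = mask_list[i]
    return X, Y, M


def _onehot(y: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(y.shape + (n,))
    np.put_along_axis(out, y[..., None], 1.0, axis=-1)
    return out


def _forward(model: CascadeModel, X, M, easy_only: bool):
    feats = Tensor(X)
    if easy_only:
        l = model.extractor.branch_project(feats)
        c = model.extractor.multiscale_conv(l)
        return model.easy_head(c), None
    easy_logits, hard_logits = model(feats, M)
    return easy_logits, hard_logits


def _batch_losses(model, X, Y, M, cfg: TrainConfig, routing: RoutingConfig | None,
                  phase: str, frozen_threshold: float | None = None):
    """Forward pass + routing + the four loss nodes for one padded batch.

    Returns (backprop Tensor, LossBreakdown, RoutingDecision over masked
    residues, easy/hard logit tensors).
    """
    Z = cfg.n_classes
    easy_only = cfg.variant == "c1"
    easy_logits, hard_logits = _forward(model, X, M, easy_only)
    Yhot = _onehot(Y, Z) * M[..., None]

    flat_mask = M.reshape(-1)
    opinions = opinion_from_logits(easy_logits.data.reshape(-1, Z)[flat_mask])
    if routing is None:
        decision = RoutingDecision(assignment=np.ones(int(flat_mask.sum()), dtype=bool),
                                   threshold_value=float("nan"))
    else:
        logits_flat = easy_logits.data.reshape(-1, Z)[flat_mask]
        z = logits_flat - logits_flat.max(axis=-1, keepdims=True)
        sm = np.exp(z)
        conf = (sm / sm.sum(axis=-1, keepdims=True)).max(axis=-1)
        decision = route(opinions, Y.reshape(-1)[flat_mask], routing, phase=phase,
                         confidence=conf, frozen_threshold=frozen_threshold)

    w_all = M.astype(float)
    ce_easy = masked_cross_entropy(easy_logits, Yhot, w_all)
    if easy_only:
        breakdown = total_loss(float(ce_easy.data), 0.0, 0.0, 0.0, beta=cfg.beta)
        return ce_easy, breakdown, decision, easy_logits, None

    hard_w = np.zeros(flat_mask.shape)
    hard_w[np.nonzero(flat_mask)[0][decision.hard]] = 1.0
    hard_w = hard_w.reshape(M.shape)

    dir_easy = masked_dirichlet_loss(easy_logits, Yhot, w_all)
    ce_hard = masked_cross_entropy(hard_logits, Yhot, hard_w)
    dir_hard = masked_dirichlet_loss(hard_logits, Yhot, hard_w)

    breakdown = total_loss(float(ce_easy.data), float(dir_easy.data),
                           float(ce_hard.data), float(dir_hard.data), beta=cfg.beta)
    if cfg.variant == "mccm_easy":
        backprop = ce_easy + cfg.beta * dir_easy
    else:
        backprop = ce_easy + cfg.beta * dir_easy + ce_hard + cfg.beta * dir_hard
    return backprop, breakdown, decision, easy_logits, hard_logits


def fit(
    train_records: Sequence[ProteinRecord],
    valid_records: Sequence[ProteinRecord] | None = None,
    train_config: TrainConfig | None = None,
    extractor_config: ExtractorConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
    log_path: str | Path | None = None,
) -> tuple[TrainedModel, list[EpochStats]]:
    """Train a cascade model; deterministic given the config seed.

    Returns the trained model (with the frozen routing threshold) and a
    per-epoch history of loss components and residue accuracies.
    """
    if len(train_records) == 0:
        raise ValueError("empty training set")
    cfg = train_config or TrainConfig()
    ex_cfg = extractor_config or ExtractorConfig()
    ex_cfg = ExtractorConfig(**{**asdict_extractor(ex_cfg), "dropout": cfg.dropout})
    cl_cfg = classifier_config or ClassifierConfig(n_classes=cfg.n_classes)
    cl_cfg.n_classes = cfg.n_classes
    cl_cfg.dropout = cfg.dropout
    routing = cfg.routing_config()

    rng = np.random.default_rng(cfg.seed)
    model = CascadeModel(rng, ex_cfg, cl_cfg)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)

    feats = [assemble_features(r) for r in train_records]
    labels = [_class_labels(r, cfg.n_classes) for r in train_records]
    masks = [r.mask for r in train_records]

    thresholds: list[float] = []
    history: list[EpochStats] = []
    log_rows: list[str] = []
    n = len(train_records)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        comp = np.zeros(4)
        backprop_sum = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            X, Y, M = _batchify(feats, labels, masks, idx)
            loss, breakdown, decision, _, _ = _batch_losses(
                model, X, Y, M, cfg, routing, phase="train")
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch starting {start} (components {breakdown.as_dict()})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            comp += [breakdown.ce_easy, breakdown.dir_easy,
                     breakdown.ce_hard, breakdown.dir_hard]
            backprop_sum += float(loss.data)
            if routing is not None and routing.mode == "evidential" \
                    and np.isfinite(decision.threshold_value):
                thresholds.append(decision.threshold_value)
            n_batches += 1

        comp /= n_batches
        epoch_loss = total_loss(*comp, beta=cfg.beta)
        thr = float(np.mean(thresholds)) if thresholds else float("nan")
        trained = TrainedModel(model=model, train_config=cfg, extractor_config=ex_cfg,
                               routing=routing, frozen_threshold=thr, seed=cfg.seed)
        train_q = _quick_accuracy(trained, feats, labels, masks)
        if valid_records:
            vfeats = [assemble_features(r) for r in valid_records]
            vlabels = [_class_labels(r, cfg.n_classes) for r in valid_records]
            vmasks = [r.mask for r in valid_records]
            valid_q = _quick_accuracy(trained, vfeats, vlabels, vmasks)
        else:
            valid_q = float("nan")
        history.append(EpochStats(epoch=epoch, loss=epoch_loss,
                                  backprop_loss=backprop_sum / n_batches,
                                  train_q=train_q, valid_q=valid_q, threshold=thr))
        log_rows.append("\t".join(
            f"{v:.6g}" for v in [epoch, epoch_loss.ce_easy, epoch_loss.dir_easy,
                                 epoch_loss.ce_hard, epoch_loss.dir_hard,
                                 epoch_loss.total, train_q, valid_q]))

    if log_path is not None:
        header = "epoch\tce_easy\tdir_easy\tce_hard\tdir_hard\ttotal\ttrain_q\tvalid_q"
        Path(log_path).write_text("\n".join([header] + log_rows) + "\n")
    trained = TrainedModel(model=model, train_config=cfg, extractor_config=ex_cfg,
                           routing=routing, frozen_threshold=float(np.mean(thresholds))
                           if thresholds else float("nan"), seed=cfg.seed)
    return trained, history


def asdict_extractor(cfg: ExtractorConfig) -> dict:
    d = asdict(cfg)
    d["branch_hidden"] = tuple(d["branch_hidden"])
    d["conv_kernels"] = tuple(d["conv_kernels"])
    return d


def _quick_accuracy(trained, feats, labels, masks) -> float:
    correct = 0
    count = 0
    for f, y, m in zip(feats, labels, masks):
        pred = _predict_one(trained, f, m, labels_for_routing=y)
        correct += int((pred["calls"][m] == y[m]).sum())
        count += int(m.sum())
    return 100.0 * correct / max(count, 1)


def _predict_one(trained: TrainedModel, features: np.ndarray, mask: np.ndarray,
                 labels_for_routing: np.ndarray | None = None) -> dict:
    cfg = trained.train_config
    model = trained.model
    model.eval()
    L = features.shape[0]
    Z = cfg.n_classes
    if not mask.any():
        return {"calls": np.full(L, -1, dtype=int),
                "easy": np.zeros(L, dtype=bool),
                "entropy": np.full(L, np.nan)}
    X = features[None, :, :]
    M = mask[None, :]
    easy_only = cfg.variant == "c1"
    easy_logits, hard_logits = _forward(model, X, M, easy_only)
    flat = mask
    e_logits = easy_logits.data[0][flat]
    opinions = opinion_from_logits(e_logits)
    if easy_only or trained.routing is None:
        decision = RoutingDecision(np.ones(int(flat.sum()), dtype=bool), float("nan"))
    else:
        if trained.routing.mode == "evidential" and not np.isfinite(trained.frozen_threshold):
            raise ValueError("evidential prediction requires a frozen threshold; train first")
        z = e_logits - e_logits.max(axis=-1, keepdims=True)
        sm = np.exp(z)
        conf = (sm / sm.sum(axis=-1, keepdims=True)).max(axis=-1)
        lab = labels_for_routing[flat] if labels_for_routing is not None else None
        decision = route(opinions, lab, trained.routing, phase="test",
                         confidence=conf, frozen_threshold=trained.frozen_threshold)
    easy_pred = opinions.prediction
    if easy_only:
        calls_masked = easy_pred
    else:
        h_logits = hard_logits.data[0][flat]
        hard_pred = np.argmax(np.maximum(h_logits, 0.0) + 1.0, axis=-1)
        calls_masked = np.where(decision.easy, easy_pred, hard_pred)
    calls = np.full(L, -1, dtype=int)
    calls[mask] = calls_masked
    easy_full = np.zeros(L, dtype=bool)
    easy_full[mask] = decision.easy
    ent = np.full(L, np.nan)
    ent[mask] = opinions.entropy
    return {"calls": calls, "easy": easy_full, "entropy": ent}


def predict(trained: TrainedModel, records: Sequence[ProteinRecord],
            labels_known: bool = True) -> list[PredictionResult]:
    """Per-residue state calls with easy/hard routing flags.

    ``labels_known=False`` declares that record labels are not to be used;
    label-routed variants then refuse to predict (their routing rule needs
    the truth), while evidential and confidence routing proceed label-free.
    """
    cfg = trained.train_config
    if trained.routing is not None and trained.routing.mode == "label" and not labels_known:
        raise ValueError("label-routed variants need labels at prediction time")
    out = []
    for rec in records:
        feats = assemble_features(rec)
        lab = _class_labels(rec, cfg.n_classes) if labels_known else None
        res = _predict_one(trained, feats, rec.mask, labels_for_routing=lab)
        calls = res["calls"]
        if cfg.n_classes == 3:
            q3 = calls
            q8 = np.full_like(calls, -1)
        else:
            q8 = calls
            q3 = np.where(calls >= 0, Q8_TO_Q3_INDEX[np.clip(calls, 0, 7)], -1)
        out.append(PredictionResult(record_id=rec.id, q8=q8, q3=q3,
                                    easy_routed=res["easy"], entropy=res["entropy"],
                                    mask=rec.mask))
    return out


# --- checkpoints -------------------------------------------------------------

def save_checkpoint(trained: TrainedModel, path: str | Path) -> None:
    """Bundle weights, configs, frozen threshold and seed into one .npz."""
    meta = {
        "train_config": asdict(trained.train_config),
        "extractor_config": asdict_extractor(trained.extractor_config),
        "classifier_config": asdict(trained.model.classifier_config),
        "frozen_threshold": trained.frozen_threshold,
        "seed": trained.seed,
    }
    arrays = {f"w{i}": a for i, a in enumerate(trained.model.state_arrays())}
    np.savez(Path(path), meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> TrainedModel:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    tc = TrainConfig(**meta["train_config"])
    ec_d = meta["extractor_config"]
    ec_d["branch_hidden"] = tuple(ec_d["branch_hidden"])
    ec_d["conv_kernels"] = tuple(ec_d["conv_kernels"])
    ec = ExtractorConfig(**ec_d)
    cc_d = meta["classifier_config"]
    cc_d["mlp_hidden"] = tuple(cc_d["mlp_hidden"])
    cc = ClassifierConfig(**cc_d)
    model = CascadeModel(np.random.default_rng(meta["seed"]), ec, cc)
    model.load_state_arrays(arrays)
    return TrainedModel(model=model, train_config=tc, extractor_config=ec,
                        routing=tc.routing_config(),
                        frozen_threshold=float(meta["frozen_threshold"]),
                        seed=int(meta["seed"]))
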