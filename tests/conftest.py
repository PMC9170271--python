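"""Shared fixtures: small extractor configs and cached behavioural runs.

The behavioural runs (separable task, planted-hard task, variant
comparisons) are session-scoped so the training and acceptance tests share
one computation each.
"""

from __future__ import annotations

import numpy as np
import pytest

import mccm
from mccm.cascade import ClassifierConfig
from mccm.extractor import ExtractorConfig

# Desk-scale extractor/classifier widths used by the behavioural runs.
DESK_EXTRACTOR = dict(branch_hidden=(16, 24, 8, 4), conv_hidden=12,
                      conv_kernels=(3, 5, 7), recurrent_hidden=16, attention_hidden=16)
DESK_MLP = (48, 64)
DESK_LR = 5e-3
DESK_DROPOUT = 0.2  # scaled to the small desk widths; 0.5 suits 512/1024 layers


@pytest.fixture
def tiny_extractor_config() -> ExtractorConfig:
    return ExtractorConfig(branch_hidden=(4, 4, 2, 2), conv_hidden=4,
                           conv_kernels=(3, 5), recurrent_hidden=4, attention_hidden=4)


@pytest.fixture
def desk_extractor_config() -> ExtractorConfig:
    return ExtractorConfig(**DESK_EXTRACTOR)


def desk_fit(records, variant, seed, epochs, valid=None, per=30.0, n_classes=8):
    cfg = mccm.TrainConfig(epochs=epochs, batch_size=10, seed=seed, variant=variant,
                           per=per, learning_rate=DESK_LR, dropout=DESK_DROPOUT,
                           n_classes=n_classes)
    return mccm.fit(records, valid, cfg, ExtractorConfig(**DESK_EXTRACTOR),
                    ClassifierConfig(mlp_hidden=DESK_MLP))


@pytest.fixture(scope="session")
def separable_run():
    """Fully separable Q8 task (all residues easy, no label noise)."""
    spec = mccm.SyntheticSpec(n_proteins=50, length_range=(80, 120), seed=11,
                              easy_fraction=1.0, label_noise=0.0)
    records = mccm.generate(spec)
    trained, history = desk_fit(records, "mccm_dir", seed=0, epochs=30)
    preds = mccm.predict(trained, records, labels_known=False)
    report = mccm.evaluate(records, preds)
    return dict(records=records, trained=trained, history=history,
                predictions=preds, report=report)


@pytest.fixture(scope="session")
def planted_run():
    """Task with a planted 30% of hard residues (overlapping classes)."""
    spec = mccm.SyntheticSpec(n_proteins=40, length_range=(80, 100), seed=23,
                              easy_fraction=0.7, hard_overlap=1.0)
    records = mccm.generate(spec)
    trained, history = desk_fit(records, "mccm_dir", seed=1, epochs=8)
    preds = mccm.predict(trained, records, labels_known=False)
    return dict(records=records, trained=trained, history=history, predictions=preds)


@pytest.fixture(scope="session")
def loss_ordering_runs():
    """mccm vs mccm_easy on identical data and seed."""
    spec = mccm.SyntheticSpec(n_proteins=40, length_range=(80, 100), seed=37,
                              easy_fraction=0.7, hard_overlap=1.0)
    records = mccm.generate(spec)
    _, hist_full = desk_fit(records, "mccm", seed=2, epochs=8)
    _, hist_easy = desk_fit(records, "mccm_easy", seed=2, epochs=8)
    return dict(records=records, mccm=hist_full, mccm_easy=hist_easy)


@pytest.fixture(scope="session")
def seed_grid_runs():
    """mccm_dir vs the easy-only ablation over five seeds; accuracy on the
    planted-hard residues of each dataset."""
    rows = []
    for seed in range(5):
        spec = mccm.SyntheticSpec(n_proteins=30, length_range=(60, 80), seed=100 + seed,
                                  easy_fraction=0.7, hard_overlap=1.0)
        records = mccm.generate(spec)
        accs = {}
        for variant in ("mccm_dir", "c1"):
            trained, _ = desk_fit(records, variant, seed=seed, epochs=30)
            preds = mccm.predict(trained, records, labels_known=False)
            correct = total = 0
            for rec, pred in zip(records, preds):
                hard = rec.mask & ~rec.easy_flags
                correct += int((pred.q8[hard] == rec.q8_labels[hard]).sum())
                total += int(hard.sum())
            accs[variant] = 100.0 * correct / total
        rows.append(accs)
    return rows
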