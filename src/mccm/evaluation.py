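"""Q-score metrics, confusion matrices and report tables.

Q_k = 100 x (number of correctly predicted residues) / N, for k = 3 or 8
states.  Q3 is computed after coarsening both streams with the fixed
eight-to-three mapping (B,E)->E, (G,I,H)->H, (S,T,C)->C, so a correct Q8
call is always a correct Q3 call and Q3 >= Q8 on the same predictions.

Confusion matrices are reported as percent-of-total with predicted labels
on rows and true labels on columns, plus "Pred freq." / "True freq."
marginals; per-label accuracy is recall (percent correct among residues
whose *true* label is the given state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import Q8_TO_Q3_INDEX, ProteinRecord
from .tables import Q3_STATES, Q8_STATES
from .training import PredictionResult


def _validate(true_labels, predicted_labels, k: int):
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label streams differ in length")
    if t.size == 0:
        raise ValueError("empty label streams")
    if t.min() < 0 or t.max() >= k or p.min() < 0 or p.max() >= k:
        raise ValueError(f"labels out of range for k={k}")
    return t, p


def _coarsen(t, p, k):
    """Map Q8 streams to Q3 when scoring at k=3."""
    if k == 3 and (t.max() > 2 or p.max() > 2):
        return Q8_TO_Q3_INDEX[t], Q8_TO_Q3_INDEX[p]
    return t, p


def q_score(true_labels, predicted_labels, k: int = 8) -> float:
    """Percentage of residues with a correct k-state call."""
    if k not in (3, 8):
        raise ValueError("k must be 3 or 8")
    t, p = _validate(true_labels, predicted_labels, 8 if k == 3 else k)
    t, p = _coarsen(t, p, k)
    score = 100.0 * float((t == p).mean())
    # internal cross-check: Q equals the trace of the count confusion matrix / N
    counts = _count_matrix(t, p, k)
    assert abs(score - 100.0 * np.trace(counts) / t.size) < 1e-9
    return score


def _count_matrix(t, p, k) -> np.ndarray:
    m = np.zeros((k, k), dtype=int)
    np.add.at(m, (p, t), 1)
    return m


def confusion_matrix(true_labels, predicted_labels, k: int = 8) -> pd.DataFrame:
    """Percent-of-total confusion matrix (rows = predicted, columns = true).

    Includes a "Pred freq." column and a "True freq." row as marginals;
    entries sum to 100.
    """
    if k not in (3, 8):
        raise ValueError("k must be 3 or 8")
    t, p = _validate(true_labels, predicted_labels, 8 if k == 3 else k)
    t, p = _coarsen(t, p, k)
    states = Q3_STATES if k == 3 else Q8_STATES
    counts = _count_matrix(t, p, k)
    pct = 100.0 * counts / t.size
    df = pd.DataFrame(pct, index=states, columns=states)
    df.insert(0, "Pred freq.", pct.sum(axis=1))
    true_row = pd.DataFrame([[100.0] + list(pct.sum(axis=0))],
                            index=["True freq."], columns=df.columns)
    out = pd.concat([true_row, df])
    out.attrs["n_labels"] = int(t.size)
    return out


def per_label_accuracy(true_labels, predicted_labels) -> dict[str, float]:
    """Recall per Q8 state in percent; NaN marks states absent from truth."""
    t, p = _validate(true_labels, predicted_labels, 8)
    out = {}
    for z, state in enumerate(Q8_STATES):
        sel = t == z
        out[state] = 100.0 * float((p[sel] == z).mean()) if sel.any() else float("nan")
    return out


@dataclass
class EvalReport:
    q3: float
    q8: float
    per_label: dict[str, float]
    confusion_q3: pd.DataFrame
    confusion_q8: pd.DataFrame
    n_labels: int

    def as_dict(self) -> dict:
        return {
            "q3": self.q3,
            "q8": self.q8,
            "n_labels": self.n_labels,
            "per_label_accuracy": {k: (None if np.isnan(v) else v)
                                   for k, v in self.per_label.items()},
        }


def evaluate(records: Sequence[ProteinRecord],
             predictions: Sequence[PredictionResult]) -> EvalReport:
    """Score a prediction set against record labels (masked residues only)."""
    if len(records) != len(predictions):
        raise ValueError("records and predictions differ in length")
    true_q8, pred_q8 = [], []
    for rec, pred in zip(records, predictions):
        m = rec.mask
        if not m.any():
            continue
        if np.any(pred.q8[m] < 0):
            raise ValueError("Q8 evaluation needs eight-state predictions")
        true_q8.append(rec.q8_labels[m])
        pred_q8.append(pred.q8[m])
    t = np.concatenate(true_q8)
    p = np.concatenate(pred_q8)
    q8 = q_score(t, p, k=8)
    q3 = q_score(t, p, k=3)
    return EvalReport(q3=q3, q8=q8, per_label=per_label_accuracy(t, p),
                      confusion_q3=confusion_matrix(t, p, k=3),
                      confusion_q8=confusion_matrix(t, p, k=8),
                      n_labels=int(t.size))


def render_report(report: EvalReport, out_dir: str | Path, prefix: str = "eval") -> None:
    """Write tab-separated report tables and a machine-readable JSON."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["Label\tAccuracy"]
    for state, acc in report.per_label.items():
        rows.append(f"{state}\t{'NA' if np.isnan(acc) else f'{acc:.2f}'}")
    (out_dir / f"{prefix}_per_label.tsv").write_text("\n".join(rows) + "\n")
    report.confusion_q3.to_csv(out_dir / f"{prefix}_confusion_q3.tsv",
                               sep="\t", float_format="%.2f")
    report.confusion_q8.to_csv(out_dir / f"{prefix}_confusion_q8.tsv",
                               sep="\t", float_format="%.2f")
    (out_dir / f"{prefix}_metrics.json").write_text(
        json.dumps(report.as_dict(), indent=2) + "\n")
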