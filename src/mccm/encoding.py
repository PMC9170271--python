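"""Residue feature encoding for packed CullPDB-style benchmark arrays.

The benchmark files (CB6133-filtered for training, CB513 for testing) store
each protein as a flat row of 700 residue slots x 57 channels.  This module
reads that layout into :class:`ProteinRecord` objects and builds the
50-dimensional per-residue input encoding used by the predictor:

    [ 21 one-hot | 21 logistic-rescaled profile | 7 physicochemical | 1 conservation ]

The conservation score is recovered from the profile block: the logistic
rescale is inverted to give per-residue substitution scores S_i, the
probabilities L_i = exp(S_i * lambda_u) * P_i are recovered against a
background distribution P, renormalised onto the simplex, and scored as

    R = log 20 + sum_i L_i log L_i          (natural log, R in [0, log 20])

which is log 20 minus the Shannon entropy of L: 0 for a uniform column,
log 20 for a perfectly conserved one.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import AA_ORDER, Q3_STATES, Q8_STATES, background_frequencies, physchem_table

# --- packed layout constants (700 slots x 57 channels) -----------------------
N_SLOTS = 700
N_CHANNELS = 57
ROW_WIDTH = N_SLOTS * N_CHANNELS  # 39900
ONEHOT = slice(0, 22)       # 20 aa + X + NoSeq
LABELS = slice(22, 31)      # C(L) B E G I H S T + NoSeq
TERMINALS = slice(31, 33)   # N-/C-terminal flags (read, unused)
SOLVENT = slice(33, 35)     # relative/absolute solvent accessibility (read, unused)
PROFILE = slice(35, 57)     # 20 aa + X + NoSeq, logistic-rescaled

#: Natural-log scale constant of the profile score recovery.
LAMBDA_U = 0.3176

_Q8_INDEX = {s: i for i, s in enumerate(Q8_STATES)}
_Q8_TO_Q3 = {"B": "E", "E": "E", "G": "H", "I": "H", "H": "H", "S": "C", "T": "C", "C": "C"}


class FormatError(ValueError):
    """Packed array does not have the expected benchmark layout."""


class DataIntegrityError(ValueError):
    """Packed array content violates the layout's internal consistency."""


@dataclass
class ProteinRecord:
    """One protein: identities, feature blocks, labels and validity mask.

    All per-residue arrays have ``length`` rows; ``mask`` is True for real
    residues and False for padding (NoSeq) slots.  ``easy_flags`` is only
    populated by the synthetic generator (ground-truth difficulty of each
    residue) and is None for benchmark data.
    """

    id: str
    residue_onehot: np.ndarray    # length x 21
    profile_logistic: np.ndarray  # length x 21, entries in (0,1)
    q8_labels: np.ndarray         # length vector of Q8 state indices
    mask: np.ndarray              # length bools
    terminals: np.ndarray | None = None   # length x 2, unused by the model
    solvent: np.ndarray | None = None     # length x 2, unused by the model
    easy_flags: np.ndarray | None = None  # length bools, synthetic only

    @property
    def length(self) -> int:
        return int(self.mask.shape[0])

    def q8_states(self) -> list[str]:
        """Q8 labels as letters, masked-true positions only."""
        return [Q8_STATES[z] for z in self.q8_labels[self.mask]]


@dataclass
class EncodingConfig:
    """Knobs of the profile-to-conservation recovery."""

    lambda_u: float = LAMBDA_U
    background_probs: np.ndarray = field(default_factory=background_frequencies)
    logistic_rescale: bool = True

    def __post_init__(self) -> None:
        p = np.asarray(self.background_probs, dtype=float)
        if p.shape != (20,) or np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("background_probs must be a positive 20-vector summing to 1")
        self.background_probs = p


def _load_packed(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rb") as fh:
            arr = np.load(fh)
    else:
        arr = np.load(path)
    arr = np.asarray(arr)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.ndim != 2 or arr.shape[1] != ROW_WIDTH:
        raise FormatError(
            f"expected packed rows of width {ROW_WIDTH} (700 slots x 57 channels), "
            f"got shape {arr.shape}"
        )
    return arr


def read_cullpdb_arrays(path: str | Path, limit: int | None = None) -> list[ProteinRecord]:
    """Read a packed benchmark file into one :class:`ProteinRecord` per row.

    NoSeq slots become mask=False; the 22-channel one-hot and profile blocks
    are reduced to 21 dims by dropping the NoSeq channel.  A masked-true slot
    whose label channels are all zero raises :class:`DataIntegrityError`.
    """
    arr = _load_packed(path)
    if limit is not None:
        arr = arr[:limit]
    records = []
    for r, row in enumerate(arr):
        grid = row.reshape(N_SLOTS, N_CHANNELS)
        onehot22 = grid[:, ONEHOT]
        labels9 = grid[:, LABELS]
        mask = onehot22[:, 21] == 0  # NoSeq one-hot channel marks padding
        # trim trailing padding: records keep only slots up to the last residue
        if mask.any():
            length = int(np.nonzero(mask)[0][-1]) + 1
        else:
            length = 0
        grid = grid[:length]
        mask = mask[:length]
        lab8 = grid[:, LABELS][:, :8]
        bad = mask & (lab8.sum(axis=1) == 0)
        if bad.any():
            raise DataIntegrityError(
                f"protein {r}: residue {int(np.nonzero(bad)[0][0])} has no label set"
            )
        records.append(
            ProteinRecord(
                id=f"protein_{r}",
                residue_onehot=grid[:, ONEHOT][:, :21].astype(float),
                profile_logistic=grid[:, PROFILE][:, :21].astype(float),
                q8_labels=np.argmax(lab8, axis=1),
                mask=mask,
                terminals=grid[:, TERMINALS].astype(float),
                solvent=grid[:, SOLVENT].astype(float),
            )
        )
    return records


def records_to_packed(records: Sequence[ProteinRecord]) -> np.ndarray:
    """Serialise records back to the packed N x 39900 layout (float32)."""
    if len(records) == 0:
        raise ValueError("no records to serialise")
    out = np.zeros((len(records), N_SLOTS, N_CHANNELS), dtype=np.float32)
    for r, rec in enumerate(records):
        L = rec.length
        if L > N_SLOTS:
            raise FormatError(f"protein {rec.id} longer than {N_SLOTS} slots")
        grid = out[r]
        m = rec.mask
        grid[:L, ONEHOT][:, :21] = rec.residue_onehot
        grid[:L, PROFILE][:, :21] = rec.profile_logistic
        lab = np.zeros((L, 9), dtype=np.float32)
        lab[np.arange(L)[m], rec.q8_labels[m]] = 1.0
        lab[~m, 8] = 1.0
        grid[:L, LABELS] = lab
        if rec.terminals is not None:
            grid[:L, TERMINALS] = rec.terminals
        if rec.solvent is not None:
            grid[:L, SOLVENT] = rec.solvent
        # NoSeq markers on padding slots, inside and after the record
        grid[:L, 21][~m] = 1.0
        grid[L:, 21] = 1.0
        grid[L:, LABELS.start + 8] = 1.0
    return out.reshape(len(records), ROW_WIDTH)


# --- profile score / probability recovery ------------------------------------

def profile_prob_from_score(score, background_prob, lambda_u: float = LAMBDA_U):
    """Recover the substitution probability L = exp(score * lambda_u) * P."""
    score = np.asarray(score, dtype=float)
    if not np.all(np.isfinite(score)):
        raise ValueError("non-finite profile score")
    return np.exp(score * lambda_u) * background_prob


def profile_score_from_prob(prob, background_prob, lambda_u: float = LAMBDA_U):
    """Inverse map: S = ln(L / P) / lambda_u."""
    prob = np.asarray(prob, dtype=float)
    if np.any(prob <= 0) or np.any(prob >= 1):
        raise ValueError("probability must lie strictly in (0,1)")
    return np.log(prob / background_prob) / lambda_u


def conservation_score(probs) -> float:
    """Column conservation R = log 20 + sum L log L (nats), with 0*log0 = 0."""
    L = np.asarray(probs, dtype=float)
    if L.shape[-1] != 20:
        raise ValueError("conservation_score expects 20 probabilities")
    if np.any(L < 0):
        raise ValueError("negative probability")
    if np.any(np.abs(L.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError("probabilities must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(L > 0, L * np.log(L), 0.0)
    return np.log(20.0) + plogp.sum(axis=-1)


def map_q8_to_q3(q8_label: str) -> str:
    """Coarsen a Q8 state: (B,E)->E, (G,I,H)->H, (S,T,C)->C."""
    try:
        return _Q8_TO_Q3[q8_label]
    except KeyError:
        raise ValueError(f"unknown Q8 state {q8_label!r}") from None


#: Index-level Q8 -> Q3 coarsening aligned with Q8_STATES / Q3_STATES.
Q8_TO_Q3_INDEX = np.array([Q3_STATES.index(_Q8_TO_Q3[s]) for s in Q8_STATES])


def _recover_simplex(profile_logistic: np.ndarray, config: EncodingConfig) -> np.ndarray:
    """Per-residue 20-simplex of substitution probabilities from the profile block."""
    p = np.clip(profile_logistic[:, :20], 1e-7, 1.0 - 1e-7)
    if config.logistic_rescale:
        scores = np.log(p / (1.0 - p))  # invert the logistic rescale
    else:
        scores = p
    L = np.exp(scores * config.lambda_u) * config.background_probs
    return L / L.sum(axis=1, keepdims=True)


def assemble_features(
    record: ProteinRecord,
    physchem_lookup: np.ndarray | None = None,
    config: EncodingConfig | None = None,
) -> np.ndarray:
    """Build the length x 50 input matrix for one protein.

    Block order is [one-hot 21 | profile 21 | physchem 7 | conservation 1];
    rows at mask=False positions are all zero.
    """
    if physchem_lookup is None:
        physchem_lookup = physchem_table()
    if physchem_lookup.shape != (21, 7):
        raise ValueError("physchem lookup must be 21x7, aligned with the one-hot order")
    config = config or EncodingConfig()
    L = record.length
    out = np.zeros((L, 50))
    m = record.mask
    if not m.any():
        return out
    onehot = record.residue_onehot[m]
    if np.any(onehot.sum(axis=1) == 0):
        raise ValueError("masked-true residue with no identity set")
    simplex = _recover_simplex(record.profile_logistic[m], config)
    out[m, 0:21] = onehot
    out[m, 21:42] = record.profile_logistic[m]
    out[m, 42:49] = physchem_lookup[np.argmax(onehot, axis=1)]
    out[m, 49] = conservation_score(simplex)
    return out


def dataset_statistics(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Per-Q8-state label counts and frequencies over all masked-true residues.

    Returns a frame with one row per Q8 state (columns Label, Count,
    Frequency in percent) plus attrs ``n_proteins`` and ``n_labels``.
    """
    if len(records) == 0:
        raise ValueError("no records")
    counts = np.zeros(8, dtype=int)
    for rec in records:
        idx, c = np.unique(rec.q8_labels[rec.mask], return_counts=True)
        counts[idx] += c
    total = int(counts.sum())
    df = pd.DataFrame(
        {
            "Label": Q8_STATES,
            "Count": counts,
            "Frequency": 100.0 * counts / max(total, 1),
        }
    )
    df.attrs["n_proteins"] = len(records)
    df.attrs["n_labels"] = total
    return df
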