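"""Synthetic protein-like records with controllable easy/hard structure.

The generator emulates the statistical situation the cascade model assumes:
most residues are *easy* (their profile features sit in well-separated
class-conditional clusters) while a controllable fraction is *hard* (cluster
centroids pulled together so classes overlap and any classifier is
uncertain).  Labels follow a short-memory Markov chain so that secondary
structure comes in runs, giving the convolutional and recurrent stages real
local/global context to exploit.  Ground-truth easy/hard flags are recorded
on each record so routing can be checked against planted difficulty.

Class-conditional features live in the 20-dim profile *score* space (one
random unit-direction centroid per class, isotropic unit noise) and are
pushed through the logistic rescale, so generated records are drawn from the
same 57-channel packed layout contract as benchmark data and round-trip
through :mod:`mccm.encoding` exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import ProteinRecord, records_to_packed
from .tables import AA_ORDER, Q8_STATES

#: Default Q8 state frequencies (percent) matching a realistic benchmark
#: label distribution, in Q8_STATES order C B E G I H S T.
DEFAULT_Q8_FREQ = {"C": 21.14, "B": 1.39, "E": 21.25, "G": 3.69,
                   "I": 0.04, "H": 30.86, "S": 9.81, "T": 11.81}

_Q3_REPRESENTATIVES = ["H", "E", "C"]  # Q8 states used when class_set="Q3"


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic dataset; fully reproducible given ``seed``."""

    n_proteins: int = 50
    length_range: tuple[int, int] = (80, 120)
    class_set: str = "Q8"                 # "Q8", "Q3", or via `states`
    easy_fraction: float = 0.8
    hard_overlap: float = 1.0             # pairwise centroid distance, hard residues
    label_noise: float = 0.0
    seed: int = 0
    states: list[str] | None = None       # explicit Q8 state subset (overrides class_set)
    class_freq: dict[str, float] | None = None
    easy_separation: float = 11.0         # pairwise centroid distance, easy residues
    stay_prob: float = 0.9                # Markov self-transition (run lengths ~10)
    hard_burst: float = 6.0               # mean length of hard segments (residues)

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid length_range {self.length_range}")
        if not 0.0 <= self.easy_fraction <= 1.0:
            raise ValueError("easy_fraction must be in [0,1]")
        if self.hard_overlap < 0:
            raise ValueError("hard_overlap must be >= 0")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0,1]")

    def state_letters(self) -> list[str]:
        if self.states is not None:
            bad = set(self.states) - set(Q8_STATES)
            if bad:
                raise ValueError(f"unknown states {sorted(bad)}")
            return list(self.states)
        if self.class_set.upper() == "Q3":
            return list(_Q3_REPRESENTATIVES)
        if self.class_set.upper() == "Q8":
            return list(Q8_STATES)
        raise ValueError(f"class_set must be Q3 or Q8, got {self.class_set!r}")

    def state_frequencies(self) -> np.ndarray:
        letters = self.state_letters()
        src = self.class_freq or DEFAULT_Q8_FREQ
        v = np.array([float(src.get(s, 0.0)) for s in letters])
        if v.sum() <= 0:
            v = np.ones(len(letters))
        return v / v.sum()

    def to_json(self, path: str | Path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        d["length_range"] = list(self.length_range)
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        d = json.loads(Path(path).read_text())
        d["length_range"] = tuple(d["length_range"])
        return cls(**d)


def _centroids(rng: np.random.Generator, n_classes: int) -> np.ndarray:
    """Random unit directions in the 20-dim profile-score space.

    Scaled by s, two such centroids are at distance ~ s*sqrt(2), so callers
    scale by separation/sqrt(2) to realise a target pairwise distance.
    """
    u = rng.normal(size=(n_classes, 20))
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def _hard_segments(rng, length, easy_fraction, mean_hard_len):
    """Bursty easy/hard flags: a two-state chain whose hard segments average
    ``mean_hard_len`` residues, with the stationary easy share kept at
    ``easy_fraction``.  Mirrors how profile quality degrades over whole
    poorly-aligned stretches rather than isolated positions.
    """
    if easy_fraction >= 1.0:
        return np.ones(length, dtype=bool)
    if easy_fraction <= 0.0:
        return np.zeros(length, dtype=bool)
    leave_hard = 1.0 / max(mean_hard_len, 1.0)
    mean_easy_len = mean_hard_len * easy_fraction / (1.0 - easy_fraction)
    leave_easy = 1.0 / max(mean_easy_len, 1.0)
    flags = np.empty(length, dtype=bool)
    flags[0] = rng.random() < easy_fraction
    for t in range(1, length):
        leave = leave_easy if flags[t - 1] else leave_hard
        flags[t] = ~flags[t - 1] if rng.random() < leave else flags[t - 1]
    return flags


def _markov_labels(rng, length, freq, stay_prob):
    states = np.empty(length, dtype=int)
    states[0] = rng.choice(len(freq), p=freq)
    for t in range(1, length):
        if rng.random() < stay_prob:
            states[t] = states[t - 1]
        else:
            states[t] = rng.choice(len(freq), p=freq)
    return states


def generate(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Draw ``spec.n_proteins`` records with planted easy/hard structure."""
    rng = np.random.default_rng(spec.seed)
    letters = spec.state_letters()
    state_idx = np.array([Q8_STATES.index(s) for s in letters])
    freq = spec.state_frequencies()
    n_cls = len(letters)

    directions = _centroids(rng, n_cls)
    easy_mu = directions * (spec.easy_separation / np.sqrt(2.0))
    hard_mu = directions * (spec.hard_overlap / np.sqrt(2.0))

    lo, hi = spec.length_range
    records = []
    for i in range(spec.n_proteins):
        L = int(rng.integers(lo, hi + 1))
        cls = _markov_labels(rng, L, freq, spec.stay_prob)
        easy = _hard_segments(rng, L, spec.easy_fraction, spec.hard_burst)

        scores = np.where(easy[:, None], easy_mu[cls], hard_mu[cls])
        scores = scores + rng.normal(size=(L, 20))
        profile = np.empty((L, 21))
        profile[:, :20] = 1.0 / (1.0 + np.exp(-scores))
        profile[:, 20] = 1.0 / (1.0 + np.exp(-rng.normal(size=L)))

        identities = rng.integers(0, 20, size=L)
        onehot = np.zeros((L, 21))
        onehot[np.arange(L), identities] = 1.0

        labels = state_idx[cls]
        if spec.label_noise > 0:
            flip = rng.random(L) < spec.label_noise
            labels = labels.copy()
            labels[flip] = state_idx[rng.integers(0, n_cls, size=int(flip.sum()))]

        terminals = np.zeros((L, 2))
        terminals[0, 0] = 1.0
        terminals[-1, 1] = 1.0
        records.append(
            ProteinRecord(
                id=f"synthetic_{i}",
                residue_onehot=onehot,
                profile_logistic=profile,
                q8_labels=labels,
                mask=np.ones(L, dtype=bool),
                terminals=terminals,
                solvent=np.zeros((L, 2)),
                easy_flags=easy,
            )
        )
    return records


def write_fixture(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Serialise records to the packed 57-channel layout read by the encoder.

    Stores float32, so values survive a write/read cycle bit-exactly
    provided they are float32-representable (the reader reproduces the
    stored bytes for masked-true channels).
    """
    if len(records) == 0:
        raise ValueError("no records to write")
    packed = records_to_packed(records)
    np.save(Path(path), packed)
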