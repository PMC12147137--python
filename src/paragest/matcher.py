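"""Dictionary matching: cosine-similarity pattern recognition plus an R^2
fidelity report.

Standard fingerprinting practice: both the measured trajectory and every
dictionary entry are L2-normalized and compared by inner product, so the
score is the cosine similarity in [-1, 1] and is insensitive to overall
signal scale.  The best hypothesis is the highest-scoring entry; ties are
broken lexicographically on the hypothesis key so results are deterministic
regardless of dictionary order or chunking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import FingerprintDictionary, MixtureHypothesis
from .engine import Fingerprint

__all__ = ["MatchResult", "normalize", "match", "fidelity_r2"]


def normalize(v: np.ndarray) -> np.ndarray:
    """Return v / ||v||_2; rejects the zero vector."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("cannot normalize the zero vector")
    return v / norm


def fidelity_r2(experimental: np.ndarray, simulated: np.ndarray) -> float:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot of the
    simulated trajectory against the experimental one, with SS_tot taken
    about the experimental mean."""
    experimental = np.asarray(experimental, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if experimental.shape != simulated.shape:
        raise ValueError("vectors must have equal length")
    ss_tot = float(np.sum((experimental - experimental.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("experimental vector is constant; R^2 undefined")
    ss_res = float(np.sum((experimental - simulated) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class MatchResult:
    """Ranked dictionary hits for one fingerprint."""

    entries: tuple[tuple[MixtureHypothesis, float], ...]
    best: MixtureHypothesis
    fidelity_r2: float

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be sorted descending")

    @property
    def best_score(self) -> float:
        return self.entries[0][1]

    def to_dict(self) -> dict:
        return {
            "best": {
                "subset": list(self.best.subset),
                "concentrations": list(self.best.concentrations),
            },
            "fidelity_r2": self.fidelity_r2,
            "entries": [
                {
                    "subset": list(h.subset),
                    "concentrations": list(h.concentrations),
                    "score": s,
                }
                for h, s in self.entries
            ],
        }


def match(
    fp: Fingerprint,
    dictionary: FingerprintDictionary,
    top_k: int = 10,
    chunk_size: int = 8192,
) -> MatchResult:
    """Match a fingerprint against every dictionary entry.

    Scores are accumulated chunk by chunk (memory stays bounded by the
    chunk), then the top ``top_k`` entries are selected with exact
    tie-breaking on the lexicographic hypothesis key.  The fidelity R^2 is
    computed between the input trajectory and the best entry's raw
    (un-normalized) simulated fingerprint.
    """
    if len(dictionary) == 0:
        raise ValueError("dictionary is empty")
    if len(fp) != dictionary.n_points:
        raise ValueError(
            f"fingerprint length {len(fp)} != dictionary vectors {dictionary.n_points}"
        )
    query = normalize(fp.values)
    n = len(dictionary)
    scores = np.empty(n)
    for start, block in dictionary.iter_chunks(chunk_size):
        block = block.astype(np.float64)
        norms = np.linalg.norm(block, axis=1)
        scores[start : start + len(block)] = (block @ query) / norms

    k = min(int(top_k), n)
    if k < 1:
        raise ValueError("top_k must be >= 1")
    # kth-largest threshold, then exact (-score, key) ordering among the
    # candidates at or above it — robust to score ties.
    kth = np.partition(scores, n - k)[n - k]
    candidates = np.flatnonzero(scores >= kth)
    order = sorted(
        candidates, key=lambda i: (-scores[i], dictionary.hypotheses[i].sort_key())
    )[:k]
    entries = tuple((dictionary.hypotheses[i], float(scores[i])) for i in order)
    best_idx = order[0]
    r2 = fidelity_r2(fp.values, dictionary.vectors[best_idx].astype(np.float64))
    return MatchResult(entries=entries, best=dictionary.hypotheses[best_idx], fidelity_r2=r2)
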