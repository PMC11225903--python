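"""Phrasal similarity: Levenshtein n-gram matching and the overlap measure SIM.

Two natural-language phrases are compared by counting, for every n-gram
length ``n`` up to the length ``N`` of the shorter phrase, how many n-grams
the phrases have in common (``m_n``).  An n-gram pair is *common* when the
normalized Levenshtein similarity of the two space-joined n-grams exceeds a
threshold (default 0.99, i.e. effectively character-identical for short
phrases).  The overall score is

    SIM(ph1, ph2) = (N / |ph2|) * tanh[ (1/s) * sum_{n=1}^{N} m_n * n^2 ]

with ``|ph1| = N <= |ph2|`` (arguments are reordered internally) and
``s = N(N+1)/2``, the number of times n-gram pairs can be formed starting at
the same position in each phrase.  For a pair of single-word phrases the
score is simply the normalized character-level Levenshtein similarity.

SIM is symmetric, lies in [0, 1], and for any phrase compared with itself is
at least tanh(2) ~= 0.9640 (the minimum, attained by two-word phrases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import edlib

__all__ = [
    "Phrase",
    "SimConfig",
    "SimBreakdown",
    "levenshtein",
    "normalized_similarity",
    "common_ngram_count",
    "phrase_similarity",
]


# A Phrase is an ordered tuple of lowercase word tokens.
Phrase = Tuple[str, ...]


def as_phrase(words: Sequence[str] | str) -> Phrase:
    """Coerce a string or token sequence to a Phrase (lowercase tuple)."""
    if isinstance(words, str):
        words = words.split()
    toks = tuple(w.lower() for w in words if w)
    if not toks:
        raise ValueError("a phrase must contain at least one token")
    return toks


@dataclass(frozen=True)
class SimConfig:
    """Tunables for the similarity measure.

    ngram_common_threshold: two n-grams count as common when their
    normalized Levenshtein similarity strictly exceeds this value.
    """

    ngram_common_threshold: float = 0.99

    def __post_init__(self) -> None:
        if not (0.0 < self.ngram_common_threshold <= 1.0):
            raise ValueError("ngram_common_threshold must lie in (0, 1]")


DEFAULT_SIM_CONFIG = SimConfig()


@dataclass
class SimBreakdown:
    """The decomposed SIM computation for one phrase pair.

    Attributes
    ----------
    N : word count of the shorter phrase
    s : number of same-start-position n-gram pair formations, N(N+1)/2
    m : map from n-gram length n to m_n, the common n-gram count
    prefactor : N / |ph2|
    score : the final similarity in [0, 1]
    """

    N: int
    s: int
    m: Dict[int, int] = field(default_factory=dict)
    prefactor: float = 1.0
    score: float = 0.0


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between two character strings.

    Delegates to edlib's exact global (Needleman-Wunsch) alignment.
    """
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def normalized_similarity(a: str, b: str) -> float:
    """1 - levenshtein(a, b) / max(len(a), len(b)), in [0, 1].

    Raises ValueError when both strings are empty (the ratio is undefined).
    """
    longest = max(len(a), len(b))
    if longest == 0:
        raise ValueError("normalized similarity of two empty strings is undefined")
    return 1.0 - levenshtein(a, b) / longest


def _ngrams(ph: Phrase, n: int) -> list[str]:
    return [" ".join(ph[i : i + n]) for i in range(len(ph) - n + 1)]


def common_ngram_count(
    ph1: Phrase, ph2: Phrase, n: int, cfg: SimConfig = DEFAULT_SIM_CONFIG
) -> int:
    """Count n-grams of the shorter phrase with a common partner in the longer.

    Pairing is greedy left-to-right and one-to-one: each longer-phrase
    n-gram can serve as the partner of at most one shorter-phrase n-gram,
    so a repeated word cannot inflate the count.
    """
    if len(ph1) > len(ph2):
        ph1, ph2 = ph2, ph1
    if not (1 <= n <= len(ph1)):
        raise ValueError(f"n-gram length {n} out of range 1..{len(ph1)}")
    short_grams = _ngrams(ph1, n)
    long_grams = _ngrams(ph2, n)
    # At threshold >= 1 - 1/len, "common" degenerates to string equality;
    # skip the edit-distance call in that common case.
    thr = cfg.ngram_common_threshold
    consumed = [False] * len(long_grams)
    count = 0
    for g1 in short_grams:
        for j, g2 in enumerate(long_grams):
            if consumed[j]:
                continue
            longest = max(len(g1), len(g2))
            if longest * (1.0 - thr) < 1.0:
                common = g1 == g2
            else:
                common = normalized_similarity(g1, g2) > thr
            if common:
                consumed[j] = True
                count += 1
                break
    return count


def phrase_similarity(
    ph1: Phrase | Sequence[str] | str,
    ph2: Phrase | Sequence[str] | str,
    cfg: SimConfig = DEFAULT_SIM_CONFIG,
) -> SimBreakdown:
    """Compute SIM(ph1, ph2) with its full breakdown.

    Arguments are reordered internally so that ph1 is the shorter phrase;
    the measure is therefore symmetric.  A pair of one-word phrases is
    scored by character-level normalized Levenshtein similarity instead of
    the n-gram route.
    """
    p1 = as_phrase(ph1)
    p2 = as_phrase(ph2)
    if len(p1) > len(p2):
        p1, p2 = p2, p1
    N = len(p1)

    if N == 1 and len(p2) == 1:
        score = normalized_similarity(p1[0], p2[0])
        return SimBreakdown(N=1, s=1, m={1: 1 if p1[0] == p2[0] else 0},
                            prefactor=1.0, score=max(0.0, min(1.0, score)))

    s = N * (N + 1) // 2
    m: Dict[int, int] = {}
    total = 0.0
    for n in range(1, N + 1):
        m_n = common_ngram_count(p1, p2, n, cfg)
        m[n] = m_n
        total += m_n * n * n
    prefactor = N / len(p2)
    score = prefactor * math.tanh(total / s)
    return SimBreakdown(N=N, s=s, m=m, prefactor=prefactor,
                        score=max(0.0, min(1.0, score)))


def sim(ph1, ph2, cfg: SimConfig = DEFAULT_SIM_CONFIG) -> float:
    """Convenience wrapper returning just the SIM score."""
    return phrase_similarity(ph1, ph2, cfg).score
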