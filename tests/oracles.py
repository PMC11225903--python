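"""Independent test oracles, written from the procedure definitions only.

These deliberately avoid the library's code paths: edit distance is naive
memoized recursion, the phrase measure enumerates every n-gram pair with no
pruning, and the matching cascade is a literal step-by-step transcription.
"""

import math
from functools import lru_cache


def naive_levenshtein(a: str, b: str) -> int:
    """Plain recursive edit distance (memoized, but no DP table tricks)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(rec(i - 1, j) + 1,
                   rec(i, j - 1) + 1,
                   rec(i - 1, j - 1) + cost)

    return rec(len(a), len(b))


def naive_norm_sim(a: str, b: str) -> float:
    return 1.0 - naive_levenshtein(a, b) / max(len(a), len(b))


def sim_oracle(ph1, ph2, threshold: float = 0.99) -> float:
    """Brute-force phrasal overlap score: enumerate every n-gram pair."""
    p1, p2 = tuple(ph1), tuple(ph2)
    if len(p1) > len(p2):
        p1, p2 = p2, p1
    N = len(p1)
    if N == 1 and len(p2) == 1:
        return naive_norm_sim(p1[0], p2[0])
    s = sum(N - n + 1 for n in range(1, N + 1))
    total = 0.0
    for n in range(1, N + 1):
        grams1 = [" ".join(p1[i:i + n]) for i in range(N - n + 1)]
        grams2 = [" ".join(p2[i:i + n]) for i in range(len(p2) - n + 1)]
        taken = set()
        m_n = 0
        for g1 in grams1:
            for j, g2 in enumerate(grams2):
                if j in taken:
                    continue
                if naive_norm_sim(g1, g2) > threshold:
                    taken.add(j)
                    m_n += 1
                    break
        total += m_n * n * n
    return (N / len(p2)) * math.tanh(total / s)


def _id_key(aid: str):
    return (0, int(aid), "") if aid.isdigit() else (1, 0, aid)


def cascade_oracle(parse, taxonomy, cfg):
    """Literal transcription of the entity-decision cascade.

    Returns (action_id or None, route) where route is "prep", "object" or
    None.  Tie rules: the best sentence verb is the highest-scoring, then
    leftmost; within the cluster the lowest action_id, earliest candidate,
    first set member wins on equal scores.
    """
    from emat import phrase_similarity

    def score(a, b):
        return phrase_similarity(a, b, cfg.sim).score

    # best verb in the sentence
    best_verb = None  # (score, position, phrase)
    for ph, pos in parse.verbs:
        top = max((score(ph, m) for act in taxonomy for m in act.verb_set),
                  default=0.0)
        if top > cfg.verb_gate:
            if (best_verb is None or top > best_verb[0]
                    or (top == best_verb[0] and pos < best_verb[1])):
                best_verb = (top, pos, ph)
    if best_verb is None:
        return None, None
    verb = best_verb[2]

    cluster = sorted(
        (act.action_id for act in taxonomy
         if any(score(verb, m) > cfg.verb_gate for m in act.verb_set)),
        key=_id_key)

    SIMD = SIMP = 0.0
    actionD = actionP = None
    for cand, _ in parse.object_candidates:
        for aid in cluster:
            for member in taxonomy[aid].object_set:
                sc = score(cand, member)
                if sc > cfg.object_gate and sc > SIMD:
                    SIMD, actionD = sc, aid
    for cand in parse.prep_candidates:
        for aid in cluster:
            for member in taxonomy[aid].prep_set:
                sc = score(cand, member)
                if sc > cfg.prep_gate and sc > SIMP:
                    SIMP, actionP = sc, aid

    if actionD is None and actionP is None:
        return None, None
    if SIMP > cfg.prep_accept:
        return actionP, "prep"
    if SIMD > SIMP:
        return actionD, "object"
    return None, None
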