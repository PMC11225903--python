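"""Rule-based shallow parsing: m-word verbs, direct-object chunks, and
prepositional phrases.

The chunker is deliberately lexicon-driven and deterministic: verb
candidates come from the taxonomy's own verb equivalence sets (matching
downstream only ever compares against those sets, so spotting with the same
lexicon loses nothing), and phrase boundaries are decided by closed-class
word lists rather than a statistical part-of-speech model.  Every returned
span is a contiguous token slice of the sentence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Sequence, Set, Tuple

from .similarity import Phrase, SimConfig, DEFAULT_SIM_CONFIG, phrase_similarity
from .text import AUXILIARIES, CONJUNCTIONS, PREPOSITIONS

__all__ = [
    "SentenceParse",
    "extract_verbs",
    "extract_object_phrase",
    "extract_prep_phrases",
    "parse_sentence",
]

# Longest prepositional span considered; longer spans are almost always
# run-on chunks that cannot clear a similarity gate anyway.
MAX_PREP_SPAN = 10
MAX_OBJECT_SPAN = 12


@dataclass
class SentenceParse:
    tokens: List[str]
    verbs: List[Tuple[Phrase, int]] = field(default_factory=list)
    object_candidates: List[Tuple[Phrase, int]] = field(default_factory=list)
    prep_candidates: List[Phrase] = field(default_factory=list)


def _span_matches_lexicon(span: Phrase, lexicon: Sequence[Phrase],
                          gate: float, cfg: SimConfig) -> bool:
    L = len(span)
    for member in lexicon:
        # SIM carries a length-ratio prefactor, so members whose length
        # ratio already falls below the gate can be skipped outright.
        ratio = min(L, len(member)) / max(L, len(member))
        if ratio <= gate and not (L == 1 and len(member) == 1):
            continue
        if phrase_similarity(span, member, cfg).score > gate:
            return True
    return False


def extract_verbs(sentence: Sequence[str], verb_lexicon,
                  gate: float = 0.95,
                  cfg: SimConfig = DEFAULT_SIM_CONFIG
                  ) -> List[Tuple[Phrase, int]]:
    """Find maximal non-overlapping verb spans matching the lexicon.

    A span is returned when its similarity to some lexicon member exceeds
    the gate.  Bare auxiliaries (forms of be/have/do) are never returned on
    their own; a passive participle is returned without its auxiliary
    ("were arrested" yields just "arrested").
    """
    lexicon = [tuple(m) for m in verb_lexicon]
    if not lexicon:
        raise ValueError("verb lexicon must be non-empty")
    max_m = max(len(m) for m in lexicon)
    toks = [t.lower() for t in sentence]
    out: List[Tuple[Phrase, int]] = []
    i = 0
    n = len(toks)
    while i < n:
        matched = False
        for L in range(min(max_m, n - i), 0, -1):
            span = tuple(toks[i:i + L])
            if all(w in AUXILIARIES for w in span):
                continue
            if _span_matches_lexicon(span, lexicon, gate, cfg):
                out.append((span, i))
                i += L
                matched = True
                break
        if not matched:
            i += 1
    return out


# Complementizers/relativizers close a noun chunk in either direction.
_RELATIVIZERS = frozenset({"that", "which", "who", "whom", "whose"})


def _is_boundary(tok: str, verb_positions: FrozenSet[int], idx: int) -> bool:
    return (tok in PREPOSITIONS or tok in CONJUNCTIONS
            or tok in _RELATIVIZERS or idx in verb_positions)


def extract_object_phrase(sentence: Sequence[str], verb_index: int,
                          verb_len: int = 1,
                          verb_positions: Optional[Set[int]] = None
                          ) -> Optional[Phrase]:
    """The noun chunk governed by the verb at verb_index.

    Active voice: the contiguous chunk immediately after the verb, stopping
    at a preposition, conjunction, or another verb token.  Passive voice
    (auxiliary directly before the verb): the chunk immediately *preceding*
    the auxiliary instead, scanned backwards under the same stop rules.
    Returns None when no chunk exists.
    """
    toks = [t.lower() for t in sentence]
    vp = frozenset(verb_positions or ())
    passive = verb_index > 0 and toks[verb_index - 1] in AUXILIARIES

    if passive:
        end = verb_index - 1  # exclusive: the auxiliary
        start = end
        while (start > 0 and end - start < MAX_OBJECT_SPAN
               and not _is_boundary(toks[start - 1], vp, start - 1)
               and toks[start - 1] not in AUXILIARIES):
            start -= 1
        if start == end:
            return None
        return tuple(toks[start:end])

    start = verb_index + verb_len
    end = start
    n = len(toks)
    while (end < n and end - start < MAX_OBJECT_SPAN
           and not _is_boundary(toks[end], vp, end)
           and toks[end] not in AUXILIARIES):
        end += 1
    if end == start:
        return None
    return tuple(toks[start:end])


def extract_prep_phrases(sentence: Sequence[str]) -> List[Phrase]:
    """All candidate prepositional spans in the sentence.

    Each span starts at a closed-class preposition.  A later preposition
    marks an intermediate endpoint (the short reading, "to prison"), and
    the first conjunction or the sentence end marks the maximal endpoint
    (the long reading, "to predict poaching plots in advance").  All
    readings are emitted; spans may overlap and order is preserved.
    """
    toks = [t.lower() for t in sentence]
    n = len(toks)
    out: List[Phrase] = []
    for i, tok in enumerate(toks):
        if tok not in PREPOSITIONS:
            continue
        j = i + 1
        endpoints: List[int] = []
        while j < n and j - i <= MAX_PREP_SPAN:
            if toks[j] in CONJUNCTIONS:
                break
            if toks[j] in PREPOSITIONS:
                endpoints.append(j)
            j += 1
        endpoints.append(j)
        for end in endpoints:
            if end - i >= 2:  # a bare preposition is not a phrase
                span = tuple(toks[i:end])
                if span not in out:
                    out.append(span)
    return out


def parse_sentence(tokens: Sequence[str], verb_lexicon,
                   gate: float = 0.95,
                   cfg: SimConfig = DEFAULT_SIM_CONFIG) -> SentenceParse:
    """Full shallow parse of one tokenized sentence."""
    toks = [t.lower() for t in tokens]
    verbs = extract_verbs(toks, verb_lexicon, gate, cfg) if verb_lexicon else []
    verb_positions = {p for ph, start in verbs for p in range(start, start + len(ph))}
    objects: List[Tuple[Phrase, int]] = []
    for ph, start in verbs:
        obj = extract_object_phrase(toks, start, len(ph), verb_positions)
        if obj:
            objects.append((obj, start))
    preps = extract_prep_phrases(toks)
    return SentenceParse(tokens=toks, verbs=verbs,
                         object_candidates=objects, prep_candidates=preps)
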