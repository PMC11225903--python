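"""Software-assisted taxonomy growth.

The taxonomy is dynamic: language drifts and new human/ecosystem
interactions appear.  Two discovery routes feed a human curator:

* concordance search — short (1–4 word) query strings are located in a
  story corpus with surrounding context, suggesting phrasing in current use;
* near-miss detection — sentences whose best prepositional score fell in
  the learning band [0.7, 0.8), or whose object score beat their
  prepositional score, are paired with the taxonomy action that produced
  the score.

The module only *suggests* edits (ready-to-apply add-member arguments or a
new-action skeleton); it never mutates the taxonomy itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .extraction import ExtractionConfig, DEFAULT_EXTRACTION_CONFIG, MatchTrace
from .shallow_parse import parse_sentence
from .similarity import Phrase
from .story_io import StoryFile, segment_sentences, strip_html
from .taxonomy import Taxonomy
from .text import tokenize

__all__ = [
    "LearningCandidate",
    "Concordance",
    "find_phrase_contexts",
    "detect_candidates",
    "render_candidate_report",
]


@dataclass(frozen=True)
class ConcordanceHit:
    story_id: int
    sentence: str
    span: Tuple[int, int]  # token start/end of the query match
    context: Tuple[str, ...] = ()
    suggested_verbs: Tuple[Phrase, ...] = ()
    suggested_objects: Tuple[Phrase, ...] = ()
    suggested_preps: Tuple[Phrase, ...] = ()


@dataclass(frozen=True)
class Concordance:
    query: str
    hits: Tuple[ConcordanceHit, ...] = ()


@dataclass(frozen=True)
class LearningCandidate:
    sentence: str
    action_id: str
    SIMP: float
    SIMD: float
    trigger: str  # "simp_band" | "simd_gt_simp"
    verb: Optional[Phrase] = None
    object_phrase: Optional[Phrase] = None
    prep_phrase: Optional[Phrase] = None


def find_phrase_contexts(queries: Sequence[str], story_file: StoryFile,
                         window: int = 1,
                         taxonomy: Optional[Taxonomy] = None
                         ) -> List[Concordance]:
    """Keyword-in-context search for 1–4-word query strings.

    Each hit carries +/- window context sentences and, when a taxonomy is
    supplied, shallow-parse suggestions (verbs/objects/preps) from the hit
    sentence that a curator can lift into equivalence sets.
    """
    for q in queries:
        n = len(q.split())
        if not (1 <= n <= 4):
            raise ValueError(f"query must have 1-4 words, got {n}: {q!r}")
    verb_lexicon = None
    if taxonomy is not None:
        from .extraction import build_verb_lexicon
        verb_lexicon = build_verb_lexicon(taxonomy)

    out: List[Concordance] = []
    for query in queries:
        q_toks = tuple(tokenize(query))
        hits: List[ConcordanceHit] = []
        for story in story_file:
            sents = segment_sentences(strip_html(story.raw_text))
            tok_sents = [tokenize(s) for s in sents]
            for si, toks in enumerate(tok_sents):
                for i in range(len(toks) - len(q_toks) + 1):
                    if tuple(toks[i:i + len(q_toks)]) == q_toks:
                        ctx = tuple(
                            sents[j] for j in range(max(0, si - window),
                                                    min(len(sents), si + window + 1))
                            if j != si)
                        sv: Tuple[Phrase, ...] = ()
                        so: Tuple[Phrase, ...] = ()
                        sp: Tuple[Phrase, ...] = ()
                        if verb_lexicon:
                            parse = parse_sentence(toks, verb_lexicon)
                            sv = tuple(ph for ph, _ in parse.verbs)
                            so = tuple(ph for ph, _ in parse.object_candidates)
                            sp = tuple(parse.prep_candidates)
                        hits.append(ConcordanceHit(
                            story_id=story.story_id, sentence=sents[si],
                            span=(i, i + len(q_toks)), context=ctx,
                            suggested_verbs=sv, suggested_objects=so,
                            suggested_preps=sp))
                        break  # one hit per sentence is enough
        out.append(Concordance(query=query, hits=tuple(hits)))
    return out


def detect_candidates(traces: Sequence[MatchTrace],
                      cfg: ExtractionConfig = DEFAULT_EXTRACTION_CONFIG
                      ) -> List[LearningCandidate]:
    """Near-miss sentences worth a curator's attention.

    A trace contributes a candidate when its best prepositional score lies
    in [learn_low, prep_accept) — the learning band — or when its best
    object score exceeds its best prepositional score.  Because scores are
    always measured against existing actions, every candidate names the
    action that produced the score.  Sentences extracted through the
    object route also satisfy the second rule and are deliberately kept:
    they often reveal prep-set members that would have matched directly.
    """
    out: List[LearningCandidate] = []
    seen = set()

    def _add(cand: LearningCandidate):
        key = (cand.sentence, cand.action_id)
        if key not in seen:
            seen.add(key)
            out.append(cand)

    for tr in traces:
        if tr.verb is None:
            continue
        simd = tr.best_sub_D[1] if tr.best_sub_D else 0.0
        simp = tr.best_sub_P[1] if tr.best_sub_P else 0.0
        obj_ph = tr.best_sub_D[2] if tr.best_sub_D else None
        prep_ph = tr.best_sub_P[2] if tr.best_sub_P else None
        if tr.best_sub_P and cfg.learn_low <= simp < cfg.prep_accept:
            _add(LearningCandidate(
                sentence=tr.sentence_text, action_id=tr.best_sub_P[0],
                SIMP=simp, SIMD=simd, trigger="simp_band",
                verb=tr.verb, object_phrase=obj_ph, prep_phrase=prep_ph))
        if tr.best_sub_D and simd > simp:
            _add(LearningCandidate(
                sentence=tr.sentence_text, action_id=tr.best_sub_D[0],
                SIMP=simp, SIMD=simd, trigger="simd_gt_simp",
                verb=tr.verb, object_phrase=obj_ph, prep_phrase=prep_ph))
    return out


def render_candidate_report(candidates: Sequence[LearningCandidate],
                            taxonomy: Taxonomy) -> str:
    """Human-readable report with one machine-applicable block per candidate.

    Each block shows the sentence, the associated action, the scores, and
    both curator options: arguments for adding the sentence's phrases to
    the existing action's equivalence sets, and a skeleton for registering
    an entirely new action seeded with those phrases.
    """
    lines: List[str] = []
    if not candidates:
        return ""
    for i, c in enumerate(candidates, start=1):
        label = taxonomy[c.action_id].label if c.action_id in taxonomy else "?"
        lines.append(f"candidate {i}")
        lines.append(f"  sentence: {c.sentence}")
        lines.append(f"  associated action: {c.action_id} ({label})")
        lines.append(f"  SIMD={c.SIMD:.4f} SIMP={c.SIMP:.4f} trigger={c.trigger}")
        lines.append("  option A — extend the existing action:")
        if c.verb:
            lines.append(f"    add-member action={c.action_id} role=verb "
                         f"phrase=\"{' '.join(c.verb)}\"")
        if c.object_phrase:
            lines.append(f"    add-member action={c.action_id} role=direct_object "
                         f"phrase=\"{' '.join(c.object_phrase)}\"")
        if c.prep_phrase:
            lines.append(f"    add-member action={c.action_id} role=prepositional "
                         f"phrase=\"{' '.join(c.prep_phrase)}\"")
        lines.append("  option B — register a new action:")
        lines.append("    new-action label=\"<describe the action>\" "
                     "category=<militaristic|diplomatic|economic|"
                     "ecosystem_directed|ecological>")
        lines.append(f"      verb=\"{' '.join(c.verb) if c.verb else ''}\"")
        lines.append(f"      object=\"{' '.join(c.object_phrase) if c.object_phrase else ''}\"")
        lines.append(f"      prep=\"{' '.join(c.prep_phrase) if c.prep_phrase else ''}\"")
        lines.append("")
    return "\n".join(lines)
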