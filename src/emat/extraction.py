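"""Entity extraction: the verb/object/preposition matching cascade, story
tagging (date, groups, regions), duplicate removal, and the pipeline driver.

For each content sentence the cascade works as follows.  The sentence's
best-matching verb selects an *action cluster*: every taxonomy action with a
verb-set member scoring above the verb gate (default 0.95).  The sentence's
object chunks are then scored against the object sets of the cluster (best
declared match -> actionD/SIMD) and its prepositional spans against the
cluster's prep sets (best declared match -> actionP/SIMP).  An entity is
emitted for actionP when SIMP clears the acceptance threshold (default 0.8),
else for actionD when SIMD > SIMP, else nothing.  The full similarity trace
— including the best below-gate scores — is kept for the learning module.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .similarity import Phrase, SimConfig, DEFAULT_SIM_CONFIG, phrase_similarity
from .taxonomy import EMATAction, Lexicon, Taxonomy
from .text import tokenize
from . import story_io
from .story_io import (ContentFilterConfig, DEFAULT_CONTENT_FILTER, Story,
                       StoryFile, content_fragment, detect_source,
                       segment_sentences, strip_html)
from .shallow_parse import SentenceParse, parse_sentence

logger = logging.getLogger("emat")

__all__ = [
    "ExtractionConfig",
    "MatchTrace",
    "EMATEntity",
    "StoryDatabase",
    "build_action_cluster",
    "extract_entity_from_sentence",
    "tag_story",
    "assign_actor_target",
    "deduplicate",
    "parse_stories",
    "find_date",
]


@dataclass(frozen=True)
class ExtractionConfig:
    """Thresholds of the extraction cascade.

    verb_gate / object_gate: declare-a-match thresholds for verbs and
    direct objects.  prep_gate: declare-a-match threshold for prepositional
    phrases; prep_accept: the score above which a prepositional match alone
    emits an entity.  learn_low: lower edge of the learning band
    [learn_low, prep_accept).
    """

    verb_gate: float = 0.95
    object_gate: float = 0.95
    prep_gate: float = 0.8
    prep_accept: float = 0.8
    learn_low: float = 0.7
    sim: SimConfig = DEFAULT_SIM_CONFIG

    def __post_init__(self) -> None:
        if not (0.0 < self.learn_low <= self.prep_accept <= 1.0):
            raise ValueError("need 0 < learn_low <= prep_accept <= 1")
        for name in ("verb_gate", "object_gate", "prep_gate"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")


DEFAULT_EXTRACTION_CONFIG = ExtractionConfig()


@dataclass
class MatchTrace:
    """Everything the cascade measured for one sentence."""

    story_id: int
    sentence_index: int
    tokens: List[str]
    sentence_text: str = ""
    verb: Optional[Phrase] = None
    verb_start: int = -1
    verb_score: float = 0.0
    cluster: Tuple[str, ...] = ()
    actionD: Optional[str] = None
    SIMD: float = 0.0
    actionP: Optional[str] = None
    SIMP: float = 0.0
    # Best (action_id, score, phrase) seen regardless of the gates; the
    # learning band lives below the gates, so these are what it reads.
    best_sub_D: Optional[Tuple[str, float, Phrase]] = None
    best_sub_P: Optional[Tuple[str, float, Phrase]] = None
    matched_object: Optional[Phrase] = None
    matched_prep: Optional[Phrase] = None
    decision: Optional[str] = None
    decision_route: Optional[str] = None  # "prep" | "object" | None


@dataclass
class EMATEntity:
    """One extracted occurrence of a taxonomy action."""

    action_id: str
    story_id: int
    sentence_index: int
    date: Optional[_dt.date] = None
    source: str = "unknown"
    actor: Optional[str] = None
    target: Optional[str] = None
    region: Optional[str] = None
    verb_phrase: Optional[Phrase] = None
    object_phrase: Optional[Phrase] = None
    prep_phrase: Optional[Phrase] = None
    verb_score: float = 0.0
    simd: float = 0.0
    simp: float = 0.0
    actor_rule: str = "none"
    target_rule: str = "none"
    sentence_text: str = ""

    def duplicate_key(self) -> tuple:
        return (self.action_id, self.story_id, self.date, self.actor,
                self.target)


@dataclass
class StoryDatabase:
    """Per-story entity lists plus the flat deduplicated history."""

    story_meta: List[dict] = field(default_factory=list)
    per_story: Dict[int, List[EMATEntity]] = field(default_factory=dict)
    entities: List[EMATEntity] = field(default_factory=list)
    traces: List[MatchTrace] = field(default_factory=list)
    parse_failures: List[Tuple[int, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# action-cluster construction (verb stage)
# ---------------------------------------------------------------------------

def _id_sort_key(action_id: str):
    return (0, int(action_id), "") if action_id.isdigit() else (1, 0, action_id)


def build_action_cluster(verb: Phrase, taxonomy: Taxonomy,
                         cfg: ExtractionConfig = DEFAULT_EXTRACTION_CONFIG
                         ) -> Tuple[Optional[str], frozenset]:
    """Score a verb against every verb-set member of every action.

    Returns (best_action_id, cluster), where the cluster holds every action
    with at least one member above the verb gate and best is the action
    owning the single highest-scoring member (ties -> lowest action_id).
    """
    best_id: Optional[str] = None
    best_score = 0.0
    cluster = set()
    for act in taxonomy:
        act_best = 0.0
        for member in act.verb_set:
            score = phrase_similarity(verb, member, cfg.sim).score
            if score > act_best:
                act_best = score
        if act_best > cfg.verb_gate:
            cluster.add(act.action_id)
            better = act_best > best_score or (
                act_best == best_score and best_id is not None
                and _id_sort_key(act.action_id) < _id_sort_key(best_id))
            if best_id is None or better:
                best_id, best_score = act.action_id, act_best
    if not cluster:
        return None, frozenset()
    return best_id, frozenset(cluster)


def _best_verb(parse: SentenceParse, taxonomy: Taxonomy,
               cfg: ExtractionConfig):
    """Choose the sentence verb with the strongest taxonomy match."""
    best = None  # (score, position, phrase, best_action, cluster)
    for ph, start in parse.verbs:
        top = 0.0
        for act in taxonomy:
            for member in act.verb_set:
                s = phrase_similarity(ph, member, cfg.sim).score
                if s > top:
                    top = s
        if top > cfg.verb_gate:
            if best is None or top > best[0] or (top == best[0] and start < best[1]):
                best = (top, start, ph)
    if best is None:
        return None
    score, start, ph = best
    best_action, cluster = build_action_cluster(ph, taxonomy, cfg)
    return score, start, ph, best_action, cluster


def _best_phrase_match(candidates: Iterable[Phrase], taxonomy: Taxonomy,
                       cluster: frozenset, role: str, cfg: ExtractionConfig):
    """Best (action, score, candidate phrase) within the cluster's sets.

    Ties are broken toward the lowest action_id, then earliest candidate.
    """
    best: Optional[Tuple[str, float, Phrase]] = None
    for cand in candidates:
        for aid in sorted(cluster, key=_id_sort_key):
            eset = taxonomy[aid].set_for_role(role)
            for member in eset:
                score = phrase_similarity(cand, member, cfg.sim).score
                if best is None or score > best[1]:
                    best = (aid, score, cand)
    return best


# ---------------------------------------------------------------------------
# the extraction cascade
# ---------------------------------------------------------------------------

def extract_entity_from_sentence(parse: SentenceParse, taxonomy: Taxonomy,
                                 cfg: ExtractionConfig = DEFAULT_EXTRACTION_CONFIG,
                                 story_id: int = -1, sentence_index: int = -1,
                                 sentence_text: str = ""
                                 ) -> Tuple[Optional[EMATEntity], MatchTrace]:
    """Run the matching cascade on one parsed sentence.

    Returns (entity draft, trace).  The draft, when present, still lacks
    date/source/actor/target tags; the trace is always returned.
    """
    trace = MatchTrace(story_id=story_id, sentence_index=sentence_index,
                       tokens=list(parse.tokens), sentence_text=sentence_text)

    chosen = _best_verb(parse, taxonomy, cfg)
    if chosen is None:
        return None, trace
    verb_score, verb_start, verb_ph, _best_act, cluster = chosen
    trace.verb, trace.verb_start, trace.verb_score = verb_ph, verb_start, verb_score
    trace.cluster = tuple(sorted(cluster, key=_id_sort_key))

    # SIMD and SIMP start at zero and are only raised by a declared match.
    object_cands = [ph for ph, _ in parse.object_candidates]
    best_obj = _best_phrase_match(object_cands, taxonomy, cluster,
                                  "direct_object", cfg)
    trace.best_sub_D = best_obj
    if best_obj and best_obj[1] > cfg.object_gate:
        trace.actionD, trace.SIMD, trace.matched_object = best_obj

    best_prep = _best_phrase_match(parse.prep_candidates, taxonomy, cluster,
                                   "prepositional", cfg)
    trace.best_sub_P = best_prep
    if best_prep and best_prep[1] > cfg.prep_gate:
        trace.actionP, trace.SIMP, trace.matched_prep = best_prep

    if trace.actionD is None and trace.actionP is None:
        return None, trace
    if trace.SIMP > cfg.prep_accept:
        trace.decision, trace.decision_route = trace.actionP, "prep"
    elif trace.SIMD > trace.SIMP:
        trace.decision, trace.decision_route = trace.actionD, "object"
    else:
        return None, trace

    entity = EMATEntity(
        action_id=trace.decision, story_id=story_id,
        sentence_index=sentence_index,
        verb_phrase=verb_ph,
        object_phrase=trace.matched_object,
        prep_phrase=trace.matched_prep,
        verb_score=verb_score, simd=trace.SIMD, simp=trace.SIMP,
        sentence_text=sentence_text)
    return entity, trace


# ---------------------------------------------------------------------------
# story tagging: date, groups, regions
# ---------------------------------------------------------------------------

_MONTHS = {m.lower(): i for i, m in enumerate(
    ["January", "February", "March", "April", "May", "June", "July",
     "August", "September", "October", "November", "December"], start=1)}
_MONTHS.update({m[:3].lower(): i for m, i in
                [(k.capitalize(), v) for k, v in _MONTHS.items()]})

_MONTH_ALT = "|".join(sorted(_MONTHS, key=len, reverse=True))

# Checked in order; the first parseable hit wins.
_DATE_PATTERNS = [
    re.compile(r'(?:datetime|content)\s*=\s*["\'](\d{4})-(\d{2})-(\d{2})',
               re.IGNORECASE),
    re.compile(rf"\b({_MONTH_ALT})\.?\s+(\d{{1,2}})(?:st|nd|rd|th)?,?\s+(\d{{4}})\b",
               re.IGNORECASE),
    re.compile(rf"\b(\d{{1,2}})(?:st|nd|rd|th)?\s+({_MONTH_ALT})\.?,?\s+(\d{{4}})\b",
               re.IGNORECASE),
    re.compile(r"\b(\d{4})-(\d{2})-(\d{2})\b"),
]


def find_date(text: str) -> Optional[_dt.date]:
    """First date matched by the regex battery, or None."""
    for idx, pat in enumerate(_DATE_PATTERNS):
        for m in pat.finditer(text):
            g = m.groups()
            try:
                if idx in (0, 3):
                    y, mo, d = int(g[0]), int(g[1]), int(g[2])
                elif idx == 1:
                    mo, d, y = _MONTHS[g[0].lower()], int(g[1]), int(g[2])
                else:
                    d, mo, y = int(g[0]), _MONTHS[g[1].lower()], int(g[2])
                return _dt.date(y, mo, d)
            except (ValueError, KeyError):
                continue
    return None


@dataclass(frozen=True)
class LexiconHit:
    name: str
    sentence_index: int
    token_start: int
    token_len: int


def _find_lexicon_hits(sentences: Sequence[Sequence[str]],
                       lexicon: Lexicon) -> List[LexiconHit]:
    """Case-insensitive longest-match occurrences of lexicon names."""
    patterns = sorted(
        ((tuple(tokenize(name)), name) for name in lexicon),
        key=lambda p: -len(p[0]))
    hits: List[LexiconHit] = []
    for si, sent in enumerate(sentences):
        toks = [t.lower() for t in sent]
        i = 0
        while i < len(toks):
            matched = False
            for pat, name in patterns:
                L = len(pat)
                if L and tuple(toks[i:i + L]) == pat:
                    hits.append(LexiconHit(name, si, i, L))
                    i += L
                    matched = True
                    break
            if not matched:
                i += 1
    return hits


def tag_story(story: Story, groups: Lexicon, regions: Lexicon
              ) -> Tuple[Optional[_dt.date], List[LexiconHit], List[LexiconHit]]:
    """Date plus group/region occurrences for one (tag-filtered) story.

    The three searches are pure functions of the story, so running them
    sequentially or concurrently gives identical results.
    """
    date = find_date(story.raw_text)
    group_hits = _find_lexicon_hits(story.sentences, groups)
    region_hits = _find_lexicon_hits(story.sentences, regions)
    return date, group_hits, region_hits


def assign_actor_target(entity: EMATEntity, parse: SentenceParse,
                        group_hits: Sequence[LexiconHit],
                        region_hits: Sequence[LexiconHit],
                        action: EMATAction,
                        verb_start: int) -> EMATEntity:
    """Fill actor/target/region tags on an entity draft.

    Actor: nearest group mention at or before the verb in the sentence,
    else the story's first group mention, else the action's first
    archetypal actor.  Target: nearest group or region mention after the
    verb, else the story's first region mention.
    """
    si = entity.sentence_index
    actor, actor_rule = None, "none"
    same_sent = [h for h in group_hits
                 if h.sentence_index == si and h.token_start <= verb_start]
    if same_sent:
        actor = max(same_sent, key=lambda h: h.token_start).name
        actor_rule = "sentence"
    elif group_hits:
        actor, actor_rule = group_hits[0].name, "story"
    elif action.archetypal_actors:
        actor, actor_rule = action.archetypal_actors[0], "archetype"

    target, target_rule = None, "none"
    after = [h for h in list(group_hits) + list(region_hits)
             if h.sentence_index == si and h.token_start > verb_start]
    if after:
        target = min(after, key=lambda h: h.token_start).name
        target_rule = "sentence"
    elif region_hits:
        target, target_rule = region_hits[0].name, "story_region"

    region = None
    sent_regions = [h for h in region_hits if h.sentence_index == si]
    if sent_regions:
        region = sent_regions[0].name
    elif region_hits:
        region = region_hits[0].name

    return replace(entity, actor=actor, target=target, region=region,
                   actor_rule=actor_rule, target_rule=target_rule)


# ---------------------------------------------------------------------------
# duplicate removal
# ---------------------------------------------------------------------------

def deduplicate(entities: Sequence[EMATEntity]) -> List[EMATEntity]:
    """Keep the first entity of each duplicate key, preserving order.

    The key is (action_id, story_id, date, actor, target): the smallest
    key under which the same event reported twice in one story collapses.
    Idempotent by construction.
    """
    seen = set()
    out: List[EMATEntity] = []
    for e in entities:
        key = e.duplicate_key()
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# the pipeline driver
# ---------------------------------------------------------------------------

def build_verb_lexicon(taxonomy: Taxonomy) -> List[Phrase]:
    """Union of all verb equivalence-set members across the taxonomy."""
    seen = set()
    out: List[Phrase] = []
    for act in taxonomy:
        for member in act.verb_set:
            if member not in seen:
                seen.add(member)
                out.append(member)
    return out


def process_story(story: Story, taxonomy: Taxonomy, groups: Lexicon,
                  regions: Lexicon,
                  cfg: ExtractionConfig = DEFAULT_EXTRACTION_CONFIG,
                  content_cfg: ContentFilterConfig = DEFAULT_CONTENT_FILTER,
                  verb_lexicon: Optional[List[Phrase]] = None,
                  ) -> Tuple[List[EMATEntity], List[MatchTrace], List[str]]:
    """Run the whole per-story pipeline; returns (entities, traces, failures)."""
    if verb_lexicon is None:
        verb_lexicon = build_verb_lexicon(taxonomy)
    failures: List[str] = []

    text = strip_html(story.raw_text)
    work = Story(story_id=story.story_id, raw_text=text)
    work.source = detect_source(work)
    sentence_texts = segment_sentences(text)
    work.sentences = [tokenize(s) for s in sentence_texts]
    kept_pairs = [(s, toks) for s, toks in zip(sentence_texts, work.sentences)
                  if toks and story_io.is_content_sentence(toks, content_cfg)]
    if not kept_pairs:
        failures.append("no content sentences")
        return [], [], failures
    work.sentences = [toks for _, toks in kept_pairs]

    story_date, group_hits, region_hits = tag_story(work, groups, regions)
    if story_date is None:
        failures.append("no date detected")

    entities: List[EMATEntity] = []
    traces: List[MatchTrace] = []
    for si, (sent_text, toks) in enumerate(kept_pairs):
        parse = parse_sentence(toks, verb_lexicon, cfg.verb_gate, cfg.sim)
        draft, trace = extract_entity_from_sentence(
            parse, taxonomy, cfg, story_id=story.story_id,
            sentence_index=si, sentence_text=sent_text)
        traces.append(trace)
        if draft is None:
            continue
        draft.date = find_date(sent_text) or story_date
        draft.source = work.source
        entity = assign_actor_target(draft, parse, group_hits, region_hits,
                                     taxonomy[draft.action_id],
                                     trace.verb_start)
        entities.append(entity)
    return deduplicate(entities), traces, failures


def _entity_line(e: EMATEntity) -> str:
    def ph(p):
        return " ".join(p) if p else ""
    return "\t".join([
        e.action_id, str(e.story_id),
        e.date.isoformat() if e.date else "",
        e.source, e.actor or "", e.target or "", e.region or "",
        ph(e.verb_phrase), ph(e.object_phrase), ph(e.prep_phrase),
        f"{e.verb_score:.4f}", f"{e.simd:.4f}", f"{e.simp:.4f}",
    ])


ENTITY_HEADER = ("#action_id\tstory_id\tdate\tsource\tactor\ttarget\tregion"
                 "\tverb\tobject\tprep\tverb_score\tsimd\tsimp")


def parse_stories(story_file: StoryFile, taxonomy: Taxonomy,
                  groups: Lexicon, regions: Lexicon,
                  cfg: ExtractionConfig = DEFAULT_EXTRACTION_CONFIG,
                  content_cfg: ContentFilterConfig = DEFAULT_CONTENT_FILTER,
                  out_entities=None, out_sdb=None, out_parsefailed=None,
                  out_assessment=None, assessment_k: int = 10
                  ) -> StoryDatabase:
    """Extract entities from every story in a story file.

    Stories are processed independently (the search is embarrassingly
    parallel over stories); duplicates are removed per story and then once
    more across the flat history.  Optional output paths receive the entity
    history, the story database, the parse-failure log, and the extraction
    assessment sample.
    """
    db = StoryDatabase()
    verb_lexicon = build_verb_lexicon(taxonomy)
    for story in story_file:
        try:
            entities, traces, failures = process_story(
                story, taxonomy, groups, regions, cfg, content_cfg,
                verb_lexicon)
        except Exception as exc:  # a bad story must not abort the run
            logger.warning("story %d failed: %s", story.story_id, exc)
            db.parse_failures.append((story.story_id, f"exception: {exc}"))
            continue
        db.per_story[story.story_id] = entities
        db.traces.extend(traces)
        for reason in failures:
            db.parse_failures.append((story.story_id, reason))
        db.story_meta.append({
            "story_id": story.story_id,
            "n_entities": len(entities),
        })
        logger.info("story %d: %d entities", story.story_id, len(entities))
        db.entities.extend(entities)
    db.entities = deduplicate(db.entities)

    if out_entities is not None:
        with open(out_entities, "w", encoding="utf-8") as fh:
            fh.write(ENTITY_HEADER + "\n")
            for e in db.entities:
                fh.write(_entity_line(e) + "\n")
    if out_sdb is not None:
        with open(out_sdb, "w", encoding="utf-8") as fh:
            for sid in sorted(db.per_story):
                fh.write(f"story {sid}\n")
                for e in db.per_story[sid]:
                    fh.write(_entity_line(e) + "\n")
                fh.write("\n")
    if out_parsefailed is not None:
        with open(out_parsefailed, "w", encoding="utf-8") as fh:
            for sid, reason in db.parse_failures:
                fh.write(f"{sid}\t{reason}\n")
    if out_assessment is not None and story_file.origin_path:
        from .assessment import write_assessment_sample
        write_assessment_sample(story_file.origin_path, db,
                                k=assessment_k, out_path=out_assessment)
    return db
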