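"""Synthetic story corpora with planted, manifest-tracked action entities.

Real story files cannot be redistributed (they are copyrighted news text),
so every downstream module is exercised on generated corpora instead: junk
boilerplate sentences drawn from the web-fluff vocabulary, optional HTML
wrappers, and content sentences of the verb + object + prepositional-phrase
shape the extraction cascade assumes, built verbatim from a known toy
taxonomy and logged in a ground-truth manifest.

Vocabulary construction is adversarial-free by design: every generated word
is at Levenshtein distance >= 2 from every other and from all closed-class
words, so a planted sentence can only ever match the action it was built
from, and a single-character perturbation can never turn one vocabulary
word into another.  Word perturbation draws are keyed by
(seed, story, sentence, word), not by the rate, so the perturbed-word set
at a low rate is a subset of the set at any higher rate — recovery is
structurally monotone in the rate.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .similarity import Phrase, levenshtein
from .taxonomy import (CATEGORIES, EMATAction, EquivalenceSet, Lexicon,
                       Taxonomy)
from .text import AUXILIARIES, CONJUNCTIONS, PREPOSITIONS
from .story_io import COMMON_WORDS, IRRELEVANT_WORDS, STORY_DELIMITER, StoryFile, read_story_file

__all__ = [
    "FixtureSpec",
    "PlantedEntity",
    "GroundTruthManifest",
    "generate_toy_taxonomy",
    "synthetic_reference_taxonomy",
    "plant_sentence",
    "generate_story_file",
]

_MONTH_NAMES = ("January", "February", "March", "April", "May", "June",
                "July", "August", "September", "October", "November",
                "December")

# Fixed neutral padding words; excluded from the generated vocabulary.
_PADDING_WORDS = frozenset({"team", "scene", "there", "event", "site",
                            "story", "bulletin", "news", "example", "com"})

_RESERVED = (frozenset(w.lower() for w in _MONTH_NAMES)
             | COMMON_WORDS | IRRELEVANT_WORDS | PREPOSITIONS
             | CONJUNCTIONS | AUXILIARIES | _PADDING_WORDS)

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class FixtureSpec:
    n_stories: int
    entities_per_story: int
    junk_sentence_rate: float = 0.3
    word_perturbation_rate: float = 0.0
    html_fluff: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("junk_sentence_rate", "word_perturbation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_stories < 0 or self.entities_per_story < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class PlantedEntity:
    story_id: int
    sentence_ordinal: int
    action_id: str
    verb: Phrase
    object_phrase: Optional[Phrase]
    prep_phrase: Optional[Phrase]
    date: str  # ISO
    actor: str
    target: str


@dataclass
class GroundTruthManifest:
    entries: List[PlantedEntity] = field(default_factory=list)
    groups: Tuple[str, ...] = ()
    regions: Tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.entries)

    def pairs(self) -> List[Tuple[int, str]]:
        """(story_id, action_id) pairs, the benchmark view of the truth."""
        return [(e.story_id, e.action_id) for e in self.entries]

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#story_id\tsentence\taction_id\tverb\tobject\tprep"
                     "\tdate\tactor\ttarget\n")
            for e in self.entries:
                fh.write("\t".join([
                    str(e.story_id), str(e.sentence_ordinal), e.action_id,
                    " ".join(e.verb),
                    " ".join(e.object_phrase) if e.object_phrase else "",
                    " ".join(e.prep_phrase) if e.prep_phrase else "",
                    e.date, e.actor, e.target]) + "\n")


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

def _fresh_word(rng: random.Random, used: set) -> str:
    """A pseudo-word at edit distance >= 2 from everything generated so far."""
    while True:
        n_syll = rng.randint(2, 3)
        word = "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
                       for _ in range(n_syll))
        if rng.random() < 0.5:
            word += rng.choice(_CONSONANTS)
        if word in _RESERVED or word in used:
            continue
        if any(abs(len(word) - len(u)) < 2 and levenshtein(word, u) < 2
               for u in used):
            continue
        used.add(word)
        return word


def _taxonomy_words(taxonomy: Taxonomy) -> set:
    words = set()
    for act in taxonomy:
        for eset in (act.verb_set, act.object_set, act.prep_set):
            for ph in eset:
                words.update(ph)
        for actor in act.archetypal_actors:
            words.update(actor.lower().split())
    return words


# ---------------------------------------------------------------------------
# taxonomy generators
# ---------------------------------------------------------------------------

def generate_toy_taxonomy(actions_per_category: int,
                          vocab_seed: int) -> Taxonomy:
    """A small taxonomy over a controlled, mutually dissimilar vocabulary.

    Every one of the five categories gets actions_per_category actions;
    each action carries 2-3 members per equivalence set built from words
    unique to that action, so ground-truth attribution is unambiguous.
    """
    if actions_per_category < 1:
        raise ValueError("actions_per_category must be >= 1")
    rng = random.Random(vocab_seed)
    used: set = set()
    preps = sorted(PREPOSITIONS)
    actions: Dict[str, EMATAction] = {}
    aid = 0
    for category in CATEGORIES:
        for _ in range(actions_per_category):
            aid += 1
            verbs = []
            for i in range(rng.randint(2, 3)):
                n_words = 1 if i == 0 else rng.randint(1, 2)
                verbs.append(tuple(_fresh_word(rng, used)
                                   for _ in range(n_words)))
            objects = [tuple(_fresh_word(rng, used)
                             for _ in range(rng.randint(2, 3)))
                       for _ in range(rng.randint(2, 3))]
            prep_list = [tuple([rng.choice(preps)]
                               + [_fresh_word(rng, used)
                                  for _ in range(rng.randint(2, 3))])
                         for _ in range(rng.randint(2, 3))]
            actor = " ".join(w.capitalize()
                             for w in (_fresh_word(rng, used),
                                       _fresh_word(rng, used)))
            label = " ".join(verbs[0] + objects[0]).capitalize()
            actions[str(aid)] = EMATAction(
                action_id=str(aid), label=label, category=category,
                archetypal_actors=(actor,),
                verb_set=EquivalenceSet("verb", tuple(verbs)),
                object_set=EquivalenceSet("direct_object", tuple(objects)),
                prep_set=EquivalenceSet("prepositional", tuple(prep_list)))
    return Taxonomy(actions)


_REFERENCE_CATEGORY_SIZES = {
    "militaristic": 119,
    "diplomatic": 191,
    "economic": 198,
    "ecosystem_directed": 92,
    "ecological": 37,
}


def synthetic_reference_taxonomy(
        category_sizes: Optional[Dict[str, int]] = None) -> Taxonomy:
    """A synthetic stand-in for the full published taxonomy.

    The real 637-action taxonomy is curated content that is not
    redistributed here; this synthetic replica only reproduces its *shape*
    — the per-category action counts (119 militaristic, 191 diplomatic,
    198 economic, 92 ecosystem-directed, 37 ecological by default) — with
    placeholder phrases, so that readers and counting logic can be
    exercised at full scale.
    """
    sizes = dict(_REFERENCE_CATEGORY_SIZES if category_sizes is None
                 else category_sizes)
    actions: Dict[str, EMATAction] = {}
    aid = 0
    for category, count in sizes.items():
        for _ in range(count):
            aid += 1
            i = str(aid)
            actions[i] = EMATAction(
                action_id=i, label=f"Synthetic action {i}",
                category=category,
                verb_set=EquivalenceSet("verb", ((f"verbword{i}",),)),
                object_set=EquivalenceSet(
                    "direct_object", ((f"objectword{i}", "thing"),)),
                prep_set=EquivalenceSet(
                    "prepositional", (("in", f"placeword{i}"),)))
    return Taxonomy(actions)


# ---------------------------------------------------------------------------
# sentence planting
# ---------------------------------------------------------------------------

def _perturb_word(word: str, rng: random.Random) -> str:
    """One random single-character substitution, insertion, or deletion."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    op = rng.choice(("sub", "ins", "del"))
    pos = rng.randrange(len(word))
    if op == "sub":
        repl = rng.choice(letters)
        while repl == word[pos]:
            repl = rng.choice(letters)
        return word[:pos] + repl + word[pos + 1:]
    if op == "ins":
        return word[:pos] + rng.choice(letters) + word[pos:]
    if len(word) > 1:
        return word[:pos] + word[pos + 1:]
    return word


def _maybe_perturb(words: Sequence[str], rate: float,
                   rng_for_word) -> List[str]:
    out = []
    for w in words:
        r = rng_for_word(w)
        if r.random() < rate and len(w) >= 3 and w.isalpha():
            out.append(_perturb_word(w, r))
        else:
            out.append(w)
    return out


def plant_sentence(action: EMATAction, perturbation: float,
                   rng: random.Random, *, actor: Optional[str] = None,
                   region: Optional[str] = None,
                   date: Optional[Tuple[int, int, int]] = None,
                   word_rng=None) -> Tuple[str, dict]:
    """Build one content sentence realizing the given action.

    The sentence is actor + verb member + object member + prepositional
    member + a date phrase, padded with common words so the content filter
    passes.  Only the verb/object/prep words are perturbed (probability
    ``perturbation`` per word, one character edit each); structural words
    and the date stay intact so degradation isolates the matching stage.

    word_rng, when given, maps a word to the random generator used for its
    perturbation draw — the hook the corpus generator uses to couple draws
    across perturbation rates.
    """
    if not len(action.verb_set):
        raise ValueError("action must have a non-empty verb set")
    verb = rng.choice(list(action.verb_set))
    obj = rng.choice(list(action.object_set)) if len(action.object_set) else None
    prep = rng.choice(list(action.prep_set)) if len(action.prep_set) else None
    if date is None:
        date = (rng.randint(2010, 2022), rng.randint(1, 12), rng.randint(1, 28))
    y, mo, d = date
    if actor is None:
        actor = (action.archetypal_actors[0] if action.archetypal_actors
                 else "The authorities")

    counter = [0]

    def default_word_rng(_word):
        counter[0] += 1
        return rng

    get_rng = word_rng or default_word_rng
    core: List[str] = list(verb)
    if obj:
        core += list(obj)
    if prep:
        core += list(prep)
    perturbed = _maybe_perturb(core, perturbation, get_rng)

    # Reassemble with the perturbed spellings in order.
    it = iter(perturbed)
    verb_out = [next(it) for _ in verb]
    obj_out = [next(it) for _ in obj] if obj else []
    prep_out = [next(it) for _ in prep] if prep else []

    tail = f"at the scene in {region}" if region else "at the scene"
    sentence = (f"{actor} {' '.join(verb_out)}"
                + (f" {' '.join(obj_out)}" if obj_out else "")
                + (f" {' '.join(prep_out)}" if prep_out else "")
                + f" on {_MONTH_NAMES[mo - 1]} {d}, {y}"
                + f" and the team was there {tail}.")
    truth = {
        "action_id": action.action_id, "verb": verb, "object": obj,
        "prep": prep, "date": f"{y:04d}-{mo:02d}-{d:02d}",
        "actor": actor, "target": region or "",
    }
    return sentence, truth


_JUNK_WORDS = sorted(IRRELEVANT_WORDS - {"http:"})


def _junk_sentence(rng: random.Random) -> str:
    words = [rng.choice(_JUNK_WORDS) for _ in range(rng.randint(5, 8))]
    return (" ".join(words)).capitalize() + "."


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def generate_story_file(spec: FixtureSpec, taxonomy: Taxonomy, out_path,
                        manifest_path=None
                        ) -> Tuple[StoryFile, GroundTruthManifest]:
    """Write a delimited story file with planted entities and its manifest.

    Fully deterministic in spec.seed: the corpus structure (actions,
    dates, actors, junk) depends only on the seed, and the perturbation
    draws only on (seed, story, sentence, word) — never on the rate — so
    runs at different rates share everything except which words are noised.
    """
    if len(taxonomy) == 0:
        raise ValueError("taxonomy must be non-empty")
    if spec.entities_per_story > len(taxonomy):
        raise ValueError("entities_per_story exceeds the number of actions")
    rng = random.Random(spec.seed)
    used = _taxonomy_words(taxonomy)
    groups = tuple(
        " ".join(w.capitalize() for w in (_fresh_word(rng, used),
                                          _fresh_word(rng, used)))
        for _ in range(4))
    regions = tuple(_fresh_word(rng, used).capitalize() for _ in range(4))
    action_ids = sorted(taxonomy.actions,
                        key=lambda a: (len(a), a))

    manifest = GroundTruthManifest(groups=groups, regions=regions)
    blocks: List[str] = []
    for si in range(spec.n_stories):
        sentences: List[str] = []
        src = _fresh_word(rng, used)
        sentences.append(f"https://{src}.example.com/story{si}.")
        chosen = rng.sample(action_ids, spec.entities_per_story)
        ordinal = 0
        for aid in chosen:
            n_junk = 0
            while rng.random() < spec.junk_sentence_rate and n_junk < 3:
                sentences.append(_junk_sentence(rng))
                n_junk += 1

            word_counter = [0]

            def word_rng(_word, _si=si, _ord=ordinal, _ctr=word_counter):
                _ctr[0] += 1
                return random.Random(
                    f"{spec.seed}|{_si}|{_ord}|{_ctr[0]}")

            sent, truth = plant_sentence(
                taxonomy[aid], spec.word_perturbation_rate, rng,
                actor=rng.choice(groups), region=rng.choice(regions),
                word_rng=word_rng)
            sentences.append(sent)
            manifest.entries.append(PlantedEntity(
                story_id=si, sentence_ordinal=ordinal, action_id=aid,
                verb=truth["verb"], object_phrase=truth["object"],
                prep_phrase=truth["prep"], date=truth["date"],
                actor=truth["actor"], target=truth["target"]))
            ordinal += 1
        n_junk = 0
        while rng.random() < spec.junk_sentence_rate and n_junk < 3:
            sentences.append(_junk_sentence(rng))
            n_junk += 1
        body = " ".join(sentences)
        if spec.html_fluff:
            body = (f'<html><head><title>Bulletin {si}</title>'
                    f'<style>p {{margin: 0}}</style></head><body>\n'
                    f'<div class="wrapper">\n<p>{body}</p>\n</div>\n'
                    f'<footer>Copyright subscribe login republish</footer>\n'
                    f'</body></html>')
        blocks.append(body)

    with open(out_path, "w", encoding="utf-8") as fh:
        for body in blocks:
            fh.write(STORY_DELIMITER + "\n")
            fh.write(body + "\n")
    if manifest_path is not None:
        manifest.write(manifest_path)
    return read_story_file(out_path), manifest


def lexicons_from_manifest(manifest: GroundTruthManifest
                           ) -> Tuple[Lexicon, Lexicon]:
    """The group/region lexicons a fixture run should be tagged with."""
    return Lexicon(manifest.groups), Lexicon(manifest.regions)
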