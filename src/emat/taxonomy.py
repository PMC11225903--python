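"""Action taxonomy: data model, readers/writers, and editing operations.

An action in the Ecosystem Management Actions Taxonomy (EMAT) belongs to one
of five categories (militaristic, diplomatic, economic, ecosystem-directed
anthropogenic, ecological) and decomposes into at most three sentence
components, each backed by an *equivalence set* of interchangeable phrases:

* a set of m-word verbs (e.g. "arrested", "picked up"),
* a set of direct-object phrases,
* a set of prepositional phrases.

The verb set must be non-empty; the other two may be empty.  Phrases are
stored lowercase and punctuation-stripped at read time so that matching is
case-insensitive.

File dialect
------------
Because the taxonomy lives in two plain-text files, this module documents a
default dialect and accepts plug-in readers for other layouts (via
``register_dialect``):

definition file (``.dfn`` role) — one action per line, tab-separated::

    # comment
    <action_id>\t<category>\t<label>\t<actor;actor;...>

equivalence file (``parsed`` role) — one record per action::

    action <action_id>
    verb: picked up
    object: a few rhino horns
    prep: in the park

Group and region lexicons are one name per line, ``#`` comments allowed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Tuple

from .similarity import Phrase
from .text import tokenize

__all__ = [
    "CATEGORIES",
    "ROLES",
    "EquivalenceSet",
    "EMATAction",
    "Taxonomy",
    "Lexicon",
    "TaxonomyWarning",
    "TaxonomyFormatError",
    "read_taxonomy",
    "write_taxonomy",
    "read_lexicon",
    "category_counts",
    "add_equivalence_member",
    "add_action",
    "lint_equivalence_sets",
    "register_dialect",
]

CATEGORIES = (
    "militaristic",
    "diplomatic",
    "economic",
    "ecosystem_directed",
    "ecological",
)

ROLES = ("verb", "direct_object", "prepositional")


class TaxonomyWarning(UserWarning):
    """Non-fatal inconsistency between taxonomy files."""


class TaxonomyFormatError(ValueError):
    """A taxonomy file line does not parse under the declared dialect."""

    def __init__(self, path: str, lineno: int, expected: str, got: str):
        super().__init__(
            f"{path}:{lineno}: expected {expected}, got {got!r}"
        )
        self.path, self.lineno = path, lineno


def _norm_phrase(text: str | Iterable[str]) -> Phrase:
    toks = tokenize(text) if isinstance(text, str) else [t.lower() for t in text]
    if not toks or any(not t for t in toks):
        raise ValueError(f"phrase must have >= 1 non-empty token: {text!r}")
    return tuple(toks)


@dataclass(frozen=True)
class EquivalenceSet:
    """An ordered, duplicate-free collection of interchangeable phrases."""

    role: str
    phrases: Tuple[Phrase, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        seen = set()
        for ph in self.phrases:
            if not ph or any(not w for w in ph):
                raise ValueError(f"empty token in phrase {ph!r}")
            if any(w != w.lower() for w in ph):
                raise ValueError(f"phrase tokens must be lowercase: {ph!r}")
            if ph in seen:
                raise ValueError(f"duplicate phrase in {self.role} set: {ph!r}")
            seen.add(ph)

    def with_phrase(self, phrase: Phrase) -> "EquivalenceSet":
        """Return a set containing phrase (no-op if already present)."""
        if phrase in self.phrases:
            return self
        return EquivalenceSet(self.role, self.phrases + (phrase,))

    def __len__(self) -> int:
        return len(self.phrases)

    def __iter__(self):
        return iter(self.phrases)

    def __contains__(self, phrase) -> bool:
        return tuple(phrase) in self.phrases


@dataclass(frozen=True)
class EMATAction:
    action_id: str
    label: str
    category: str
    archetypal_actors: Tuple[str, ...] = ()
    verb_set: EquivalenceSet = field(
        default_factory=lambda: EquivalenceSet("verb"))
    object_set: EquivalenceSet = field(
        default_factory=lambda: EquivalenceSet("direct_object"))
    prep_set: EquivalenceSet = field(
        default_factory=lambda: EquivalenceSet("prepositional"))

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}")

    def set_for_role(self, role: str) -> EquivalenceSet:
        return {"verb": self.verb_set,
                "direct_object": self.object_set,
                "prepositional": self.prep_set}[role]


@dataclass(frozen=True)
class Taxonomy:
    """Immutable collection of actions keyed by action_id."""

    actions: Dict[str, EMATAction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aid, act in self.actions.items():
            if aid != act.action_id:
                raise ValueError(f"key {aid!r} != action_id {act.action_id!r}")

    def __len__(self) -> int:
        return len(self.actions)

    def __iter__(self):
        return iter(self.actions.values())

    def __getitem__(self, action_id: str) -> EMATAction:
        return self.actions[action_id]

    def __contains__(self, action_id: str) -> bool:
        return action_id in self.actions


@dataclass(frozen=True)
class Lexicon:
    """Group or region name list (case preserved, matching is case-folded)."""

    names: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        folded = set()
        for name in self.names:
            if not name.strip():
                raise ValueError("lexicon names must be non-empty")
            key = name.casefold()
            if key in folded:
                raise ValueError(f"duplicate lexicon name: {name!r}")
            folded.add(key)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


GroupLexicon = Lexicon
RegionLexicon = Lexicon


# ---------------------------------------------------------------------------
# dialect registry
# ---------------------------------------------------------------------------

# A dialect is a pair of parsers: (parse_definitions, parse_equivalences).
# parse_definitions(text, path) -> list of (action_id, category, label, actors)
# parse_equivalences(text, path) -> dict action_id -> {role: [phrase, ...]}
_DIALECTS: Dict[str, Tuple[Callable, Callable]] = {}


def register_dialect(name: str, parse_definitions: Callable,
                     parse_equivalences: Callable) -> None:
    """Register a reader plug-in for an alternative taxonomy file layout."""
    _DIALECTS[name] = (parse_definitions, parse_equivalences)


def _parse_definitions_default(text: str, path: str):
    records = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise TaxonomyFormatError(
                path, lineno, "id<TAB>category<TAB>label[<TAB>actors]", raw)
        aid, category, label = parts[0].strip(), parts[1].strip(), parts[2].strip()
        if category not in CATEGORIES:
            raise TaxonomyFormatError(
                path, lineno, f"category in {CATEGORIES}", category)
        actors: Tuple[str, ...] = ()
        if len(parts) >= 4 and parts[3].strip():
            actors = tuple(a.strip() for a in parts[3].split(";") if a.strip())
        records.append((aid, category, label, actors))
    return records


def _parse_equivalences_default(text: str, path: str):
    out: Dict[str, Dict[str, List[Phrase]]] = {}
    current: Optional[str] = None
    role_map = {"verb": "verb", "object": "direct_object",
                "prep": "prepositional"}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("action "):
            current = line[len("action "):].strip()
            out.setdefault(current, {r: [] for r in ROLES})
            continue
        head, sep, rest = line.partition(":")
        if sep and head.strip() in role_map:
            if current is None:
                raise TaxonomyFormatError(
                    path, lineno, "an 'action <id>' header before phrase lines", raw)
            phrase = _norm_phrase(rest.strip())
            role = role_map[head.strip()]
            if phrase not in out[current][role]:
                out[current][role].append(phrase)
            continue
        raise TaxonomyFormatError(
            path, lineno, "'action <id>' or 'verb:|object:|prep: <phrase>'", raw)
    return out


register_dialect("default", _parse_definitions_default,
                 _parse_equivalences_default)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_taxonomy(definition_path, equivalence_path,
                  dialect: str = "default") -> Taxonomy:
    """Read the definition + equivalence file pair into a Taxonomy.

    Actions present in only one of the two files are kept (with empty
    equivalence sets when the equivalence record is missing) and reported
    through a TaxonomyWarning.
    """
    try:
        parse_defs, parse_equivs = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown taxonomy dialect {dialect!r}; "
                         f"known: {sorted(_DIALECTS)}") from None
    def_text = Path(definition_path).read_text(encoding="utf-8")
    eq_text = Path(equivalence_path).read_text(encoding="utf-8")
    records = parse_defs(def_text, str(definition_path))
    equivs = parse_equivs(eq_text, str(equivalence_path))

    actions: Dict[str, EMATAction] = {}
    for aid, category, label, actors in records:
        if aid in actions:
            raise TaxonomyFormatError(str(definition_path), 0,
                                      "unique action ids", aid)
        sets = equivs.get(aid, {r: [] for r in ROLES})
        actions[aid] = EMATAction(
            action_id=aid, label=label, category=category,
            archetypal_actors=actors,
            verb_set=EquivalenceSet("verb", tuple(sets["verb"])),
            object_set=EquivalenceSet("direct_object",
                                      tuple(sets["direct_object"])),
            prep_set=EquivalenceSet("prepositional",
                                    tuple(sets["prepositional"])),
        )

    missing_sets = [aid for aid, _, _, _ in records if aid not in equivs]
    if missing_sets:
        warnings.warn(
            f"actions with no equivalence record (kept with empty sets): "
            f"{missing_sets}", TaxonomyWarning, stacklevel=2)
    unknown = sorted(set(equivs) - set(actions))
    if unknown:
        warnings.warn(
            f"equivalence records for unknown action ids (ignored): {unknown}",
            TaxonomyWarning, stacklevel=2)
    return Taxonomy(actions)


def write_taxonomy(t: Taxonomy, definition_path, equivalence_path) -> None:
    """Write a Taxonomy in the default dialect (canonical formatting)."""
    dfn = io.StringIO()
    eqf = io.StringIO()
    for act in t:
        actors = ";".join(act.archetypal_actors)
        dfn.write(f"{act.action_id}\t{act.category}\t{act.label}\t{actors}\n")
        eqf.write(f"action {act.action_id}\n")
        for tag, eset in (("verb", act.verb_set), ("object", act.object_set),
                          ("prep", act.prep_set)):
            for ph in eset:
                eqf.write(f"{tag}: {' '.join(ph)}\n")
    Path(definition_path).write_text(dfn.getvalue(), encoding="utf-8")
    Path(equivalence_path).write_text(eqf.getvalue(), encoding="utf-8")


def read_lexicon(path) -> Lexicon:
    """Read a one-name-per-line lexicon file (# comments allowed)."""
    names = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return Lexicon(tuple(names))


def write_lexicon(lex: Lexicon, path) -> None:
    Path(path).write_text("".join(f"{n}\n" for n in lex), encoding="utf-8")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def category_counts(t: Taxonomy) -> Dict[str, int]:
    """Number of actions per category; every category key is present."""
    counts = {c: 0 for c in CATEGORIES}
    for act in t:
        counts[act.category] += 1
    return counts


def add_equivalence_member(t: Taxonomy, action_id: str, role: str,
                           phrase) -> Taxonomy:
    """Return a taxonomy with phrase added to one equivalence set.

    Adding a phrase that is already present is a no-op; all other sets are
    untouched.
    """
    if action_id not in t:
        raise KeyError(f"unknown action_id {action_id!r}")
    ph = _norm_phrase(phrase)
    act = t[action_id]
    if role == "verb":
        act = replace(act, verb_set=act.verb_set.with_phrase(ph))
    elif role == "direct_object":
        act = replace(act, object_set=act.object_set.with_phrase(ph))
    elif role == "prepositional":
        act = replace(act, prep_set=act.prep_set.with_phrase(ph))
    else:
        raise ValueError(f"role must be one of {ROLES}, got {role!r}")
    actions = dict(t.actions)
    actions[action_id] = act
    return Taxonomy(actions)


def _next_action_id(t: Taxonomy) -> str:
    numeric = [int(aid) for aid in t.actions if aid.isdigit()]
    return str(max(numeric, default=0) + 1)


def add_action(t: Taxonomy, label: str, category: str, verb,
               object_phrase=None, prep_phrase=None,
               archetypal_actors: Iterable[str] = ()) -> Taxonomy:
    """Create a new action whose sets hold the given initial members.

    The new action_id is max existing numeric id + 1, so growth is
    reproducible.  object/prep may be None for actions with fewer than
    three sentence components.
    """
    if any(act.label == label for act in t):
        raise ValueError(f"an action labelled {label!r} already exists")
    verb_ph = _norm_phrase(verb)
    obj = EquivalenceSet("direct_object",
                         (_norm_phrase(object_phrase),) if object_phrase else ())
    prep = EquivalenceSet("prepositional",
                          (_norm_phrase(prep_phrase),) if prep_phrase else ())
    aid = _next_action_id(t)
    act = EMATAction(
        action_id=aid, label=label, category=category,
        archetypal_actors=tuple(archetypal_actors),
        verb_set=EquivalenceSet("verb", (verb_ph,)),
        object_set=obj, prep_set=prep)
    actions = dict(t.actions)
    actions[aid] = act
    return Taxonomy(actions)


@dataclass(frozen=True)
class LintWarning:
    action_id: str
    role: str
    phrase: Phrase
    message: str


def lint_equivalence_sets(t: Taxonomy, min_words: int = 4,
                          spurious_actions: Optional[Iterable[str]] = None
                          ) -> List[LintWarning]:
    """Flag short object/prep phrases that invite spurious matches.

    Actions that keep showing up as spurious extractions usually have
    object or prepositional members of four words or fewer, which match too
    many unrelated strings.  By default every object/prep phrase with
    <= min_words tokens is flagged; pass spurious_actions to restrict the
    lint to actions already observed to misfire.
    """
    if min_words < 1:
        raise ValueError("min_words must be >= 1")
    scope = set(spurious_actions) if spurious_actions is not None else None
    out: List[LintWarning] = []
    for act in t:
        if scope is not None and act.action_id not in scope:
            continue
        for role, eset in (("direct_object", act.object_set),
                           ("prepositional", act.prep_set)):
            for ph in eset:
                if len(ph) <= min_words:
                    out.append(LintWarning(
                        act.action_id, role, ph,
                        f"{role} phrase {' '.join(ph)!r} of action "
                        f"{act.action_id} has only {len(ph)} word(s); "
                        f"members of more than {min_words} words are less "
                        f"likely to match spuriously"))
    return out
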