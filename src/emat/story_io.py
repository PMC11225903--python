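"""Story files: delimited multi-story text, HTML stripping, sentence
segmentation, and the textual-content filter.

A *story* is one scraped news article, social-media post, or report.  On
disk a story file holds many stories, each preceded by a line that is
exactly ``beginarticle 0``.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from lxml import etree, html as lxml_html

from .text import tokenize

__all__ = [
    "STORY_DELIMITER",
    "Story",
    "StoryFile",
    "ContentFilterConfig",
    "concatenate_story_files",
    "read_story_file",
    "write_story_file",
    "strip_html",
    "detect_source",
    "segment_sentences",
    "is_content_sentence",
    "content_fragment",
    "format_eco_story",
]

STORY_DELIMITER = "beginarticle 0"

# Words whose presence marks a sentence as carrying textual content.
COMMON_WORDS = frozenset({
    "the", "a", "of", "is", "by", "to", "be", "from", "and", "have",
    "in", "that", "on", "with", "as", "at", "inside",
})

# Web-boilerplate markers; "http:" matches any token starting with "http".
IRRELEVANT_WORDS = frozenset({
    "content", "copyright", "stylesheet", "subscribe", "subscription",
    "login", "header", "sidebar", "wrapper", "label", "navigation",
    "class", "column", "http:", "republish", "div",
})

DEFAULT_TAG_BLOCKLIST = frozenset({
    "script", "style", "head", "nav", "footer", "form", "iframe",
})


@dataclass
class Story:
    story_id: int
    raw_text: str
    source: str = "unknown"
    sentences: List[List[str]] = field(default_factory=list)


@dataclass
class StoryFile:
    stories: List[Story] = field(default_factory=list)
    origin_path: Optional[str] = None

    def __len__(self) -> int:
        return len(self.stories)

    def __iter__(self):
        return iter(self.stories)


@dataclass(frozen=True)
class ContentFilterConfig:
    common_words: frozenset = COMMON_WORDS
    irrelevant_words: frozenset = IRRELEVANT_WORDS
    min_common: int = 3
    max_irrelevant_frac: float = 0.80

    def __post_init__(self) -> None:
        if self.min_common < 1:
            raise ValueError("min_common must be >= 1")
        if not (0.0 < self.max_irrelevant_frac <= 1.0):
            raise ValueError("max_irrelevant_frac must lie in (0, 1]")


DEFAULT_CONTENT_FILTER = ContentFilterConfig()


# ---------------------------------------------------------------------------
# delimited story files
# ---------------------------------------------------------------------------

def read_story_file(path) -> StoryFile:
    """Split a delimited file into stories.

    Non-empty text before the first delimiter becomes a leading story.  An
    empty file (or one with no delimiters and no content) yields an empty
    StoryFile.
    """
    text = Path(path).read_text(encoding="utf-8")
    chunks: List[str] = []
    current: List[str] = []
    saw_delim = False
    for line in text.splitlines():
        if line.rstrip("\r") == STORY_DELIMITER:
            if saw_delim or current:
                chunks.append("\n".join(current))
            current = []
            saw_delim = True
        else:
            current.append(line)
    if saw_delim or current:
        chunks.append("\n".join(current))
    # Drop an empty pre-delimiter chunk (file starting with the delimiter).
    if chunks and not saw_delim and not chunks[0].strip():
        chunks = []
    elif chunks and saw_delim and not chunks[0].strip() and text.lstrip().startswith(STORY_DELIMITER):
        chunks = chunks[1:]
    stories = [Story(story_id=i, raw_text=chunk) for i, chunk in enumerate(chunks)]
    return StoryFile(stories=stories, origin_path=str(path))


def write_story_file(sf: StoryFile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for story in sf:
            fh.write(STORY_DELIMITER + "\n")
            fh.write(story.raw_text)
            if not story.raw_text.endswith("\n"):
                fh.write("\n")


def concatenate_story_files(paths: Sequence, out_path) -> StoryFile:
    """Concatenate input files into one delimited story file.

    Each input contributes one story, prefixed by the delimiter line; a
    file that already starts with the delimiter is not double-delimited.
    """
    with open(out_path, "w", encoding="utf-8") as fh:
        for p in paths:
            try:
                text = Path(p).read_text(encoding="utf-8")
            except OSError as exc:
                raise OSError(f"cannot read story input {p}: {exc}") from exc
            if not text.lstrip().startswith(STORY_DELIMITER):
                fh.write(STORY_DELIMITER + "\n")
            fh.write(text)
            if text and not text.endswith("\n"):
                fh.write("\n")
    return read_story_file(out_path)


# ---------------------------------------------------------------------------
# HTML stripping
# ---------------------------------------------------------------------------

def strip_html(raw: str, tag_blocklist=DEFAULT_TAG_BLOCKLIST) -> str:
    """Remove blocklisted elements entirely; keep text of all other tags.

    Best effort: malformed markup never raises, and input without markup
    passes through unchanged.
    """
    if "<" not in raw:
        return raw
    try:
        tree = lxml_html.fromstring(raw)
    except (etree.ParserError, ValueError):
        return re.sub(r"<[^>]*>", " ", raw)
    for tag in tag_blocklist:
        for el in list(tree.iter(tag)):
            el.drop_tree()
    # Give block-level elements a newline so lines do not run together.
    block_tags = {"p", "div", "br", "li", "tr", "h1", "h2", "h3", "h4",
                  "h5", "h6", "title", "section", "article"}
    for el in tree.iter():
        if isinstance(el.tag, str) and el.tag in block_tags:
            el.tail = "\n" + (el.tail or "")
    text = tree.text_content()
    lines = [ln.strip() for ln in text.splitlines()]
    return "\n".join(ln for ln in lines if ln)


# ---------------------------------------------------------------------------
# source detection
# ---------------------------------------------------------------------------

_URL_RE = re.compile(r"https?://([^\s/]+)", re.IGNORECASE)


def detect_source(story: Story) -> str:
    """Identify a story's reporting source.

    The registrable domain of the first URL wins; otherwise a short
    (<= 8 token) first line is taken as a masthead; otherwise "unknown".
    """
    m = _URL_RE.search(story.raw_text)
    if m:
        host = m.group(1).lower()
        if host.startswith("www."):
            host = host[4:]
        return host.rstrip(".:")
    for line in story.raw_text.splitlines():
        stripped = line.strip()
        if stripped:
            if len(stripped.split()) <= 8:
                return stripped
            return "unknown"
    return "unknown"


# ---------------------------------------------------------------------------
# sentence segmentation
# ---------------------------------------------------------------------------

ABBREVIATIONS = frozenset({
    "mr.", "mrs.", "ms.", "dr.", "prof.", "st.", "no.", "vs.", "etc.",
    "e.g.", "i.e.", "u.s.", "u.k.", "jr.", "sr.", "gen.", "col.", "lt.",
    "sgt.", "rev.", "hon.", "fig.", "approx.", "dept.", "gov.",
})

_SPLIT_RE = re.compile(r"[.?!]+(\s+)(?=[A-Z0-9])")
_INITIAL_RE = re.compile(r"^[A-Za-z]\.$")


def segment_sentences(text: str) -> List[str]:
    """Deterministic rule-based sentence split.

    Splits at [.?!] runs followed by whitespace and an uppercase letter or
    digit, except after known abbreviations and single-letter initials.
    Decimal numbers and in-sentence dates ("June 10, 2019") never split.
    """
    sentences: List[str] = []
    start = 0
    for m in _SPLIT_RE.finditer(text):
        before = text[start:m.start() + len(m.group(0)) - len(m.group(1))]
        last_word = before.split()[-1] if before.split() else ""
        if last_word.lower() in ABBREVIATIONS or _INITIAL_RE.match(last_word):
            continue
        sent = text[start:m.end() - len(m.group(1))].strip()
        if sent:
            sentences.append(sent)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# ---------------------------------------------------------------------------
# content filter
# ---------------------------------------------------------------------------

def is_content_sentence(sentence_tokens: Sequence[str],
                        cfg: ContentFilterConfig = DEFAULT_CONTENT_FILTER
                        ) -> bool:
    """True iff the sentence carries textual content.

    Requires at least ``min_common`` occurrences of common words and fewer
    than ``max_irrelevant_frac`` of tokens drawn from the boilerplate list.
    Counting is over token occurrences, so the test is order-invariant.
    """
    if not sentence_tokens:
        raise ValueError("sentence must be non-empty")
    n_common = sum(1 for t in sentence_tokens if t in cfg.common_words)
    http_rule = "http:" in cfg.irrelevant_words
    n_irr = sum(
        1 for t in sentence_tokens
        if t in cfg.irrelevant_words or (http_rule and t.startswith("http"))
    )
    frac_irr = n_irr / len(sentence_tokens)
    return n_common >= cfg.min_common and frac_irr < cfg.max_irrelevant_frac


def content_fragment(story: Story,
                     cfg: ContentFilterConfig = DEFAULT_CONTENT_FILTER
                     ) -> Story:
    """Story with only its content sentences, original order preserved."""
    kept = [s for s in story.sentences if s and is_content_sentence(s, cfg)]
    return Story(story_id=story.story_id, raw_text=story.raw_text,
                 source=story.source, sentences=kept)


# ---------------------------------------------------------------------------
# one-sentence ecological-data stories
# ---------------------------------------------------------------------------

ECO_DATA_TYPES = ("abundance", "presence/absence", "capture-recapture",
                  "rainfall", "NDVI", "landuse")
_NO_SPECIES_TYPES = {"rainfall", "NDVI", "landuse"}


def format_eco_story(group: str, data_type: str, species: str, region: str,
                     country: str, startdate, enddate) -> str:
    """Render an ecological data set as a one-sentence story.

    Data sets (abundance series, satellite indices, ...) enter the pipeline
    as template sentences so that the same extraction machinery can treat
    them as observations of a data-collection action.  For rainfall, NDVI
    and landuse data the species attribute is "N/A".
    """
    if data_type not in ECO_DATA_TYPES:
        raise ValueError(
            f"data_type must be one of {ECO_DATA_TYPES}, got {data_type!r}")
    if data_type in _NO_SPECIES_TYPES:
        species = "N/A"

    def _iso(d) -> str:
        if isinstance(d, (_dt.date, _dt.datetime)):
            return d.strftime("%Y-%m-%d")
        return str(d)

    return (f"{group} collected {data_type} data on {species} in "
            f"{region}, {country} during the period "
            f"{_iso(startdate)} to {_iso(enddate)}.")


def tokenize_sentences(story: Story) -> Story:
    """Populate story.sentences from raw text (segment + tokenize)."""
    sents = [tokenize(s) for s in segment_sentences(story.raw_text)]
    story.sentences = [s for s in sents if s]
    return story
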