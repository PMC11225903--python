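"""Extraction-accuracy assessment.

A human reads a uniformly sampled subset of stories (the extraction
assessment file) and records, per story, the actions truly present.  With
``n_true`` human-extracted actions, ``n_correct`` of them also found by the
machine, and ``n_spurious`` machine extractions absent from the human list:

    r_correct  = n_correct  / n_true    (1.0 = machine matches the human)
    r_spurious = n_spurious / n_true    (0.0 ideal)

r_correct below ~70% signals that the algorithm or the equivalence sets are
missing real actions; r_spurious above ~40% signals equivalence-set members
that are too short or too ambiguous and match unrelated text.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

from .extraction import EMATEntity, StoryDatabase, _entity_line
from .story_io import STORY_DELIMITER

__all__ = [
    "AssessmentResult",
    "LOW_RECALL_THRESHOLD",
    "HIGH_SPURIOUS_THRESHOLD",
    "write_assessment_sample",
    "score_against_benchmark",
    "read_benchmark",
]

LOW_RECALL_THRESHOLD = 0.70
HIGH_SPURIOUS_THRESHOLD = 0.40


@dataclass(frozen=True)
class AssessmentResult:
    n_true: int
    n_correct: int
    n_spurious: int

    def __post_init__(self) -> None:
        if self.n_true <= 0:
            raise ValueError("n_true must be positive (ratios undefined)")
        if not (0 <= self.n_correct <= self.n_true):
            raise ValueError("need 0 <= n_correct <= n_true")
        if self.n_spurious < 0:
            raise ValueError("n_spurious must be non-negative")

    @property
    def r_correct(self) -> float:
        return self.n_correct / self.n_true

    @property
    def r_spurious(self) -> float:
        return self.n_spurious / self.n_true

    @property
    def low_recall_flag(self) -> bool:
        """True when too many human-visible actions were missed."""
        return self.r_correct < LOW_RECALL_THRESHOLD

    @property
    def high_spurious_flag(self) -> bool:
        """True when spurious matches dominate (sets too short/ambiguous)."""
        return self.r_spurious > HIGH_SPURIOUS_THRESHOLD


def write_assessment_sample(story_path, db: StoryDatabase, k: int = 10,
                            out_path=None) -> List[int]:
    """Write k uniformly line-spaced stories with their extracted entities.

    With m total lines in the story file, the story containing line
    floor(i*m/k) is sampled for i = 0..k-1; duplicates are skipped forward
    to the next unsampled story.  Files with fewer than k stories are
    sampled whole.  Returns the sampled story ids.
    """
    lines = Path(story_path).read_text(encoding="utf-8").splitlines()
    m = len(lines)
    # Map each line to the ordinal of the story it belongs to.
    story_of_line: List[int] = []
    ordinal = -1
    for line in lines:
        if line.rstrip("\r") == STORY_DELIMITER:
            ordinal += 1
        elif ordinal == -1 and line.strip():
            ordinal = 0  # leading text before the first delimiter
        story_of_line.append(max(ordinal, 0))
    n_stories = (max(story_of_line) + 1) if story_of_line else 0

    if n_stories <= k:
        sampled = list(range(n_stories))
    else:
        sampled = []
        for i in range(k):
            sid = story_of_line[min((i * m) // k, m - 1)]
            while sid in sampled and sid < n_stories - 1:
                sid += 1
            if sid not in sampled:
                sampled.append(sid)

    if out_path is not None:
        with open(out_path, "w", encoding="utf-8") as fh:
            for sid in sampled:
                fh.write(f"=== story {sid} ===\n")
                text = "\n".join(l for l, s in zip(lines, story_of_line)
                                 if s == sid and l.rstrip("\r") != STORY_DELIMITER)
                fh.write(text + "\n")
                fh.write(f"--- entities extracted from story {sid} ---\n")
                for e in db.per_story.get(sid, []):
                    fh.write(_entity_line(e) + "\n")
                fh.write("\n")
    return sampled


def _as_pairs(entities) -> List[Tuple[int, str]]:
    out = []
    for e in entities:
        if isinstance(e, EMATEntity):
            out.append((e.story_id, e.action_id))
        else:
            sid, aid = e
            out.append((int(sid), str(aid)))
    return out


def score_against_benchmark(machine: Sequence, human: Sequence
                            ) -> AssessmentResult:
    """Compare machine extractions against a human benchmark.

    Both lists hold entities or (story_id, action_id) pairs; the match
    criterion is same story and same action.  Matching is multiset-aware:
    each machine extraction can account for at most one human entity.
    """
    h = Counter(_as_pairs(human))
    m = Counter(_as_pairs(machine))
    if sum(h.values()) == 0:
        raise ValueError("empty human benchmark: ratios are undefined")
    n_correct = sum(min(h[k], m[k]) for k in h)
    n_spurious = sum(c - min(c, h[k]) for k, c in m.items())
    return AssessmentResult(n_true=sum(h.values()), n_correct=n_correct,
                            n_spurious=n_spurious)


def read_benchmark(path) -> List[Tuple[int, str]]:
    """Read a tab-separated (story_id, action_id) benchmark file."""
    pairs = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(),
                                 start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected story_id<TAB>action_id")
        pairs.append((int(parts[0]), parts[1]))
    return pairs
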