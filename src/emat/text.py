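"""Shared tokenization rules and closed-class word lists.

Tokenization is deliberately simple and deterministic: lowercase, split on
whitespace, strip leading/trailing punctuation.  Intra-word hyphens and
"http..." prefixes survive intact, which the boilerplate filter relies on.
"""

from __future__ import annotations

from typing import List

# Punctuation stripped from token edges; hyphens are kept so that
# "capture-recapture" stays one token.
_EDGE_PUNCT = ".,;:!?\"'()[]{}<>|/\\*`~"

PREPOSITIONS = frozenset({
    "of", "in", "on", "at", "to", "from", "with", "by", "for",
    "against", "into", "during", "over", "under", "inside",
})

CONJUNCTIONS = frozenset({"and", "or", "but", "nor"})

# Auxiliary verb forms: never a verb match on their own, and dropped in
# front of passive participles ("were arrested" -> "arrested").
AUXILIARIES = frozenset({
    "be", "am", "is", "are", "was", "were", "been", "being",
    "have", "has", "had", "having", "do", "does", "did", "doing",
})


def tokenize(text: str) -> List[str]:
    """Split text into lowercase tokens with edge punctuation stripped."""
    out: List[str] = []
    for raw in text.split():
        tok = raw.lower()
        if tok.startswith("http"):
            out.append(tok)
            continue
        tok = tok.strip(_EDGE_PUNCT)
        if tok:
            out.append(tok)
    return out
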