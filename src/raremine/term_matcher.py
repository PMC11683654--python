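"""Dictionary string matching with negation detection — the first step of
entity extraction.

Candidate medical terms are found by case-insensitive, word-boundary,
longest-match-wins scanning of a segment against the compiled concept
lexicon.  A small regex-driven negation detector then flags candidates in the
scope of a preceding negation cue ("no", "without", "no evidence of", ...);
flagged candidates are retained and surfaced to the language model rather
than dropped, so the model sees the cue context.

This is deliberately not a full NegEx/ConText implementation: only
pre-position cues are handled, within a token window, with periods and
semicolons terminating scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

from .normalize import normalize_name
from .ontology_kb import OntologyConcept

_WORD = re.compile(r"\w+(?:[-']\w+)*")
_CLAUSE_BOUNDARY = re.compile(r"[.;]")

DEFAULT_NEGATION_WINDOW = 5


@dataclass(frozen=True)
class TermMatch:
    """A lexicon hit in a segment, carrying the concept's definition so it
    can be injected into prompts."""

    surface: str
    concept_id: str
    span: tuple[int, int]
    negated: bool = False
    definition: str = ""
    category: str = "disease"


@dataclass(frozen=True)
class NegationLexicon:
    keywords: tuple[str, ...]
    window_tokens: int = DEFAULT_NEGATION_WINDOW

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("negation lexicon needs at least one cue")
        if self.window_tokens < 1:
            raise ValueError("negation window must be >= 1 token")


def load_negation_lexicon(
    path: str | Path | None = None, window_tokens: int = DEFAULT_NEGATION_WINDOW
) -> NegationLexicon:
    """Load cues (one per line, UTF-8, '#' comments) from ``path`` or from
    the seed list shipped with the package."""
    if path is None:
        raw = resources.files("raremine").joinpath("data/negation_cues.txt").read_text("utf-8")
    else:
        raw = Path(path).read_text(encoding="utf-8")
    cues = tuple(
        line.strip() for line in raw.splitlines() if line.strip() and not line.startswith("#")
    )
    return NegationLexicon(keywords=cues, window_tokens=window_tokens)


def match_terms(
    segment_text: str, concept_lexicon: dict[str, OntologyConcept]
) -> list[TermMatch]:
    """Scan a segment for lexicon terms.

    Matches are case-insensitive, anchored at word boundaries, longest match
    wins at each position, and returned spans never overlap (left-to-right
    greedy).  Multi-word terms must appear with plain whitespace between
    words; intervening punctuation blocks the phrase.
    """
    if not segment_text or not concept_lexicon:
        return []
    max_words = max(len(key.split()) for key in concept_lexicon)
    words = list(_WORD.finditer(segment_text))
    matches: list[TermMatch] = []
    i = 0
    while i < len(words):
        found = None
        for n in range(min(max_words, len(words) - i), 0, -1):
            start = words[i].start()
            end = words[i + n - 1].end()
            key = normalize_name(segment_text[start:end])
            concept = concept_lexicon.get(key)
            if concept is not None:
                found = (n, start, end, concept)
                break
        if found is None:
            i += 1
            continue
        n, start, end, concept = found
        matches.append(
            TermMatch(
                surface=segment_text[start:end],
                concept_id=concept.concept_id,
                span=(start, end),
                definition=concept.definition,
                category=concept.category,
            )
        )
        i += n
    return matches


def detect_negation(
    segment_text: str, match: TermMatch, neg: NegationLexicon
) -> bool:
    """True iff a cue precedes the match within the token window with no
    intervening clause boundary (period or semicolon).

    Pure function of (text, span, lexicon).
    """
    preceding = segment_text[: match.span[0]]
    boundaries = list(_CLAUSE_BOUNDARY.finditer(preceding))
    scope_start = boundaries[-1].end() if boundaries else 0
    scope = preceding[scope_start:]
    scope_words = list(_WORD.finditer(scope))
    if not scope_words:
        return False
    window_words = scope_words[-neg.window_tokens :]
    window_start = window_words[0].start()
    window = scope[window_start:]
    for cue in neg.keywords:
        pattern = r"(?<!\w)" + r"\s+".join(re.escape(w) for w in cue.split()) + r"(?!\w)"
        if re.search(pattern, window, flags=re.IGNORECASE):
            return True
    return False


def annotate_negation(
    matches: list[TermMatch], segment_text: str, neg: NegationLexicon
) -> list[TermMatch]:
    """Set the negated flag on every match, preserving order."""
    return [
        replace(m, negated=detect_negation(segment_text, m, neg)) for m in matches
    ]
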