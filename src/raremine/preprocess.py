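"""Token-budgeted document segmentation.

Long documents are cut at natural paragraph boundaries (one or more blank
lines) so that each segment stays under a token budget (default 2000, chosen
for an 8000-token context window with ~1000 tokens of instructions).  A single
paragraph at or over budget falls back to sentence-boundary packing, and a
pathological unsplittable sentence is hard-wrapped at the token level with a
warning.

Because relations occasionally span a paragraph boundary, bridge windows
centered on each boundary are emitted for a second relation-extraction pass;
they overlap the flanking segments and are marked ``is_bridge``.

Segment character spans tile the source document exactly, so concatenating
the segment texts reconstructs the input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable

logger = logging.getLogger(__name__)

DEFAULT_SEGMENT_TOKENS = 2000
DEFAULT_BRIDGE_TOKENS = 1000

_PARA_BREAK = re.compile(r"\n[ \t]*\n+")
_SENT_BREAK = re.compile(r"(?<=[.!?])\s+")
_TOKEN = re.compile(r"\S+")


@dataclass(frozen=True)
class Segment:
    """A contiguous slice of a document, with ``is_bridge`` marking the
    overlapping boundary windows used only for relation re-extraction."""

    doc_id: str
    seg_index: int
    text: str
    char_start: int
    char_end: int
    token_count: int
    is_bridge: bool = False


# ---------------------------------------------------------------------------
# token counting

def _whitespace_count(text: str) -> int:
    return len(text.split())


def _resolve_tokenizer(tokenizer_spec: str) -> Callable[[str], int]:
    """Map a spec string to a counting function.

    ``whitespace`` is the rule-based fallback; ``tiktoken:<encoding>`` uses a
    GPT-style byte-pair encoder when that library is importable; ``auto``
    prefers byte-pair and falls back to whitespace.
    """
    if tokenizer_spec == "whitespace":
        return _whitespace_count
    if tokenizer_spec.startswith("tiktoken") or tokenizer_spec == "auto":
        name = tokenizer_spec.split(":", 1)[1] if ":" in tokenizer_spec else "cl100k_base"
        try:
            import tiktoken

            enc = tiktoken.get_encoding(name)
            return lambda text: len(enc.encode(text))
        except ImportError:
            if tokenizer_spec == "auto":
                return _whitespace_count
            raise ValueError(
                f"tokenizer spec {tokenizer_spec!r} requires the tiktoken library"
            ) from None
    raise ValueError(f"unknown tokenizer spec {tokenizer_spec!r}")


def count_tokens(text: str, tokenizer_spec: str = "auto") -> int:
    """Deterministic token count for a fixed spec; 0 for empty text."""
    if not text:
        return 0
    return _resolve_tokenizer(tokenizer_spec)(text)


# ---------------------------------------------------------------------------
# segmentation

def _tiled_spans(text: str, breaks: re.Pattern) -> list[tuple[int, int]]:
    """Split ``text`` at ``breaks`` into spans that tile [0, len(text)):
    each span runs from the start of one unit to the start of the next, so
    separators travel with the preceding unit."""
    starts = [0]
    for m in breaks.finditer(text):
        if m.end() < len(text):
            starts.append(m.end())
    spans = []
    for i, s in enumerate(starts):
        e = starts[i + 1] if i + 1 < len(starts) else len(text)
        spans.append((s, e))
    return spans


def _pack_spans(
    text: str,
    spans: list[tuple[int, int]],
    max_tokens: int,
    counter: Callable[[str], int],
    oversize: Callable[[tuple[int, int]], list[tuple[int, int]]],
) -> list[tuple[int, int]]:
    """Greedily merge consecutive unit spans while the merged slice stays
    under ``max_tokens``; a single over-budget unit is delegated to
    ``oversize`` for finer splitting."""
    out: list[tuple[int, int]] = []
    current: tuple[int, int] | None = None
    for span in spans:
        unit_tokens = counter(text[span[0] : span[1]])
        if unit_tokens >= max_tokens:
            if current is not None:
                out.append(current)
                current = None
            out.extend(oversize(span))
            continue
        if current is None:
            current = span
        else:
            merged = (current[0], span[1])
            if counter(text[merged[0] : merged[1]]) < max_tokens:
                current = merged
            else:
                out.append(current)
                current = span
    if current is not None:
        out.append(current)
    return out


def _hard_wrap(text: str, span: tuple[int, int], max_tokens: int) -> list[tuple[int, int]]:
    """Last-resort token-level wrap of an unsplittable stretch; keeps every
    chunk under budget and tiles the span."""
    logger.warning(
        "hard-wrapping an unsplittable stretch of %d chars at the token level",
        span[1] - span[0],
    )
    token_starts = [span[0] + m.start() for m in _TOKEN.finditer(text[span[0] : span[1]])]
    if not token_starts:
        return [span]
    chunk = max(1, max_tokens - 1)
    chunks = []
    for i in range(0, len(token_starts), chunk):
        start = token_starts[i] if chunks else span[0]
        end = token_starts[i + chunk] if i + chunk < len(token_starts) else span[1]
        chunks.append((start, end))
    return chunks


def segment_document(
    text: str,
    max_tokens: int = DEFAULT_SEGMENT_TOKENS,
    *,
    doc_id: str = "",
    tokenizer_spec: str = "auto",
) -> list[Segment]:
    """Cut a document into paragraph-bounded segments under ``max_tokens``.

    Consecutive paragraphs are packed greedily; an over-budget paragraph is
    re-packed at sentence boundaries, and an over-budget sentence is
    hard-wrapped.  The returned (non-bridge) segments' character spans are
    ordered, non-overlapping, and cover the document exactly.
    """
    if max_tokens < 1:
        raise ValueError(f"max_tokens must be >= 1, got {max_tokens}")
    if not text:
        return []
    counter = _resolve_tokenizer(tokenizer_spec)

    def split_sentence_level(span: tuple[int, int]) -> list[tuple[int, int]]:
        para = text[span[0] : span[1]]
        sent_spans = [(span[0] + s, span[0] + e) for s, e in _tiled_spans(para, _SENT_BREAK)]
        return _pack_spans(
            text, sent_spans, max_tokens, counter, lambda sp: _hard_wrap(text, sp, max_tokens)
        )

    para_spans = _tiled_spans(text, _PARA_BREAK)
    packed = _pack_spans(text, para_spans, max_tokens, counter, split_sentence_level)
    return [
        Segment(
            doc_id=doc_id,
            seg_index=i,
            text=text[s:e],
            char_start=s,
            char_end=e,
            token_count=counter(text[s:e]),
        )
        for i, (s, e) in enumerate(packed)
    ]


def bridge_windows(
    text: str,
    segments: list[Segment],
    window_tokens: int = DEFAULT_BRIDGE_TOKENS,
    *,
    tokenizer_spec: str = "auto",
) -> list[Segment]:
    """One overlapping window per adjacent segment boundary, centered on the
    boundary with ``window_tokens/2`` tokens drawn from each side (clipped at
    the flanking segments' edges).

    Windows exist to re-extract relations whose arguments straddle a
    boundary; fewer than two segments yield no windows.
    """
    counter = _resolve_tokenizer(tokenizer_spec)
    base = [s for s in segments if not s.is_bridge]
    if len(base) < 2:
        return []
    half = max(1, window_tokens // 2)
    windows = []
    for i in range(len(base) - 1):
        left, right = base[i], base[i + 1]
        # token-start offsets are computed with the whitespace rule; the
        # window edge only needs to land on a word boundary
        left_tokens = [left.char_start + m.start() for m in _TOKEN.finditer(left.text)]
        right_tokens = [
            (right.char_start + m.start(), right.char_start + m.end())
            for m in _TOKEN.finditer(right.text)
        ]
        start = left_tokens[-half] if len(left_tokens) > half else left.char_start
        end = right_tokens[half - 1][1] if len(right_tokens) > half else right.char_end
        windows.append(
            Segment(
                doc_id=left.doc_id,
                seg_index=i,
                text=text[start:end],
                char_start=start,
                char_end=end,
                token_count=counter(text[start:end]),
                is_bridge=True,
            )
        )
    return windows
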