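"""Language-model backend contract, robust JSON payload parsing, and the
deterministic fixture-driven mock backend.

Every prompt rendered by :mod:`raremine.prompting` begins with a
machine-readable stage marker line::

    <<raremine stage=extract_entities doc=D0007 span=120-840 bridge=0>>

A live backend treats the marker as harmless instruction text; the mock
backend uses it to route the request to the right gold answer.  The mock is
the default backend: it answers each stage from gold annotations, optionally
thinned/perturbed by seeded Bernoulli corruption, and is byte-deterministic
given (oracle state, prompt).  No module outside this one performs network
I/O.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
import re
import time
from dataclasses import dataclass, field
from typing import Protocol

from .corpus_io import ENTITY_TYPES, AnnotatedDocument
from .preprocess import count_tokens

logger = logging.getLogger(__name__)

STAGE_MARKER_TEMPLATE = "<<raremine stage={stage} doc={doc_id} span={start}-{end} bridge={bridge}>>"
_STAGE_MARKER = re.compile(
    r"<<raremine stage=(?P<stage>[\w-]+) doc=(?P<doc>[^ >]*) "
    r"span=(?P<start>\d+)-(?P<end>\d+) bridge=(?P<bridge>[01])>>"
)
_FENCED = re.compile(r"```(?:json)?\s*\n(.*?)```", re.DOTALL)
_SLOT_BLOCK = re.compile(
    r"\[slot:(?P<name>[\w-]+)\]\s*```(?:json)?\s*\n(?P<body>.*?)```", re.DOTALL
)

STAGES = ("extract_more_terms", "extract_entities", "extract_relations", "calibrate")

#: token head-room reserved for the model's reply when checking context fit
RESPONSE_RESERVE_TOKENS = 1000


class BackendError(RuntimeError):
    """Unrecoverable backend failure (carries the last cause on retry exhaustion)."""


class TransientBackendError(BackendError):
    """A failure worth retrying (rate limit, timeout, flaky transport)."""


class PayloadParseError(ValueError):
    """No JSON object could be recovered from a response; raw text attached."""

    def __init__(self, message: str, raw_text: str = ""):
        super().__init__(message)
        self.raw_text = raw_text


class PayloadSchemaError(ValueError):
    """The recovered JSON object does not have the expected shape."""


@dataclass
class BackendConfig:
    backend_name: str = "mock"
    temperature: float = 0.0  # 0 for the most stable output
    max_context_tokens: int = 8000
    retry_limit: int = 2
    seed: int = 0
    tokenizer_spec: str = "auto"

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.max_context_tokens <= RESPONSE_RESERVE_TOKENS:
            raise ValueError("max_context_tokens must exceed the response reserve")


@dataclass
class CompletionRecord:
    prompt_text: str
    response_text: str
    backend_name: str
    latency: float = 0.0
    token_counts: tuple[int, int] = (0, 0)


class Backend(Protocol):
    name: str

    def respond(self, prompt_text: str) -> str: ...


def complete(config: BackendConfig, prompt_text: str, backend: Backend) -> CompletionRecord:
    """Dispatch a prompt, retrying transient failures up to ``retry_limit``.

    The prompt is refused before dispatch if it cannot fit in the context
    window together with the reserved response budget.
    """
    prompt_tokens = count_tokens(prompt_text, config.tokenizer_spec)
    if prompt_tokens + RESPONSE_RESERVE_TOKENS > config.max_context_tokens:
        raise BackendError(
            f"prompt of {prompt_tokens} tokens cannot fit a "
            f"{config.max_context_tokens}-token context with "
            f"{RESPONSE_RESERVE_TOKENS} tokens reserved for the response"
        )
    last_error: Exception | None = None
    for attempt in range(config.retry_limit + 1):
        started = time.perf_counter()
        try:
            response = backend.respond(prompt_text)
        except TransientBackendError as exc:
            last_error = exc
            logger.warning("backend %s attempt %d failed: %s", backend.name, attempt + 1, exc)
            continue
        record = CompletionRecord(
            prompt_text=prompt_text,
            response_text=response,
            backend_name=backend.name,
            latency=time.perf_counter() - started,
            token_counts=(prompt_tokens, count_tokens(response, config.tokenizer_spec)),
        )
        logger.debug(
            "completion via %s: %d prompt / %d response tokens",
            backend.name, *record.token_counts,
        )
        return record
    raise BackendError(
        f"backend {backend.name} failed after {config.retry_limit + 1} attempts"
    ) from last_error


# ---------------------------------------------------------------------------
# payload parsing

def _balance_repair(fragment: str) -> str:
    """Append the closing brackets a truncated JSON object is missing."""
    stack = []
    in_string = False
    escaped = False
    for ch in fragment:
        if escaped:
            escaped = False
            continue
        if ch == "\\":
            escaped = True
        elif in_string:
            if ch == '"':
                in_string = False
        elif ch == '"':
            in_string = True
        elif ch in "{[":
            stack.append("}" if ch == "{" else "]")
        elif ch in "}]":
            if stack:
                stack.pop()
    if in_string:
        fragment += '"'
    return fragment + "".join(reversed(stack))


def _candidate_fragments(response_text: str):
    yield response_text
    for m in _FENCED.finditer(response_text):
        yield m.group(1)
    brace = response_text.find("{")
    if brace >= 0:
        yield response_text[brace:]


def parse_json_payload(
    response_text: str,
    expected_keys: tuple[str, ...] | list[str] = (),
    *,
    list_keys: tuple[str, ...] | list[str] = (),
) -> dict:
    """Extract the first well-formed JSON object from a model response.

    Tries, in order: the whole text, fenced code blocks, a raw decode from
    the first ``{``, and finally a bracket-balancing truncation repair.
    ``list_keys`` are coerced to ``[]`` when missing or null; any remaining
    ``expected_keys`` must be present or a :class:`PayloadSchemaError` lists
    them.
    """
    decoder = json.JSONDecoder()
    payload = None
    for fragment in _candidate_fragments(response_text):
        for attempt in (fragment, _balance_repair(fragment)):
            try:
                value, _ = decoder.raw_decode(attempt.strip())
            except (json.JSONDecodeError, ValueError):
                continue
            if isinstance(value, dict):
                payload = value
                break
        if payload is not None:
            break
    if payload is None:
        raise PayloadParseError("no JSON object found in response", raw_text=response_text)
    for key in list_keys:
        if payload.get(key) is None:
            payload[key] = []
        elif not isinstance(payload[key], list):
            raise PayloadSchemaError(f"key {key!r} must be a list, got {type(payload[key]).__name__}")
    missing = [k for k in expected_keys if k not in payload]
    if missing:
        raise PayloadSchemaError(f"response object is missing keys: {missing}")
    return payload


def parse_stage_marker(prompt_text: str) -> dict | None:
    """Recover the routing header a rendered prompt embeds, if any."""
    m = _STAGE_MARKER.search(prompt_text)
    if m is None:
        return None
    return {
        "stage": m.group("stage"),
        "doc_id": m.group("doc"),
        "window": (int(m.group("start")), int(m.group("end"))),
        "is_bridge": m.group("bridge") == "1",
    }


def parse_slot_blocks(prompt_text: str) -> dict[str, object]:
    """Recover the JSON slot payloads embedded in a rendered prompt."""
    slots: dict[str, object] = {}
    for m in _SLOT_BLOCK.finditer(prompt_text):
        try:
            slots[m.group("name")] = json.loads(m.group("body"))
        except json.JSONDecodeError:
            continue
    return slots


# ---------------------------------------------------------------------------
# mock backend

def _stable_seed(*parts) -> int:
    digest = hashlib.blake2s("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _mentions_in_window(doc: AnnotatedDocument, window: tuple[int, int]):
    a, b = window
    for m in doc.entities:
        if m.span is not None and a <= m.span[0] and m.span[1] <= b:
            yield m


def mock_respond(oracle_state, prompt_text: str) -> str:
    """Answer a stage prompt from gold fixtures.

    ``oracle_state`` exposes ``gold`` (doc_id -> AnnotatedDocument),
    ``corruption`` (entity_drop_p, type_confuse_p, relation_drop_p,
    spurious_rate) and ``seed``.  The response is the gold-derived JSON for
    the stage the prompt's marker encodes, restricted to the marker's
    character window and perturbed by seeded Bernoulli corruption.
    Deterministic given (oracle_state, prompt_text).
    """
    marker = parse_stage_marker(prompt_text)
    if marker is None:
        raise BackendError("mock backend: prompt has no stage marker")
    stage = marker["stage"]
    if stage not in STAGES:
        raise BackendError(f"mock backend: unknown stage {stage!r}")

    if stage == "calibrate":
        slots = parse_slot_blocks(prompt_text)
        listed = slots.get("candidate_entities", [])
        names = [e.get("text", "") for e in listed if isinstance(e, dict)]
        return json.dumps({"entities": names})

    doc = oracle_state.gold.get(marker["doc_id"])
    if doc is None:
        raise BackendError(f"mock backend: no gold for document {marker['doc_id']!r}")
    window = marker["window"]
    corruption = oracle_state.corruption
    rng = random.Random(
        _stable_seed(oracle_state.seed, marker["doc_id"], stage, window[0], window[1])
    )
    in_window = list(_mentions_in_window(doc, window))

    if stage == "extract_more_terms":
        terms = [m.surface for m in in_window if m.entity_type != "anaphor"]
        anaphors = [m.surface for m in in_window if m.entity_type == "anaphor"]
        return json.dumps({"terms": terms, "anaphors": anaphors})

    if stage == "extract_entities":
        entities = []
        for m in in_window:
            if rng.random() < corruption.entity_drop_p:
                continue
            etype = m.entity_type
            if corruption.type_confuse_p and rng.random() < corruption.type_confuse_p:
                etype = rng.choice([t for t in ENTITY_TYPES if t != m.entity_type])
            entities.append(
                {
                    "text": m.surface,
                    "type": etype,
                    "start": m.span[0] - window[0],
                    "end": m.span[1] - window[0],
                }
            )
        if corruption.spurious_rate and rng.random() < corruption.spurious_rate:
            entities.append(
                {
                    "text": f"spurious finding {rng.randrange(10**6)}",
                    "type": rng.choice(ENTITY_TYPES[:3]),
                }
            )
        return json.dumps({"entities": entities})

    # extract_relations
    ids_in_window = {m.mention_id for m in in_window}
    relations = []
    for rel in doc.relations:
        if rel.subject_ref in ids_in_window and rel.object_ref in ids_in_window:
            if rng.random() < corruption.relation_drop_p:
                continue
            subj = doc.mention_by_id(rel.subject_ref)
            obj = doc.mention_by_id(rel.object_ref)
            relations.append(
                {"subject": subj.surface, "type": rel.relation_type, "object": obj.surface}
            )
    return json.dumps({"relations": relations})


class MockBackend:
    """Deterministic gold-oracle test double for a live LLM."""

    name = "mock"

    def __init__(self, oracle_state):
        self.oracle_state = oracle_state

    def respond(self, prompt_text: str) -> str:
        return mock_respond(self.oracle_state, prompt_text)


class OpenAICompatibleBackend:
    """Thin adapter for an OpenAI-compatible chat-completions API.

    Isolated and optional: the library is imported lazily, and nothing in the
    offline test path touches this class.
    """

    def __init__(self, model: str = "gpt-4-0613", temperature: float = 0.0, **client_kwargs):
        try:
            from openai import OpenAI
        except ImportError as exc:
            raise BackendError(
                "the 'openai' package is required for the live backend; "
                "install it or use the mock backend"
            ) from exc
        self._client = OpenAI(**client_kwargs)
        self.model = model
        self.temperature = temperature
        self.name = f"openai:{model}"

    def respond(self, prompt_text: str) -> str:
        try:
            result = self._client.chat.completions.create(
                model=self.model,
                temperature=self.temperature,
                messages=[{"role": "user", "content": prompt_text}],
            )
        except Exception as exc:  # transport errors are worth retrying
            raise TransientBackendError(str(exc)) from exc
        return result.choices[0].message.content or ""


def get_backend(config: BackendConfig, oracle_state=None) -> Backend:
    if config.backend_name == "mock":
        if oracle_state is None:
            raise BackendError("mock backend requires an oracle state")
        return MockBackend(oracle_state)
    if config.backend_name in ("openai", "openai-compatible"):
        return OpenAICompatibleBackend(temperature=config.temperature)
    raise BackendError(f"unknown backend {config.backend_name!r}")
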