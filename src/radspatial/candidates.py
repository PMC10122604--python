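"""Tokenization, mention tagging and {trigger, entity} candidate generation.

A sentence is tokenized on whitespace with edge punctuation split off
(hyphens and internal periods preserved, so "C5-C7" and "1.5" survive).
Entity mentions come from three matchers: longest-match dictionary lookup
(with the location-descriptor exception), a distance regex ("1 cm",
"2-3 mm") and a vertebral-segment regex ("C5-C7", "T12").  Spatial
triggers are dictionary-matched separately.  Candidates are the cross
product of triggers and entities within a sentence, minus overlapping
pairs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .lexicon import Lexicon, normalize

_EDGE_PUNCT = set(".,;:()/")

_DISTANCE_RE = re.compile(
    r"\b\d+(?:\.\d+)?(?:\s*-\s*\d+(?:\.\d+)?)?\s*"
    r"(?:mm|cm|millimeters?|centimeters?)\b",
    re.IGNORECASE,
)
_SEGMENT_RE = re.compile(r"\b[CTL]\d{1,2}(?:-[CTL]?\d{1,2})?\b")


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int


@dataclass(eq=False)  # identity equality/hash: mentions embed their sentence
class Sentence:
    doc_id: str
    sent_id: int
    text: str
    tokens: list[Token] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.doc_id, self.sent_id)

    def token_span_for(self, start: int, end: int) -> tuple[int, int] | None:
        """Token index range covering chars [start, end), or None if the
        span is not token-aligned."""
        first = last = None
        for i, tok in enumerate(self.tokens):
            if tok.start == start:
                first = i
            if tok.end == end:
                last = i
        if first is None or last is None or last < first:
            return None
        return (first, last)


@dataclass(frozen=True)
class EntityMention:
    sentence: Sentence
    start: int
    end: int
    tok_first: int
    tok_last: int
    surface: str
    categories: frozenset[str]
    matcher: str  # dictionary | distance_regex | segment_regex

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class TriggerMention:
    sentence: Sentence
    start: int
    end: int
    tok_first: int
    tok_last: int
    surface: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class CandidatePair:
    trigger: TriggerMention
    entity: EntityMention
    token_gap: int
    entity_side: str  # left | right

    @property
    def sentence(self) -> Sentence:
        return self.trigger.sentence


def tokenize(text: str, doc_id: str = "doc", sent_id: int = 0) -> Sentence:
    """Whitespace tokenization with edge punctuation split into own tokens."""
    tokens: list[Token] = []
    for match in re.finditer(r"\S+", text):
        chunk, start = match.group(), match.start()
        end = start + len(chunk)
        # peel leading punctuation
        while chunk and chunk[0] in _EDGE_PUNCT:
            tokens.append(Token(chunk[0], start, start + 1))
            chunk, start = chunk[1:], start + 1
        # peel trailing punctuation (collect, emit after the core)
        trailing: list[Token] = []
        while chunk and chunk[-1] in _EDGE_PUNCT:
            trailing.append(Token(chunk[-1], end - 1, end))
            chunk, end = chunk[:-1], end - 1
        if chunk:
            tokens.append(Token(chunk, start, end))
        tokens.extend(reversed(trailing))
    return Sentence(doc_id, sent_id, text, tokens)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _dictionary_candidates(sentence: Sentence, lexicon: Lexicon) -> list[EntityMention]:
    out = []
    n = len(sentence.tokens)
    width = max(lexicon.max_tokens, 1)
    for i in range(n):
        for j in range(i, min(i + width, n)):
            start = sentence.tokens[i].start
            end = sentence.tokens[j].end
            surface = sentence.text[start:end]
            cats = lexicon.lookup(surface)
            if cats:
                out.append(
                    EntityMention(
                        sentence, start, end, i, j, surface, frozenset(cats), "dictionary"
                    )
                )
    return out


def _select_longest(cands: list[EntityMention]) -> list[EntityMention]:
    """Greedy longest-match selection; ties by leftmost start, then
    dictionary matches before regex matches."""
    priority = {"dictionary": 0, "distance_regex": 1, "segment_regex": 2}
    ordered = sorted(
        cands, key=lambda m: (-(m.end - m.start), m.start, priority[m.matcher])
    )
    kept: list[EntityMention] = []
    for cand in ordered:
        if not any(_overlaps(cand.span, k.span) for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda m: (m.start, m.end))


def _descriptor_exception(
    selected: list[EntityMention], sentence: Sentence, lexicon: Lexicon
) -> list[EntityMention]:
    """Split multi-token anatomy spans that begin with a location descriptor
    into the descriptor mention plus the remaining anatomy mention."""
    out: list[EntityMention] = []
    for m in selected:
        if (
            m.matcher == "dictionary"
            and "anatomy" in m.categories
            and m.tok_last > m.tok_first
            and "location_descriptor" in lexicon.lookup(sentence.tokens[m.tok_first].surface)
        ):
            head = sentence.tokens[m.tok_first]
            rest_first = m.tok_first + 1
            rest_start = sentence.tokens[rest_first].start
            rest_surface = sentence.text[rest_start : m.end]
            rest_cats = lexicon.lookup(rest_surface) or {"anatomy"}
            out.append(
                EntityMention(
                    sentence,
                    head.start,
                    head.end,
                    m.tok_first,
                    m.tok_first,
                    head.surface,
                    frozenset(lexicon.lookup(head.surface)),
                    "dictionary",
                )
            )
            out.append(
                EntityMention(
                    sentence,
                    rest_start,
                    m.end,
                    rest_first,
                    m.tok_last,
                    rest_surface,
                    frozenset(rest_cats),
                    "dictionary",
                )
            )
        else:
            out.append(m)
    return sorted(out, key=lambda m: (m.start, m.end))


def tag_entities(sentence: Sentence, lexicon: Lexicon) -> list[EntityMention]:
    """Dictionary mentions: longest-match with the descriptor exception."""
    if len(lexicon) == 0:
        raise ValueError("entity lexicon is empty")
    selected = _select_longest(_dictionary_candidates(sentence, lexicon))
    return _descriptor_exception(selected, sentence, lexicon)


def _regex_mentions(
    sentence: Sentence, pattern: re.Pattern, categories: frozenset[str], matcher: str
) -> list[EntityMention]:
    out = []
    for m in pattern.finditer(sentence.text):
        span = sentence.token_span_for(m.start(), m.end())
        if span is None:
            continue
        out.append(
            EntityMention(
                sentence, m.start(), m.end(), span[0], span[1], m.group(), categories, matcher
            )
        )
    return out


def match_distance(sentence: Sentence) -> list[EntityMention]:
    """Distance measurements: number (or range) followed by a length unit."""
    return _regex_mentions(sentence, _DISTANCE_RE, frozenset({"distance"}), "distance_regex")


def match_segment(sentence: Sentence) -> list[EntityMention]:
    """Vertebral segment codes (C/T/L + level, optionally hyphenated)."""
    return _regex_mentions(sentence, _SEGMENT_RE, frozenset({"anatomy"}), "segment_regex")


def tag_triggers(sentence: Sentence, triggers: Lexicon) -> list[TriggerMention]:
    """Longest-match trigger tagging over the spatial-trigger dictionary."""
    if len(triggers) == 0:
        raise ValueError("trigger lexicon is empty")
    selected = _select_longest(_dictionary_candidates(sentence, triggers))
    return [
        TriggerMention(sentence, m.start, m.end, m.tok_first, m.tok_last, m.surface)
        for m in sorted(selected, key=lambda m: (m.start, m.end))
    ]


def extract_mentions(
    sentence: Sentence, entity_lexicon: Lexicon, trigger_lexicon: Lexicon
) -> tuple[list[EntityMention], list[TriggerMention]]:
    """Combined entity tagging (dictionary + regexes, joint longest-match,
    descriptor exception) and trigger tagging for one sentence."""
    cands = (
        _dictionary_candidates(sentence, entity_lexicon)
        + match_distance(sentence)
        + match_segment(sentence)
    )
    entities = _descriptor_exception(_select_longest(cands), sentence, entity_lexicon)
    return entities, tag_triggers(sentence, trigger_lexicon)


def generate_pairs(
    triggers: list[TriggerMention], entities: list[EntityMention]
) -> list[CandidatePair]:
    """Cross product of triggers and entities minus overlapping pairs."""
    pairs = []
    for trig in sorted(triggers, key=lambda t: t.start):
        for ent in sorted(entities, key=lambda e: e.start):
            if _overlaps(trig.span, ent.span):
                continue
            if ent.tok_first > trig.tok_last:
                gap = ent.tok_first - trig.tok_last - 1
                side = "right"
            else:
                gap = trig.tok_first - ent.tok_last - 1
                side = "left"
            pairs.append(CandidatePair(trig, ent, gap, side))
    return pairs


@dataclass
class TaggedSentence:
    """One sentence with its mentions and candidate pairs."""

    sentence: Sentence
    entities: list[EntityMention]
    triggers: list[TriggerMention]
    pairs: list[CandidatePair]


def tag_sentence(
    sentence: Sentence, entity_lexicon: Lexicon, trigger_lexicon: Lexicon
) -> TaggedSentence:
    entities, triggers = extract_mentions(sentence, entity_lexicon, trigger_lexicon)
    return TaggedSentence(sentence, entities, triggers, generate_pairs(triggers, entities))


# -- I/O -------------------------------------------------------------------


def read_sentences_jsonl(path: str | Path) -> list[Sentence]:
    """One record per line: {"doc_id", "sent_id", "text"}."""
    sentences = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        sentences.append(tokenize(rec["text"], rec.get("doc_id", "doc"), int(rec.get("sent_id", 0))))
    return sentences


def read_sentences_text(path: str | Path) -> list[Sentence]:
    """Plain text, one sentence per line; doc id from the filename."""
    path = Path(path)
    return [
        tokenize(line, path.stem, i)
        for i, line in enumerate(path.read_text().splitlines())
        if line.strip()
    ]


def tagged_to_standoff(tagged: TaggedSentence) -> dict:
    ent_index = {e: i for i, e in enumerate(tagged.entities)}
    trig_index = {t: i for i, t in enumerate(tagged.triggers)}
    return {
        "doc_id": tagged.sentence.doc_id,
        "sent_id": tagged.sentence.sent_id,
        "text": tagged.sentence.text,
        "entities": [
            {
                "start": e.start,
                "end": e.end,
                "surface": e.surface,
                "categories": sorted(e.categories),
                "matcher": e.matcher,
            }
            for e in tagged.entities
        ],
        "triggers": [
            {"start": t.start, "end": t.end, "surface": t.surface} for t in tagged.triggers
        ],
        "pairs": [
            {
                "trigger_idx": trig_index[p.trigger],
                "entity_idx": ent_index[p.entity],
                "token_gap": p.token_gap,
                "side": p.entity_side,
            }
            for p in tagged.pairs
        ],
    }


def write_standoff(tagged_sentences: Iterable[TaggedSentence], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([tagged_to_standoff(t) for t in tagged_sentences], indent=1)
    )
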