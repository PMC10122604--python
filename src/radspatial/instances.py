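"""Trigger-level instances, weak-label filtering, and BIO sequences.

Probabilistically labeled pairs are regrouped per spatial trigger: each
entity span is recorded under its argmax frame-element label with its
posterior probability.  Two filters then clean the weak training set — the
Figure+Ground constraint (a spatial frame needs both fundamental elements;
in evaluation mode only Ground is required, raising trigger recall) and a
frequent-phrase blocklist around common triggers ("history of" is not a
spatial "of").  Surviving instances are rendered as BIO tag sequences with
every trigger token replaced by the mask symbol ``$sptrg$``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .candidates import CandidatePair, Sentence, TriggerMention
from .labelmodel import ProbabilisticLabel
from .lfs import FELabel

TRIGGER_MASK = "$sptrg$"

BIO_TAGS = ["O"] + [f"{p}-{lab.name}" for lab in FELabel for p in ("B", "I")]


class ContractError(ValueError):
    pass


@dataclass
class TriggerInstance:
    sentence: Sentence
    trigger: TriggerMention
    fe_spans: dict[FELabel, list[tuple[int, int, float]]] = field(default_factory=dict)
    provenance: str = "weak"  # weak | gold

    @property
    def key(self) -> tuple[str, int, int, int]:
        return (
            self.sentence.doc_id,
            self.sentence.sent_id,
            self.trigger.start,
            self.trigger.end,
        )


@dataclass
class FilterConfig:
    require_figure_ground: bool = True
    ground_only_mode: bool = False  # evaluation mode: only Ground required
    # trigger surface -> phrases that, directly left/right, mark a
    # non-spatial use of the trigger.  Repo-chosen defaults.
    frequent_phrases: dict[str, dict[str, list[str]]] = field(
        default_factory=lambda: {
            "of": {"left": ["history", "status", "complaints"], "right": []},
            "with": {"left": ["consistent", "compatible", "associated"], "right": []},
            "in": {"left": [], "right": ["place", "order"]},
        }
    )


@dataclass
class BioSequence:
    tokens: list[str]  # trigger tokens replaced by the mask symbol
    tags: list[str]
    instance: TriggerInstance | None = None

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ContractError("tokens and tags must have equal length")


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def build_instances(
    pairs: list[CandidatePair], labels: list[ProbabilisticLabel]
) -> list[TriggerInstance]:
    """Group non-abstained labeled pairs into one instance per trigger.

    Overlapping same-label spans keep the higher probability, then the
    longer span.
    """
    if len(pairs) != len(labels):
        raise ContractError("labels are not aligned to pairs")
    by_trigger: dict[tuple, TriggerInstance] = {}
    order: list[tuple] = []
    for pair, plab in zip(pairs, labels):
        if plab.abstained:
            continue
        key = (
            pair.sentence.doc_id,
            pair.sentence.sent_id,
            pair.trigger.start,
            pair.trigger.end,
        )
        if key not in by_trigger:
            by_trigger[key] = TriggerInstance(pair.sentence, pair.trigger)
            order.append(key)
        inst = by_trigger[key]
        label = plab.label
        span = (pair.entity.start, pair.entity.end, plab.prob)
        existing = inst.fe_spans.setdefault(label, [])
        clashing = [s for s in existing if _overlaps((s[0], s[1]), (span[0], span[1]))]
        if clashing:
            best = max(
                clashing + [span], key=lambda s: (s[2], s[1] - s[0])
            )
            inst.fe_spans[label] = [
                s for s in existing if s not in clashing
            ] + [best]
        else:
            existing.append(span)
    for inst in by_trigger.values():
        for label in inst.fe_spans:
            inst.fe_spans[label].sort()
    return [by_trigger[k] for k in order]


def filter_figure_ground(instance: TriggerInstance, cfg: FilterConfig) -> bool:
    """Frame completeness: Figure+Ground present (default), or Ground only
    (evaluation mode)."""
    if cfg.ground_only_mode:
        return bool(instance.fe_spans.get(FELabel.GROUND))
    return bool(instance.fe_spans.get(FELabel.FIGURE)) and bool(
        instance.fe_spans.get(FELabel.GROUND)
    )


def filter_frequent_phrases(instance: TriggerInstance, cfg: FilterConfig) -> bool:
    """Reject the instance when a configured frequent phrase sits directly
    left/right of the trigger (case-insensitive token match)."""
    phrases = cfg.frequent_phrases.get(instance.trigger.surface.lower())
    if not phrases:
        return True
    toks = instance.sentence.tokens
    for phrase in phrases.get("left", []):
        words = phrase.lower().split()
        lo = instance.trigger.tok_first - len(words)
        if lo >= 0 and [t.surface.lower() for t in toks[lo : instance.trigger.tok_first]] == words:
            return False
    for phrase in phrases.get("right", []):
        words = phrase.lower().split()
        hi = instance.trigger.tok_last + 1 + len(words)
        if hi <= len(toks) and [
            t.surface.lower() for t in toks[instance.trigger.tok_last + 1 : hi]
        ] == words:
            return False
    return True


def filter_instances(
    instances: Iterable[TriggerInstance], cfg: FilterConfig | None = None
) -> list[TriggerInstance]:
    cfg = cfg or FilterConfig()
    out = []
    for inst in instances:
        if cfg.require_figure_ground and not filter_figure_ground(inst, cfg):
            continue
        if not filter_frequent_phrases(inst, cfg):
            continue
        out.append(inst)
    return out


def to_bio(instance: TriggerInstance) -> BioSequence:
    """Render one instance as a masked BIO token sequence.

    Cross-label span overlaps resolve by higher probability, then label
    order; spans must be token-aligned.
    """
    sent = instance.sentence
    flat = [
        (label, s, e, p)
        for label, spans in instance.fe_spans.items()
        for (s, e, p) in spans
    ]
    flat.sort(key=lambda x: (-x[3], x[0], x[1]))
    kept: list[tuple[FELabel, int, int, float]] = []
    for cand in flat:
        if not any(_overlaps((cand[1], cand[2]), (k[1], k[2])) for k in kept):
            kept.append(cand)

    tokens = []
    tags = ["O"] * len(sent.tokens)
    for i, tok in enumerate(sent.tokens):
        if instance.trigger.tok_first <= i <= instance.trigger.tok_last:
            tokens.append(TRIGGER_MASK)  # one mask token per original token
        else:
            tokens.append(tok.surface)
    for label, s, e, _ in kept:
        span = sent.token_span_for(s, e)
        if span is None:
            raise ContractError(
                f"span ({s},{e}) is not token-aligned in: {sent.text!r}"
            )
        first, last = span
        tags[first] = f"B-{label.name}"
        for i in range(first + 1, last + 1):
            tags[i] = f"I-{label.name}"
    # masked positions stay O
    for i in range(instance.trigger.tok_first, instance.trigger.tok_last + 1):
        tags[i] = "O"
    return BioSequence(tokens, tags, instance)


def is_valid_bio(tags: list[str]) -> bool:
    prev = "O"
    for tag in tags:
        if tag not in BIO_TAGS:
            return False
        if tag.startswith("I-"):
            lab = tag[2:]
            if prev not in (f"B-{lab}", f"I-{lab}"):
                return False
        prev = tag
    return True


def bio_to_spans(seq: BioSequence) -> list[tuple[FELabel, int, int]]:
    """Decode maximal B/I runs into (label, first_token, last_token)."""
    spans = []
    open_label, start = None, None
    for i, tag in enumerate(seq.tags + ["O"]):
        if tag.startswith("B-") or tag == "O" or (
            tag.startswith("I-") and tag[2:] != open_label
        ):
            if open_label is not None:
                spans.append((FELabel[open_label], start, i - 1))
                open_label = None
            if tag.startswith("B-") or tag.startswith("I-"):
                open_label, start = tag[2:], i
    return spans


# -- CoNLL-style I/O -------------------------------------------------------


def write_bio(sequences: Iterable[BioSequence], path: str | Path) -> None:
    blocks = []
    for seq in sequences:
        header = "# doc sent trigger_start trigger_end"
        if seq.instance is not None:
            inst = seq.instance
            header = (
                f"# {inst.sentence.doc_id} {inst.sentence.sent_id} "
                f"{inst.trigger.start} {inst.trigger.end}"
            )
        lines = [header] + [f"{tok}\t{tag}" for tok, tag in zip(seq.tokens, seq.tags)]
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n")


def read_bio(path: str | Path) -> list[BioSequence]:
    sequences = []
    tokens: list[str] = []
    tags: list[str] = []
    for line in Path(path).read_text().splitlines() + [""]:
        if not line.strip():
            if tokens:
                sequences.append(BioSequence(tokens, tags))
                tokens, tags = [], []
            continue
        if line.startswith("#"):
            continue
        tok, tag = line.split("\t")
        tokens.append(tok)
        tags.append(tag)
    return sequences
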