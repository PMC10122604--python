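"""Labeling functions: deterministic heuristics voting one of nine spatial
frame-element labels (or abstaining) for each {trigger, entity} candidate.

Each labeling function (LF) inspects a candidate pair in the context of its
sentence's full mention lists and either emits its single target label or
abstains.  The default registry holds 19 LFs covering all nine frame
elements; cue lists and window lengths live in :class:`LFConfig` so the
heuristics can be re-targeted to other reporting styles without code
changes.

Frame elements: Figure (the located finding/device), Ground (the anatomical
location), Hedge (uncertainty phrase), Diagnosis (differential suggested
after a hedge), PositionStatus (device position wording), RelativePosition
(orientation descriptor), Distance (measured offset), Reason (causal
condition), AssociatedProcess (activity linked to the relation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable

from .candidates import CandidatePair, EntityMention, Sentence, TaggedSentence, TriggerMention
from .lexicon import Lexicon


class FELabel(IntEnum):
    """The nine spatial frame elements.  Declaration order is the
    deterministic tie-break order used throughout."""

    FIGURE = 0
    GROUND = 1
    HEDGE = 2
    DIAGNOSIS = 3
    POSITION_STATUS = 4
    RELATIVE_POSITION = 5
    DISTANCE = 6
    REASON = 7
    ASSOCIATED_PROCESS = 8


ABSTAIN = -1

N_LABELS = len(FELabel)


@dataclass
class LFConfig:
    """Cue lists and window lengths shared by the labeling functions."""

    copula_triggers: list[str] = field(
        default_factory=lambda: [
            "with", "without", "show", "shows", "demonstrate", "demonstrates",
            "is", "are", "reveal", "reveals",
        ]
    )
    hedge_left_window: list[str] = field(
        default_factory=lambda: ["represent", "suggest", "indicat", "consistent with"]
    )
    hedge_right_window: list[str] = field(
        default_factory=lambda: ["ruled out", "excluded", "vs", "versus"]
    )
    window_len: int = 4
    ground_gap_max: int = 2
    reason_cues: list[str] = field(default_factory=lambda: ["due to", "secondary to", "from"])
    process_cues: list[str] = field(default_factory=lambda: ["during", "while"])
    hedge_prepositions: list[str] = field(default_factory=lambda: ["of", "for", "with", "to"])
    position_verbs: list[str] = field(
        default_factory=lambda: ["terminates", "tip", "positioned", "advanced"]
    )
    # verbal subset of the copulas: "with"/"without" are prepositional, so a
    # finding to their right is not that trigger's Figure
    verbal_copulas: list[str] = field(
        default_factory=lambda: [
            "is", "are", "show", "shows", "demonstrate", "demonstrates",
            "reveal", "reveals",
        ]
    )
    hedge_surface_cues: list[str] = field(
        default_factory=lambda: [
            "consistent with", "concerning for", "worrisome for", "suggestive of",
            "compatible with", "suspicious for", "may represent",
        ]
    )

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")


@dataclass
class LFContext:
    """Sentence-level context an LF may consult (all mentions, lexicon)."""

    sentence: Sentence
    entities: list[EntityMention]
    triggers: list[TriggerMention]
    lexicon: Lexicon
    cfg: LFConfig


VoteFn = Callable[[CandidatePair, LFContext], int]


@dataclass(frozen=True)
class LabelingFunction:
    name: str
    target_label: FELabel
    vote_fn: VoteFn

    def __call__(self, pair: CandidatePair, ctx: LFContext) -> int:
        vote = self.vote_fn(pair, ctx)
        if vote != ABSTAIN and vote != self.target_label:
            raise RuntimeError(
                f"LF {self.name} emitted {vote}, declared target {self.target_label}"
            )
        return vote


# -- window / context helpers ---------------------------------------------


def _left_window_text(ctx: LFContext, tok_first: int, k: int) -> str:
    toks = ctx.sentence.tokens[max(0, tok_first - k) : tok_first]
    return " ".join(t.surface.lower() for t in toks)


def _right_window_text(ctx: LFContext, tok_last: int, k: int) -> str:
    toks = ctx.sentence.tokens[tok_last + 1 : tok_last + 1 + k]
    return " ".join(t.surface.lower() for t in toks)


def _tokens_right_of(ctx: LFContext, tok_last: int) -> list[str]:
    return [t.surface for t in ctx.sentence.tokens[tok_last + 1 :]]


def _mention_gap(a, b) -> int:
    """Tokens strictly between two mentions (0 if adjacent/overlapping)."""
    if b.tok_first > a.tok_last:
        return b.tok_first - a.tok_last - 1
    if a.tok_first > b.tok_last:
        return a.tok_first - b.tok_last - 1
    return 0


def _is_copula(trigger: TriggerMention, cfg: LFConfig) -> bool:
    return trigger.surface.lower() in cfg.copula_triggers


def _triggers_between(ctx: LFContext, left_end_tok: int, right_start_tok: int,
                      exclude: TriggerMention, skip_copula: bool = False) -> list[TriggerMention]:
    found = []
    for t in ctx.triggers:
        if t == exclude:
            continue
        if t.tok_first > left_end_tok and t.tok_last < right_start_tok:
            if skip_copula and _is_copula(t, ctx.cfg):
                continue
            found.append(t)
    return found


def _hedge_mentions(ctx: LFContext) -> list[EntityMention]:
    return [
        e
        for e in ctx.entities
        if e.categories & {"hedge", "certainty_descriptor"}
    ]


def _contains_preposition(mention: EntityMention, cfg: LFConfig) -> bool:
    words = mention.surface.lower().split()
    return any(p in words for p in cfg.hedge_prepositions)


def _sentence_final(ctx: LFContext, entity: EntityMention) -> bool:
    """True iff the only token right of the entity is '.'."""
    return _tokens_right_of(ctx, entity.tok_last) == ["."]


def _span_between(ctx: LFContext, pair: CandidatePair):
    """Token index range strictly between trigger and entity (lo, hi)."""
    if pair.entity_side == "right":
        return pair.trigger.tok_last, pair.entity.tok_first
    return pair.entity.tok_last, pair.trigger.tok_first


# -- Ground ---------------------------------------------------------------


def lf_ground_adjacency(pair: CandidatePair, ctx: LFContext) -> int:
    """Copula triggers take their Ground as the anatomy immediately to the
    left; other triggers take a nearby anatomy on the right."""
    cfg = ctx.cfg
    if _is_copula(pair.trigger, cfg):
        if (
            pair.entity_side == "left"
            and pair.token_gap == 0
            and "anatomy" in pair.entity.categories
        ):
            return FELabel.GROUND
        return ABSTAIN
    if (
        pair.entity_side == "right"
        and pair.token_gap <= cfg.ground_gap_max
        and "anatomy" in pair.entity.categories
    ):
        return FELabel.GROUND
    return ABSTAIN


def lf_ground_closest(pair: CandidatePair, ctx: LFContext) -> int:
    """Anatomy to the right of the trigger with no other trigger between."""
    if pair.entity_side != "right" or "anatomy" not in pair.entity.categories:
        return ABSTAIN
    if pair.token_gap == 0:
        return FELabel.GROUND
    lo, hi = pair.trigger.tok_last, pair.entity.tok_first
    if not _triggers_between(ctx, lo, hi, exclude=pair.trigger):
        return FELabel.GROUND
    return ABSTAIN


def lf_ground_colon_heading(pair: CandidatePair, ctx: LFContext) -> int:
    """'location: finding' style — anatomy heading directly before a colon
    with the trigger anywhere to the right of that colon."""
    if "anatomy" not in pair.entity.categories or pair.entity_side != "left":
        return ABSTAIN
    colon_idx = pair.entity.tok_last + 1
    toks = ctx.sentence.tokens
    if colon_idx < len(toks) and toks[colon_idx].surface == ":":
        if pair.trigger.tok_first > colon_idx:
            return FELabel.GROUND
    return ABSTAIN


# -- Diagnosis ------------------------------------------------------------


def lf_diagnosis_sentence_final(pair: CandidatePair, ctx: LFContext) -> int:
    """Sentence-final finding introduced by a hedge (either a
    preposition-bearing hedge between trigger and entity, or any hedge in
    the left window with no further trigger in between)."""
    cfg = ctx.cfg
    ent = pair.entity
    if "finding" not in ent.categories or not _sentence_final(ctx, ent):
        return ABSTAIN
    lo, hi = _span_between(ctx, pair)
    for h in _hedge_mentions(ctx):
        if h.tok_first > lo and h.tok_last < hi and _contains_preposition(h, cfg):
            return FELabel.DIAGNOSIS
    for h in _hedge_mentions(ctx):
        gap_left = ent.tok_first - h.tok_last - 1
        if h.tok_last < ent.tok_first and gap_left < cfg.window_len:
            if not _triggers_between(ctx, lo, hi, exclude=pair.trigger):
                return FELabel.DIAGNOSIS
    return ABSTAIN


def lf_diagnosis_hedge_window(pair: CandidatePair, ctx: LFContext) -> int:
    """Finding with a hedge cue in its 4-token left or right window
    (substring match, so "indicat" hits "indicating")."""
    cfg = ctx.cfg
    ent = pair.entity
    if "finding" not in ent.categories:
        return ABSTAIN
    left = _left_window_text(ctx, ent.tok_first, cfg.window_len)
    if any(cue in left for cue in cfg.hedge_left_window):
        return FELabel.DIAGNOSIS
    right = _right_window_text(ctx, ent.tok_last, cfg.window_len)
    if any(cue in right for cue in cfg.hedge_right_window):
        return FELabel.DIAGNOSIS
    return ABSTAIN


# -- Figure ---------------------------------------------------------------


def lf_figure_left_of_trigger(pair: CandidatePair, ctx: LFContext) -> int:
    """Finding/device shortly left of the trigger with no intervening
    non-copula trigger (bare copulas sit between Figure and trigger in
    ordinary report syntax: "ETT tube is 1 cm above the carina")."""
    cfg = ctx.cfg
    if pair.entity_side != "left" or pair.token_gap >= cfg.window_len:
        return ABSTAIN
    if not pair.entity.categories & {"finding", "device"}:
        return ABSTAIN
    lo, hi = pair.entity.tok_last, pair.trigger.tok_first
    if _triggers_between(ctx, lo, hi, exclude=pair.trigger, skip_copula=True):
        return ABSTAIN
    return FELabel.FIGURE


def lf_figure_after_copula(pair: CandidatePair, ctx: LFContext) -> int:
    """Finding/device immediately right of a verbal copula trigger."""
    if (
        pair.trigger.surface.lower() in ctx.cfg.verbal_copulas
        and pair.entity_side == "right"
        and pair.token_gap == 0
        and pair.entity.categories & {"finding", "device"}
    ):
        return FELabel.FIGURE
    return ABSTAIN


def lf_figure_chained_anatomy(pair: CandidatePair, ctx: LFContext) -> int:
    """Chained frames: an anatomy left-adjacent to a non-copula trigger,
    with an earlier trigger in the sentence, is the Figure of the second
    frame ("opacity in the lingula extending to the pleura")."""
    if (
        pair.entity_side == "left"
        and pair.token_gap == 0
        and "anatomy" in pair.entity.categories
        and not _is_copula(pair.trigger, ctx.cfg)
        and any(t.tok_last < pair.entity.tok_first for t in ctx.triggers if t != pair.trigger)
    ):
        return FELabel.FIGURE
    return ABSTAIN


# -- Hedge ----------------------------------------------------------------


def lf_hedge_category(pair: CandidatePair, ctx: LFContext) -> int:
    """Hedge/certainty-descriptor entity near the trigger or a finding."""
    cfg = ctx.cfg
    ent = pair.entity
    if not ent.categories & {"hedge", "certainty_descriptor"}:
        return ABSTAIN
    if _mention_gap(ent, pair.trigger) <= cfg.window_len:
        return FELabel.HEDGE
    for other in ctx.entities:
        if other is not ent and "finding" in other.categories:
            if _mention_gap(ent, other) <= cfg.window_len:
                return FELabel.HEDGE
    return ABSTAIN


def lf_hedge_cue_surface(pair: CandidatePair, ctx: LFContext) -> int:
    """Entity surface itself is a known hedging phrase."""
    surface = pair.entity.surface.lower()
    if any(cue in surface for cue in ctx.cfg.hedge_surface_cues):
        return FELabel.HEDGE
    return ABSTAIN


# -- Distance -------------------------------------------------------------


def lf_distance_regex(pair: CandidatePair, ctx: LFContext) -> int:
    """Measurement match shortly left of the trigger ("1 cm above")."""
    if (
        pair.entity.matcher == "distance_regex"
        and pair.entity_side == "left"
        and pair.token_gap < ctx.cfg.window_len
    ):
        return FELabel.DISTANCE
    return ABSTAIN


# -- RelativePosition -----------------------------------------------------


def lf_relpos_window(pair: CandidatePair, ctx: LFContext) -> int:
    """Orientation descriptor within the trigger's window."""
    if (
        pair.entity.categories & {"relative_position", "location_descriptor"}
        and pair.token_gap <= ctx.cfg.window_len
    ):
        return FELabel.RELATIVE_POSITION
    return ABSTAIN


def lf_relpos_descriptor_split(pair: CandidatePair, ctx: LFContext) -> int:
    """Location descriptor directly preceding an anatomy mention (the
    descriptor-exception split, e.g. "inferior" + "cerebellar peduncle")."""
    ent = pair.entity
    if "location_descriptor" not in ent.categories:
        return ABSTAIN
    for other in ctx.entities:
        if "anatomy" in other.categories and other.tok_first == ent.tok_last + 1:
            return FELabel.RELATIVE_POSITION
    return ABSTAIN


# -- PositionStatus -------------------------------------------------------


def lf_posstatus_device(pair: CandidatePair, ctx: LFContext) -> int:
    """Position-status wording left of the trigger in a device sentence."""
    cfg = ctx.cfg
    if (
        "position_status" in pair.entity.categories
        and pair.entity_side == "left"
        and pair.token_gap < cfg.window_len
        and any("device" in e.categories for e in ctx.entities)
    ):
        return FELabel.POSITION_STATUS
    return ABSTAIN


def lf_posstatus_verb(pair: CandidatePair, ctx: LFContext) -> int:
    """Device position verb family near the trigger."""
    cfg = ctx.cfg
    if (
        pair.entity.surface.lower() in cfg.position_verbs
        and _mention_gap(pair.entity, pair.trigger) <= cfg.window_len
    ):
        return FELabel.POSITION_STATUS
    return ABSTAIN


# -- Reason ---------------------------------------------------------------


def lf_reason_cue(pair: CandidatePair, ctx: LFContext) -> int:
    """Finding preceded by a causal cue ("due to", "secondary to")."""
    cfg = ctx.cfg
    ent = pair.entity
    if "finding" not in ent.categories:
        return ABSTAIN
    left = _left_window_text(ctx, ent.tok_first, cfg.window_len)
    if any(cue in left for cue in cfg.reason_cues):
        return FELabel.REASON
    return ABSTAIN


def lf_reason_sentence_final(pair: CandidatePair, ctx: LFContext) -> int:
    """Sentence-final finding after a causal cue with no hedge mention
    between trigger and entity."""
    cfg = ctx.cfg
    ent = pair.entity
    if "finding" not in ent.categories or not _sentence_final(ctx, ent):
        return ABSTAIN
    lo, hi = _span_between(ctx, pair)
    between = " ".join(
        t.surface.lower() for t in ctx.sentence.tokens[lo + 1 : hi]
    )
    if not any(cue in between for cue in cfg.reason_cues):
        return ABSTAIN
    for h in _hedge_mentions(ctx):
        if h.tok_first > lo and h.tok_last < hi:
            return ABSTAIN
    return FELabel.REASON


# -- AssociatedProcess ----------------------------------------------------


def _cue_token_indices(ctx: LFContext, cues: list[str]) -> list[int]:
    return [
        i
        for i, t in enumerate(ctx.sentence.tokens)
        if t.surface.lower() in cues
    ]


def lf_process_clause(pair: CandidatePair, ctx: LFContext) -> int:
    """Process entity inside a clause opened by "during"/"while" (no comma
    between the cue and the entity)."""
    ent = pair.entity
    if "process" not in ent.categories:
        return ABSTAIN
    toks = ctx.sentence.tokens
    for i in _cue_token_indices(ctx, ctx.cfg.process_cues):
        if i < ent.tok_first and not any(
            toks[j].surface == "," for j in range(i + 1, ent.tok_first)
        ):
            return FELabel.ASSOCIATED_PROCESS
    return ABSTAIN


def lf_process_during_prefix(pair: CandidatePair, ctx: LFContext) -> int:
    """Process entity directly prefixed by a process cue (allowing an
    article: "During the movement of the right foot")."""
    ent = pair.entity
    if "process" not in ent.categories:
        return ABSTAIN
    for i in _cue_token_indices(ctx, ctx.cfg.process_cues):
        if 1 <= ent.tok_first - i <= 2:
            return FELabel.ASSOCIATED_PROCESS
    return ABSTAIN


# -- registry & application -----------------------------------------------


def default_registry() -> list[LabelingFunction]:
    """The 19 default labeling functions, in registration order."""
    return [
        LabelingFunction("ground_adjacency", FELabel.GROUND, lf_ground_adjacency),
        LabelingFunction("ground_closest", FELabel.GROUND, lf_ground_closest),
        LabelingFunction("ground_colon_heading", FELabel.GROUND, lf_ground_colon_heading),
        LabelingFunction("diagnosis_sentence_final", FELabel.DIAGNOSIS, lf_diagnosis_sentence_final),
        LabelingFunction("diagnosis_hedge_window", FELabel.DIAGNOSIS, lf_diagnosis_hedge_window),
        LabelingFunction("figure_left_of_trigger", FELabel.FIGURE, lf_figure_left_of_trigger),
        LabelingFunction("figure_after_copula", FELabel.FIGURE, lf_figure_after_copula),
        LabelingFunction("figure_chained_anatomy", FELabel.FIGURE, lf_figure_chained_anatomy),
        LabelingFunction("hedge_category", FELabel.HEDGE, lf_hedge_category),
        LabelingFunction("hedge_cue_surface", FELabel.HEDGE, lf_hedge_cue_surface),
        LabelingFunction("distance_regex", FELabel.DISTANCE, lf_distance_regex),
        LabelingFunction("relpos_window", FELabel.RELATIVE_POSITION, lf_relpos_window),
        LabelingFunction("relpos_descriptor_split", FELabel.RELATIVE_POSITION, lf_relpos_descriptor_split),
        LabelingFunction("posstatus_device", FELabel.POSITION_STATUS, lf_posstatus_device),
        LabelingFunction("posstatus_verb", FELabel.POSITION_STATUS, lf_posstatus_verb),
        LabelingFunction("reason_cue", FELabel.REASON, lf_reason_cue),
        LabelingFunction("reason_sentence_final", FELabel.REASON, lf_reason_sentence_final),
        LabelingFunction("process_clause", FELabel.ASSOCIATED_PROCESS, lf_process_clause),
        LabelingFunction("process_during_prefix", FELabel.ASSOCIATED_PROCESS, lf_process_during_prefix),
    ]


def apply_lfs(
    tagged_sentences: list[TaggedSentence],
    registry: list[LabelingFunction],
    lexicon: Lexicon,
    cfg: LFConfig | None = None,
):
    """Apply every LF to every candidate pair; returns a VoteMatrix.

    Column order is registration order; cell (i, j) is LF j's vote on
    pair i (label value, or -1 for abstain).
    """
    from .labelmodel import VoteMatrix  # local import to avoid a cycle

    if not registry:
        raise ValueError("empty LF registry")
    names = [lf.name for lf in registry]
    if len(set(names)) != len(names):
        raise ValueError("duplicate LF names in registry")
    cfg = cfg or LFConfig()

    pairs: list[CandidatePair] = []
    votes: list[list[int]] = []
    for ts in tagged_sentences:
        ctx = LFContext(ts.sentence, ts.entities, ts.triggers, lexicon, cfg)
        for pair in ts.pairs:
            pairs.append(pair)
            votes.append([lf(pair, ctx) for lf in registry])
    import numpy as np

    mat = np.array(votes, dtype=np.int8).reshape(len(pairs), len(registry))
    return VoteMatrix(
        votes=mat,
        lf_names=names,
        target_labels=[lf.target_label for lf in registry],
        pair_refs=pairs,
    )
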