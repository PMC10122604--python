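"""Synthetic radiology-like sentences with gold spatial frames.

A template grammar emulates the common reporting styles — "finding in
location", the "location: finding" heading style, device position
statements, hedged differential diagnoses, measured distances, causal
attributions and associated processes — over the packaged vocabulary, and
records gold spans exactly.  It is the test harness standing in for real
report corpora: within-distribution for the default labeling functions by
design, with a misspelling corruptor to stress dictionary coverage.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .candidates import Sentence, tokenize
from .lexicon import Lexicon, default_entity_lexicon
from .lfs import FELabel

STYLES = (
    "finding_in_location",
    "location_colon_finding",
    "device_position",
    "hedge_diagnosis",
    "distance",
    "reason",
    "process",
)

DEFAULT_STYLE_MIX = {
    "finding_in_location": 0.25,
    "location_colon_finding": 0.10,
    "device_position": 0.15,
    "hedge_diagnosis": 0.20,
    "distance": 0.10,
    "reason": 0.10,
    "process": 0.10,
}

_MODIFIERS = ["hazy", "subtle", "patchy", "scattered", "stable", "small", "focal"]


@dataclass
class SynthConfig:
    n_sentences: int = 100
    seed: int = 0
    style_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STYLE_MIX))
    misspell_rate: float = 0.0
    distractor_rate: float = 0.25
    vocab: Lexicon | None = None  # defaults to the packaged lexicon

    def __post_init__(self) -> None:
        total = sum(self.style_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"style mix proportions sum to {total}, not 1")
        if not 0 <= self.misspell_rate <= 0.3:
            raise ValueError("misspell_rate must lie in [0, 0.3]")
        if not 0 <= self.distractor_rate <= 1:
            raise ValueError("distractor_rate out of range")


@dataclass
class GoldFrame:
    sentence: Sentence
    trigger_span: tuple[int, int]
    fe_spans: dict[FELabel, list[tuple[int, int]]]

    @property
    def key(self) -> tuple[str, int, int, int]:
        return (
            self.sentence.doc_id,
            self.sentence.sent_id,
            self.trigger_span[0],
            self.trigger_span[1],
        )


class _Builder:
    """Accumulates sentence parts while tracking role spans."""

    def __init__(self) -> None:
        self.text = ""
        self.trigger: tuple[int, int] | None = None
        self.fe: dict[FELabel, list[tuple[int, int]]] = {}

    def add(self, part: str, role: FELabel | str | None = None, glue: bool = False) -> None:
        if self.text and not glue:
            self.text += " "
        start = len(self.text)
        self.text += part
        span = (start, len(self.text))
        if role == "trigger":
            self.trigger = span
        elif isinstance(role, FELabel):
            self.fe.setdefault(role, []).append(span)


def _pool(vocab: Lexicon, category: str, max_words: int = 2) -> list[str]:
    """Sorted sampling pool of base/manual surfaces of one category, kept
    template-safe: no embedded "of", and anatomy never starts with a
    location descriptor (avoids the descriptor-exception split)."""
    out = []
    for entry in vocab.entries:
        if entry.category != category or entry.source not in ("base", "manual"):
            continue
        words = entry.surface.split()
        if len(words) > max_words or "of" in words:
            continue
        if category == "anatomy" and "location_descriptor" in vocab.lookup(words[0]):
            continue
        out.append(entry.surface)
    return sorted(set(out))


def generate(config: SynthConfig) -> list[tuple[Sentence, list[GoldFrame]]]:
    """Sample sentences per the style mix; reproducible by seed."""
    vocab = config.vocab or default_entity_lexicon()
    rng = random.Random(config.seed)

    findings = _pool(vocab, "finding")
    anatomies = _pool(vocab, "anatomy")
    devices = _pool(vocab, "device")
    processes = _pool(vocab, "process")
    hedges = [
        h
        for h in _pool(vocab, "hedge", max_words=2)
        if set(h.split()) & {"of", "for", "with"} or h == "concerning for"
    ]
    relpos = _pool(vocab, "relative_position") + [
        w for w in ("left", "right", "upper", "lower") if w in vocab
    ]
    missing = [
        name
        for name, pool in [
            ("finding", findings),
            ("anatomy", anatomies),
            ("device", devices),
            ("process", processes),
            ("hedge", hedges),
            ("relative_position", relpos),
        ]
        if not pool
    ]
    if missing:
        raise ValueError(f"vocabulary lacks required categories: {missing}")

    preps = ["in", "within", "at"]
    dir_preps = ["above", "below"]
    styles = list(config.style_mix)
    weights = [config.style_mix[s] for s in styles]

    corpus = []
    for i in range(config.n_sentences):
        style = rng.choices(styles, weights=weights)[0]
        b = _Builder()
        finding = rng.choice(findings)
        anatomy = rng.choice(anatomies)

        def add_figure_finding() -> None:
            if rng.random() < config.distractor_rate:
                b.add(rng.choice(_MODIFIERS))
            b.add(finding, FELabel.FIGURE)

        if style == "finding_in_location":
            b.add("There is")
            add_figure_finding()
            b.add(rng.choice(preps + ["of"]), "trigger")
            b.add("the")
            if rng.random() < 0.4:
                b.add(rng.choice(relpos), FELabel.RELATIVE_POSITION)
            b.add(anatomy, FELabel.GROUND)
        elif style == "location_colon_finding":
            b.add(anatomy, FELabel.GROUND)
            b.add(":", glue=True)
            b.add("There")
            b.add("are", "trigger")
            b.add(finding, FELabel.FIGURE)
        elif style == "device_position":
            device = rng.choice(devices)
            b.add("The")
            b.add(device, FELabel.FIGURE)
            variant = rng.random()
            if variant < 0.4:
                b.add("terminates", FELabel.POSITION_STATUS)
            elif variant < 0.7:
                b.add("is")
                b.add(rng.choice(["positioned", "placed", "advanced"]), FELabel.POSITION_STATUS)
            else:
                b.add("tip", FELabel.POSITION_STATUS)
                b.add("is")
                b.add(rng.choice(relpos), FELabel.RELATIVE_POSITION)
            b.add(rng.choice(preps[:2]), "trigger")
            b.add("the")
            b.add(anatomy, FELabel.GROUND)
        elif style == "hedge_diagnosis":
            diagnosis = rng.choice([f for f in findings if f != finding] or findings)
            b.add("There is")
            add_figure_finding()
            b.add(rng.choice(preps), "trigger")
            b.add("the")
            b.add(anatomy, FELabel.GROUND)
            b.add(rng.choice(hedges), FELabel.HEDGE)
            b.add(diagnosis, FELabel.DIAGNOSIS)
        elif style == "distance":
            device = rng.choice(devices)
            b.add("The")
            b.add(device, FELabel.FIGURE)
            b.add("is")
            value = rng.choice(["1", "2", "3", "4", "1.5", "2.5"])
            unit = rng.choice(["cm", "mm"])
            b.add(f"{value} {unit}", FELabel.DISTANCE)
            b.add(rng.choice(dir_preps), "trigger")
            b.add("the")
            b.add(anatomy, FELabel.GROUND)
        elif style == "reason":
            cause = rng.choice([f for f in findings if f != finding] or findings)
            b.add("There is")
            add_figure_finding()
            b.add(rng.choice(preps), "trigger")
            b.add("the")
            b.add(anatomy, FELabel.GROUND)
            b.add("due to")
            b.add(cause, FELabel.REASON)
        elif style == "process":
            process = rng.choice(processes)
            b.add("During the")
            b.add(process, FELabel.ASSOCIATED_PROCESS)
            b.add(",", glue=True)
            b.add("there is")
            add_figure_finding()
            b.add(rng.choice(preps), "trigger")
            b.add("the")
            b.add(anatomy, FELabel.GROUND)
        b.add(".", glue=True)

        text = b.text[0].upper() + b.text[1:]
        sentence = tokenize(text, doc_id="synth", sent_id=i)
        frame = GoldFrame(sentence, b.trigger, b.fe)
        if config.misspell_rate > 0:
            protected = [b.trigger] + [s for spans in b.fe.values() for s in spans]
            sentence, mapping = _corrupt_tokens(
                sentence, config.misspell_rate, rng, protected
            )
            frame = GoldFrame(
                sentence,
                (mapping[b.trigger[0]], mapping[b.trigger[1]]),
                {
                    lab: [(mapping[s], mapping[e]) for (s, e) in spans]
                    for lab, spans in b.fe.items()
                },
            )
        corpus.append((sentence, [frame]))
    return corpus


def _char_edit(word: str, rng: random.Random) -> str:
    if len(word) < 2:
        return word + word  # duplicate
    i = rng.randrange(len(word) - 1)
    op = rng.choice(("swap", "drop", "duplicate"))
    if op == "swap":
        return word[:i] + word[i + 1] + word[i] + word[i + 2 :]
    if op == "drop":
        return word[:i] + word[i + 1 :]
    return word[:i] + word[i] + word[i:]


def _corrupt_tokens(
    sentence: Sentence,
    rate: float,
    rng: random.Random,
    protected: list[tuple[int, int]],
) -> tuple[Sentence, dict[int, int]]:
    """Token-level misspelling; protected spans untouched.  Returns the new
    sentence plus an old-offset -> new-offset map for span boundaries."""

    def is_protected(tok) -> bool:
        return any(tok.start < e and s < tok.end for (s, e) in protected)

    mapping: dict[int, int] = {0: 0}
    pieces = []
    cursor_old = 0
    cursor_new = 0
    for tok in sentence.tokens:
        gap = sentence.text[cursor_old : tok.start]
        pieces.append(gap)
        cursor_new += len(gap)
        mapping[tok.start] = cursor_new
        surface = tok.surface
        if not is_protected(tok) and surface.isalpha() and rng.random() < rate:
            surface = _char_edit(surface, rng)
        pieces.append(surface)
        cursor_old = tok.end
        cursor_new += len(surface)
        mapping[tok.end] = cursor_new
    pieces.append(sentence.text[cursor_old:])
    new_text = "".join(pieces)
    return tokenize(new_text, sentence.doc_id, sentence.sent_id), mapping


def corrupt(sentence: Sentence, rate: float, seed: int,
            protected: list[tuple[int, int]] | None = None) -> Sentence:
    """Misspell non-protected alphabetic tokens at ``rate`` (deterministic
    per seed); rate 0 is the identity."""
    if not 0 <= rate <= 0.3:
        raise ValueError("rate must lie in [0, 0.3]")
    if rate == 0:
        return sentence
    new_sentence, _ = _corrupt_tokens(
        sentence, rate, random.Random(seed), protected or []
    )
    return new_sentence
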