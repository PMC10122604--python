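"""Sequence tagger over masked BIO data.

The shipped backend is an averaged perceptron: a per-token multiclass
classifier over sparse window features with BIO-transition-constrained
greedy decoding.  It trains in seconds on one CPU and is bit-for-bit
reproducible given a seed and input order.  A transformer backend is
specified only as an adapter contract (same train/predict signatures over
the same BIO files); plugging one in is the caller's responsibility.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .candidates import Sentence
from .instances import BIO_TAGS, TRIGGER_MASK, BioSequence, bio_to_spans, is_valid_bio
from .lexicon import Lexicon
from .lfs import FELabel

_TAG_INDEX = {t: i for i, t in enumerate(BIO_TAGS)}


@dataclass
class TaggerConfig:
    backend: str = "baseline"
    max_seq_len: int = 128
    epochs: int = 5  # baseline; a transformer adapter would use 4
    learning_rate: float = 2e-5  # transformer adapter only
    seed: int = 0


def _shape(tok: str) -> str:
    out = []
    for ch in tok:
        if ch.isupper():
            out.append("X")
        elif ch.islower():
            out.append("x")
        elif ch.isdigit():
            out.append("9")
        else:
            out.append(ch)
    shape = "".join(out)
    return shape[:4] + "~" if len(shape) > 4 else shape


def _token_features(
    tokens: list[str], i: int, mask_positions: list[int], lexicon: Lexicon | None
) -> list[str]:
    w = tokens[i]
    feats = [
        "bias",
        f"w={w.lower()}",
        f"shape={_shape(w)}",
        f"suf3={w.lower()[-3:]}",
        f"pre2={w.lower()[:2]}",
        f"ismask={w == TRIGGER_MASK}",
    ]
    if mask_positions:
        nearest = min(mask_positions, key=lambda p: abs(i - p))
        delta = max(-5, min(5, i - nearest))
        feats.append(f"maskdist={delta}")
    for off in (-2, -1, 1, 2):
        j = i + off
        tok = tokens[j].lower() if 0 <= j < len(tokens) else "<pad>"
        feats.append(f"w[{off}]={tok}")
    if lexicon is not None and w != TRIGGER_MASK:
        for cat in sorted(lexicon.lookup(w)):
            feats.append(f"lexcat={cat}")
    return feats


@dataclass
class TrainedTagger:
    backend: str
    weights: dict[str, list[float]]  # feature -> per-tag weight vector
    tag_inventory: list[str]
    config: TaggerConfig
    truncation_warnings: list[str] = field(default_factory=list)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "backend": self.backend,
                    "tag_inventory": self.tag_inventory,
                    "config": self.config.__dict__,
                    "weights": self.weights,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedTagger":
        payload = json.loads(Path(path).read_text())
        return cls(
            backend=payload["backend"],
            weights=payload["weights"],
            tag_inventory=payload["tag_inventory"],
            config=TaggerConfig(**payload["config"]),
        )


def _constrained_argmax(scores: list[float], prev_tag: str) -> int:
    """Highest-scoring tag whose I- continuation is licensed by prev_tag."""
    best, best_score = 0, None
    for idx, tag in enumerate(BIO_TAGS):
        if tag.startswith("I-"):
            lab = tag[2:]
            if prev_tag not in (f"B-{lab}", f"I-{lab}"):
                continue
        if best_score is None or scores[idx] > best_score:
            best, best_score = idx, scores[idx]
    return best


class _Perceptron:
    """Averaged perceptron with lazy averaging."""

    def __init__(self, n_tags: int):
        self.n_tags = n_tags
        self.w: dict[str, list[float]] = {}
        self._totals: dict[str, list[float]] = {}
        self._stamps: dict[str, list[int]] = {}
        self._t = 0

    def scores(self, feats: list[str]) -> list[float]:
        s = [0.0] * self.n_tags
        for f in feats:
            vec = self.w.get(f)
            if vec:
                for k in range(self.n_tags):
                    s[k] += vec[k]
        return s

    def update(self, feats: list[str], gold: int, pred: int) -> None:
        self._t += 1
        if gold == pred:
            return
        for f in feats:
            self._tick(f)
            self.w[f][gold] += 1.0
            self.w[f][pred] -= 1.0

    def _tick(self, f: str) -> None:
        if f not in self.w:
            self.w[f] = [0.0] * self.n_tags
            self._totals[f] = [0.0] * self.n_tags
            self._stamps[f] = [self._t] * self.n_tags
            return
        for k in range(self.n_tags):
            self._totals[f][k] += (self._t - self._stamps[f][k]) * self.w[f][k]
            self._stamps[f][k] = self._t

    def averaged(self) -> dict[str, list[float]]:
        self._t += 1
        out = {}
        for f, vec in self.w.items():
            self._tick_final(f)
            avg = [self._totals[f][k] / self._t for k in range(self.n_tags)]
            if any(abs(v) > 1e-12 for v in avg):
                out[f] = [round(v, 6) for v in avg]
        return out

    def _tick_final(self, f: str) -> None:
        for k in range(self.n_tags):
            self._totals[f][k] += (self._t - self._stamps[f][k]) * self.w[f][k]
            self._stamps[f][k] = self._t


def train(
    sequences: list[BioSequence],
    config: TaggerConfig | None = None,
    lexicon: Lexicon | None = None,
) -> TrainedTagger:
    """Train the baseline tagger on BIO sequences.

    Raises on an empty training set or invalid BIO; truncation at
    ``max_seq_len`` is recorded as a warning per affected sequence.
    """
    config = config or TaggerConfig()
    if config.backend != "baseline":
        raise NotImplementedError(
            "only the baseline backend is shipped; see TransformerTaggerAdapter"
        )
    if not sequences:
        raise ValueError("empty training set")
    for k, seq in enumerate(sequences):
        if not is_valid_bio(seq.tags):
            raise ValueError(f"invalid BIO tags in training sequence {k}: {seq.tags}")

    truncation_warnings: list[str] = []
    prepared = []
    for k, seq in enumerate(sequences):
        tokens, tags = seq.tokens, seq.tags
        if len(tokens) > config.max_seq_len:
            cut = config.max_seq_len
            if tags[cut].startswith("I-"):
                msg = f"sequence {k}: truncation at {cut} splits a B-I run"
            else:
                msg = f"sequence {k}: truncated to {cut} tokens"
            truncation_warnings.append(msg)
            warnings.warn(msg)
            tokens, tags = tokens[:cut], tags[:cut]
        mask_positions = [i for i, t in enumerate(tokens) if t == TRIGGER_MASK]
        feats = [
            _token_features(tokens, i, mask_positions, lexicon)
            for i in range(len(tokens))
        ]
        prepared.append((feats, [_TAG_INDEX[t] for t in tags]))

    model = _Perceptron(len(BIO_TAGS))
    rng = random.Random(config.seed)
    order = list(range(len(prepared)))
    for _ in range(config.epochs):
        rng.shuffle(order)
        for idx in order:
            feats_seq, gold_seq = prepared[idx]
            prev_tag = "O"
            for feats, gold in zip(feats_seq, gold_seq):
                f = feats + [f"prev={prev_tag}"]
                scores = model.scores(f)
                pred = _constrained_argmax(scores, prev_tag)
                if pred != gold:
                    model.update(f, gold, pred)
                else:
                    # demand a strictly positive margin over the runner-up:
                    # ties left at zero would be broken arbitrarily after
                    # weight averaging
                    rival_scores = list(scores)
                    rival_scores[gold] = float("-inf")
                    rival = _constrained_argmax(rival_scores, prev_tag)
                    if scores[gold] <= scores[rival]:
                        model.update(f, gold, rival)
                    else:
                        model.update(f, gold, gold)  # advances the average clock
                prev_tag = BIO_TAGS[gold]  # teacher forcing
    return TrainedTagger(
        backend="baseline",
        weights=model.averaged(),
        tag_inventory=list(BIO_TAGS),
        config=config,
        truncation_warnings=truncation_warnings,
    )


def tag_tokens(model: TrainedTagger, tokens: list[str], lexicon: Lexicon | None = None) -> list[str]:
    """Greedy constrained decoding over a masked token sequence."""
    tokens = tokens[: model.config.max_seq_len]
    mask_positions = [i for i, t in enumerate(tokens) if t == TRIGGER_MASK]
    tags = []
    prev_tag = "O"
    for i in range(len(tokens)):
        feats = _token_features(tokens, i, mask_positions, lexicon) + [
            f"prev={prev_tag}"
        ]
        scores = [0.0] * len(BIO_TAGS)
        for f in feats:
            vec = model.weights.get(f)
            if vec:
                for k in range(len(scores)):
                    scores[k] += vec[k]
        idx = _constrained_argmax(scores, prev_tag)
        tag = BIO_TAGS[idx]
        if i in mask_positions:
            tag = "O"  # masked positions carry no frame element
        tags.append(tag)
        prev_tag = tag
    return repair_bio(tags)


def repair_bio(tags: list[str]) -> list[str]:
    """Promote invalid I- continuations to B- (safety net for backends
    without constrained decoding)."""
    out = []
    prev = "O"
    for tag in tags:
        if tag.startswith("I-"):
            lab = tag[2:]
            if prev not in (f"B-{lab}", f"I-{lab}"):
                tag = f"B-{lab}"
        out.append(tag)
        prev = tag
    return out


def predict(
    model: TrainedTagger,
    sentence: Sentence,
    trigger_span: tuple[int, int],
    lexicon: Lexicon | None = None,
) -> list[tuple[FELabel, tuple[int, int]]]:
    """Mask the trigger, tag the sentence, decode spans as char offsets."""
    tok_span = sentence.token_span_for(*trigger_span)
    if tok_span is None:
        raise ValueError(f"trigger span {trigger_span} not token-aligned")
    first, last = tok_span
    tokens = [
        TRIGGER_MASK if first <= i <= last else t.surface
        for i, t in enumerate(sentence.tokens)
    ]
    tags = tag_tokens(model, tokens, lexicon)
    seq = BioSequence(tokens[: len(tags)], tags)
    out = []
    for label, tfirst, tlast in bio_to_spans(seq):
        out.append(
            (label, (sentence.tokens[tfirst].start, sentence.tokens[tlast].end))
        )
    return out


class TransformerTaggerAdapter:
    """Contract for an external transformer backend.

    An implementation must provide ``train(sequences, config)`` returning an
    object with the same ``predict`` surface as the baseline, consuming and
    producing the identical CoNLL-style BIO files (one mask token per
    original trigger token; sub-word alignment policy is the adapter's to
    document).  No implementation ships here.
    """

    def train(self, sequences: list[BioSequence], config: TaggerConfig):
        raise NotImplementedError("supply a transformer implementation")

    def predict(self, sentence: Sentence, trigger_span: tuple[int, int]):
        raise NotImplementedError("supply a transformer implementation")
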