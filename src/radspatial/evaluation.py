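"""Trigger and frame-element scoring with end-to-end trigger accounting.

Matching is strict: a predicted trigger or frame-element span counts only
on exact character-offset (and label) equality.  In ``predicted_triggers``
mode the score charges the full pipeline for its trigger errors — every
frame element predicted under a false-positive trigger is a false
positive, and every gold frame element under a missed trigger is a false
negative.  ``gold_triggers`` mode scores frame elements for gold trigger
keys only (oracle triggers).  Metrics are percentages; Overall is
micro-averaged by default with a macro option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .lfs import FELabel

Key = tuple[str, int, int, int]  # doc, sent, trigger char start/end
Span = tuple[int, int]


@dataclass
class EvalInstance:
    key: Key
    fe_spans: dict[FELabel, set[Span]] = field(default_factory=dict)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass
class EvalReport:
    trigger: tuple[float, float, float] | None
    per_fe: dict[FELabel, tuple[float, float, float, int]]
    overall: tuple[float, float, float]
    macro: tuple[float, float, float] | None = None

    def to_tsv(self) -> str:
        lines = ["item\tprecision\trecall\tf1\tgold_count"]
        for label, (p, r, f1, n) in self.per_fe.items():
            lines.append(f"{label.name}\t{p:.2f}\t{r:.2f}\t{f1:.2f}\t{n}")
        p, r, f1 = self.overall
        lines.append(f"Overall\t{p:.2f}\t{r:.2f}\t{f1:.2f}\t"
                     f"{sum(v[3] for v in self.per_fe.values())}")
        if self.trigger is not None:
            tp, tr, tf1 = self.trigger
            lines.append(f"Trigger\t{tp:.2f}\t{tr:.2f}\t{tf1:.2f}\t-")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "trigger": self.trigger,
                    "per_fe": {l.name: v for l, v in self.per_fe.items()},
                    "overall": self.overall,
                    "macro": self.macro,
                },
                indent=1,
            )
        )


def score_triggers(
    gold: set[Key] | list[Key], pred: set[Key] | list[Key]
) -> tuple[float, float, float]:
    """Exact char-span precision/recall/F1 over trigger spans (percent)."""
    gold, pred = set(gold), set(pred)
    tp = len(gold & pred)
    return _prf(tp, len(pred - gold), len(gold - pred))


def _index(instances: list[EvalInstance]) -> dict[Key, EvalInstance]:
    out: dict[Key, EvalInstance] = {}
    for inst in instances:
        if inst.key in out:
            raise ValueError(f"duplicate instance key: {inst.key}")
        out[inst.key] = inst
    return out


def score_fes(
    gold_instances: list[EvalInstance],
    pred_instances: list[EvalInstance],
    mode: str = "predicted_triggers",
) -> EvalReport:
    """Strict span+label scoring of frame elements grouped by trigger."""
    if mode not in ("gold_triggers", "predicted_triggers"):
        raise ValueError(f"unknown mode: {mode}")
    gold = _index(gold_instances)
    pred = _index(pred_instances)

    tp = {l: 0 for l in FELabel}
    fp = {l: 0 for l in FELabel}
    fn = {l: 0 for l in FELabel}
    gold_count = {l: 0 for l in FELabel}

    for key, ginst in gold.items():
        pinst = pred.get(key)
        for label, gspans in ginst.fe_spans.items():
            gold_count[label] += len(gspans)
            pspans = pinst.fe_spans.get(label, set()) if pinst else set()
            tp[label] += len(gspans & pspans)
            fn[label] += len(gspans - pspans)
        if pinst:
            for label, pspans in pinst.fe_spans.items():
                gspans = ginst.fe_spans.get(label, set())
                fp[label] += len(pspans - gspans)
    if mode == "predicted_triggers":
        for key, pinst in pred.items():
            if key not in gold:  # FEs under a false-positive trigger
                for label, pspans in pinst.fe_spans.items():
                    fp[label] += len(pspans)

    per_fe = {
        label: (*_prf(tp[label], fp[label], fn[label]), gold_count[label])
        for label in FELabel
    }
    overall = _prf(sum(tp.values()), sum(fp.values()), sum(fn.values()))
    active = [l for l in FELabel if gold_count[l] or fp[l]]
    if active:
        macro = tuple(
            sum(per_fe[l][i] for l in active) / len(active) for i in range(3)
        )
    else:
        macro = (0.0, 0.0, 0.0)
    trigger = score_triggers(set(gold), set(pred))
    return EvalReport(trigger=trigger, per_fe=per_fe, overall=overall, macro=macro)


def instances_from_trigger_instances(instances) -> list[EvalInstance]:
    """Convert weak/predicted TriggerInstance objects for scoring."""
    out = []
    for inst in instances:
        fe = {
            label: {(s, e) for (s, e, _p) in spans}
            for label, spans in inst.fe_spans.items()
            if spans
        }
        out.append(EvalInstance(inst.key, fe))
    return out


def instances_from_predictions(
    key: Key, spans: list[tuple[FELabel, Span]]
) -> EvalInstance:
    """Build one scoring instance from tagger predictions for a trigger."""
    fe: dict[FELabel, set[Span]] = {}
    for label, span in spans:
        fe.setdefault(label, set()).add(span)
    return EvalInstance(key, fe)
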