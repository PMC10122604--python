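"""End-to-end weak-supervision pipeline glue.

Chains the stages in method order: mention tagging and candidate
generation, labeling-function application, generative label aggregation,
trigger-instance assembly, filtering, and BIO conversion.  The functions
here are thin; each stage lives in its own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import candidates, instances, labelmodel, lfs
from .candidates import Sentence, TaggedSentence, tag_sentence
from .instances import BioSequence, FilterConfig, TriggerInstance, to_bio
from .labelmodel import LabelModelConfig, LabelModelParams, ProbabilisticLabel, VoteMatrix
from .lexicon import Lexicon, default_entity_lexicon, default_trigger_lexicon
from .lfs import LFConfig, LabelingFunction


@dataclass
class WeakLabelResult:
    tagged: list[TaggedSentence]
    votes: VoteMatrix
    params: LabelModelParams
    labels: list[ProbabilisticLabel]
    instances: list[TriggerInstance]
    filtered: list[TriggerInstance]


def weak_label(
    sentences: list[Sentence],
    entity_lexicon: Lexicon | None = None,
    trigger_lexicon: Lexicon | None = None,
    lf_config: LFConfig | None = None,
    registry: list[LabelingFunction] | None = None,
    lm_config: LabelModelConfig | None = None,
    filter_config: FilterConfig | None = None,
    aggregator: str = "em",
) -> WeakLabelResult:
    """Run the full weak-labeling pipeline over raw sentences."""
    entity_lexicon = entity_lexicon or default_entity_lexicon()
    trigger_lexicon = trigger_lexicon or default_trigger_lexicon()
    tagged = [tag_sentence(s, entity_lexicon, trigger_lexicon) for s in sentences]
    votes = lfs.apply_lfs(
        tagged, registry or lfs.default_registry(), entity_lexicon, lf_config
    )
    if aggregator == "em":
        params, labels = labelmodel.fit_predict(votes, lm_config)
    elif aggregator == "majority":
        params = None
        labels = labelmodel.fit_majority(votes)
    else:
        raise ValueError(f"unknown aggregator: {aggregator}")
    pairs = votes.pair_refs or []
    insts = instances.build_instances(pairs, labels)
    filtered = instances.filter_instances(insts, filter_config)
    return WeakLabelResult(tagged, votes, params, labels, insts, filtered)


def to_bio_sequences(filtered: list[TriggerInstance]) -> list[BioSequence]:
    return [to_bio(inst) for inst in filtered]
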