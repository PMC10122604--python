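"""Trigger-instance assembly, weak-label filtering and BIO sequences."""

import numpy as np
import pytest

import radspatial as rs
from radspatial.candidates import TriggerMention, tokenize
from radspatial.instances import (
    ContractError,
    FilterConfig,
    TriggerInstance,
    bio_to_spans,
    build_instances,
    filter_figure_ground,
    filter_frequent_phrases,
    filter_instances,
    is_valid_bio,
    read_bio,
    to_bio,
    write_bio,
)
from radspatial.labelmodel import ProbabilisticLabel
from radspatial.lfs import N_LABELS, FELabel

TABLE_TEXT = "There is hazy opacity of the lung consistent with hyaline membrane disease."


def _plabel(pair, label, prob=0.9):
    dist = np.full(N_LABELS, (1 - prob) / (N_LABELS - 1))
    dist[label] = prob
    return ProbabilisticLabel(pair, dist, False)


def _abstained(pair):
    return ProbabilisticLabel(pair, np.full(N_LABELS, 1 / N_LABELS), True)


@pytest.fixture
def table_instance(entity_lexicon, trigger_lexicon):
    ts = rs.tag_sentence(tokenize(TABLE_TEXT, "d", 0), entity_lexicon, trigger_lexicon)
    roles = {
        "opacity": FELabel.FIGURE,
        "lung": FELabel.GROUND,
        "consistent with": FELabel.HEDGE,
        "hyaline membrane disease": FELabel.DIAGNOSIS,
    }
    pairs = [p for p in ts.pairs if p.trigger.surface == "of" and p.entity.surface in roles]
    labels = [_plabel(p, roles[p.entity.surface]) for p in pairs]
    (inst,) = build_instances(pairs, labels)
    return inst


class TestBuildInstances:
    def test_table_sentence_yields_four_fe_entries(self, table_instance):
        assert set(table_instance.fe_spans) == {
            FELabel.FIGURE, FELabel.GROUND, FELabel.HEDGE, FELabel.DIAGNOSIS,
        }
        assert table_instance.trigger.surface == "of"

    def test_all_abstained_yields_no_instances(self, entity_lexicon, trigger_lexicon):
        ts = rs.tag_sentence(tokenize(TABLE_TEXT), entity_lexicon, trigger_lexicon)
        labels = [_abstained(p) for p in ts.pairs]
        assert build_instances(ts.pairs, labels) == []

    def test_shared_entity_gets_per_trigger_labels(self, entity_lexicon, trigger_lexicon):
        ts = rs.tag_sentence(
            tokenize("There is opacity in the lung near the carina."),
            entity_lexicon, trigger_lexicon,
        )
        pairs = [p for p in ts.pairs if p.entity.surface == "lung"
                 and p.trigger.surface in ("in", "near")]
        assert len(pairs) == 2
        labels = [
            _plabel(pairs[0], FELabel.GROUND),
            _plabel(pairs[1], FELabel.FIGURE),
        ]
        insts = build_instances(pairs, labels)
        assert len(insts) == 2
        span_labels = [next(iter(i.fe_spans)) for i in insts]
        assert span_labels == [FELabel.GROUND, FELabel.FIGURE]

    def test_overlapping_same_label_spans_keep_higher_prob(self, entity_lexicon, trigger_lexicon):
        ts = rs.tag_sentence(tokenize(TABLE_TEXT), entity_lexicon, trigger_lexicon)
        lung = next(p for p in ts.pairs if p.trigger.surface == "of" and p.entity.surface == "lung")
        labels = [_plabel(lung, FELabel.GROUND, 0.6), _plabel(lung, FELabel.GROUND, 0.9)]
        (inst,) = build_instances([lung, lung], labels)
        assert [round(p, 2) for (_, _, p) in inst.fe_spans[FELabel.GROUND]] == [0.9]


class TestFilters:
    def _inst(self, fe_labels, text="There is opacity in the lung.", trig="in"):
        sent = tokenize(text)
        ts = rs.tag_sentence(sent, rs.default_entity_lexicon(), rs.default_trigger_lexicon())
        trigger = next(t for t in ts.triggers if t.surface.lower() == trig)
        inst = TriggerInstance(sent, trigger)
        for lab in fe_labels:
            inst.fe_spans[lab] = [(0, 5, 0.9)]
        return inst

    def test_figure_ground_modes(self):
        both = self._inst([FELabel.FIGURE, FELabel.GROUND])
        ground_only = self._inst([FELabel.GROUND])
        empty = self._inst([])
        default = FilterConfig()
        eval_mode = FilterConfig(ground_only_mode=True)
        assert filter_figure_ground(both, default)
        assert not filter_figure_ground(ground_only, default)
        assert filter_figure_ground(ground_only, eval_mode)
        assert not filter_figure_ground(empty, default)
        assert not filter_figure_ground(empty, eval_mode)

    def test_frequent_phrase_left_of_trigger(self):
        cfg = FilterConfig()
        bad = self._inst(
            [FELabel.FIGURE, FELabel.GROUND],
            text="There is history of opacity in the lung.", trig="of",
        )
        assert not filter_frequent_phrases(bad, cfg)
        ok = self._inst([FELabel.FIGURE, FELabel.GROUND])
        assert filter_frequent_phrases(ok, cfg)
        unmapped = self._inst(
            [FELabel.FIGURE, FELabel.GROUND],
            text="The tube is 1 cm above the carina.", trig="above",
        )
        assert filter_frequent_phrases(unmapped, cfg)

    def test_filtering_monotone_and_idempotent(self):
        insts = [
            self._inst([FELabel.FIGURE, FELabel.GROUND]),
            self._inst([FELabel.GROUND]),
            self._inst([]),
        ]
        once = filter_instances(insts)
        assert set(id(i) for i in once) <= set(id(i) for i in insts)
        assert filter_instances(once) == once


class TestBio:
    def test_table_sentence_tags(self, table_instance):
        seq = to_bio(table_instance)
        expected = {
            "opacity": "B-FIGURE",
            "lung": "B-GROUND",
            "consistent": "B-HEDGE",
            "with": "I-HEDGE",
            "hyaline": "B-DIAGNOSIS",
            "membrane": "I-DIAGNOSIS",
            "disease": "I-DIAGNOSIS",
        }
        for tok, tag in zip(seq.tokens, seq.tags):
            assert tag == expected.get(tok, "O")
        # the trigger "of" is masked and tagged O
        i = table_instance.trigger.tok_first
        assert seq.tokens[i] == "$sptrg$" and seq.tags[i] == "O"
        assert is_valid_bio(seq.tags)

    def test_no_fe_spans_all_outside(self, entity_lexicon, trigger_lexicon):
        ts = rs.tag_sentence(tokenize(TABLE_TEXT), entity_lexicon, trigger_lexicon)
        trigger = next(t for t in ts.triggers if t.surface == "of")
        seq = to_bio(TriggerInstance(ts.sentence, trigger))
        assert set(seq.tags) == {"O"}

    def test_two_triggers_differ_only_in_mask_and_tags(self, entity_lexicon, trigger_lexicon):
        sent = tokenize("There is opacity in the lung near the carina.")
        ts = rs.tag_sentence(sent, entity_lexicon, trigger_lexicon)
        t_in = next(t for t in ts.triggers if t.surface == "in")
        t_near = next(t for t in ts.triggers if t.surface == "near")
        seqs = [to_bio(TriggerInstance(sent, t)) for t in (t_in, t_near)]
        diffs = [i for i, (a, b) in enumerate(zip(*[s.tokens for s in seqs])) if a != b]
        assert diffs == sorted({t_in.tok_first, t_near.tok_first})

    def test_unaligned_span_is_contract_error(self):
        sent = tokenize("There is opacity in the lung.")
        ts = rs.tag_sentence(sent, rs.default_entity_lexicon(), rs.default_trigger_lexicon())
        trigger = next(t for t in ts.triggers if t.surface == "in")
        inst = TriggerInstance(sent, trigger)
        inst.fe_spans[FELabel.FIGURE] = [(1, 4, 0.9)]  # mid-token boundaries
        with pytest.raises(ContractError):
            to_bio(inst)

    def test_round_trip_decode_recovers_spans(self, table_instance):
        seq = to_bio(table_instance)
        decoded = {
            (label, table_instance.sentence.tokens[f].start,
             table_instance.sentence.tokens[l].end)
            for label, f, l in bio_to_spans(seq)
        }
        expected = {
            (label, s, e)
            for label, spans in table_instance.fe_spans.items()
            for (s, e, _p) in spans
        }
        assert decoded == expected

    def test_file_round_trip(self, table_instance, tmp_path):
        seq = to_bio(table_instance)
        path = tmp_path / "train.bio"
        write_bio([seq, seq], path)
        back = read_bio(path)
        assert len(back) == 2
        assert back[0].tokens == seq.tokens and back[0].tags == seq.tags
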