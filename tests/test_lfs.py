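"""Labeling-function registry behavior on the printed heuristics examples."""

import pytest

import radspatial as rs
from radspatial import lfs
from radspatial.lfs import ABSTAIN, FELabel, LFConfig, LFContext, default_registry


def _ctx(text, entity_lexicon, trigger_lexicon, cfg=None):
    ts = rs.tag_sentence(rs.tokenize(text), entity_lexicon, trigger_lexicon)
    return ts, LFContext(ts.sentence, ts.entities, ts.triggers, entity_lexicon, cfg or LFConfig())


def _pair(ts, trigger_surface, entity_surface):
    for p in ts.pairs:
        if (
            p.trigger.surface.lower() == trigger_surface
            and p.entity.surface.lower() == entity_surface
        ):
            return p
    raise AssertionError(f"no pair ({trigger_surface}, {entity_surface})")


class TestGroundLFs:
    def test_copula_left_adjacent_anatomy(self, entity_lexicon, trigger_lexicon):
        ts, ctx = _ctx(
            "The lungs demonstrate hazy bilateral opacity of hyaline membrane disease.",
            entity_lexicon, trigger_lexicon,
        )
        assert lfs.lf_ground_adjacency(_pair(ts, "demonstrate", "lungs"), ctx) == FELabel.GROUND

    def test_right_side_gap_and_category_gate(self, entity_lexicon, trigger_lexicon):
        ts, ctx = _ctx(
            "There is hazy opacity of the lung consistent with hyaline membrane disease.",
            entity_lexicon, trigger_lexicon,
        )
        assert lfs.lf_ground_adjacency(_pair(ts, "of", "lung"), ctx) == FELabel.GROUND
        # finding (not anatomy) on the right abstains
        assert lfs.lf_ground_adjacency(_pair(ts, "of", "hyaline membrane disease"), ctx) == ABSTAIN

    def test_closest_trigger_variants(self, entity_lexicon, trigger_lexicon):
        ts, ctx = _ctx(
            "There are scattered T2 high signal intensity foci in the periventricular "
            "white matter and centrum semi-ovale consistent with microvascular angiopathy.",
            entity_lexicon, trigger_lexicon,
        )
        assert lfs.lf_ground_closest(_pair(ts, "in", "periventricular white matter"), ctx) == FELabel.GROUND
        assert lfs.lf_ground_closest(_pair(ts, "in", "centrum semi-ovale"), ctx) == FELabel.GROUND

    def test_closest_abstains_with_intervening_trigger(self, entity_lexicon, trigger_lexicon):
        ts, ctx = _ctx(
            "There is opacity in the lung.", entity_lexicon, trigger_lexicon
        )
        # for trigger "is", gap to "lung" > 0 and "in" intervenes
        assert lfs.lf_ground_closest(_pair(ts, "is", "lung"), ctx) == ABSTAIN

    def test_colon_heading(self, entity_lexicon, trigger_lexicon):
        ts, ctx = _ctx("Brain parenchyma: There are atherosclerotic changes.",
                       entity_lexicon, trigger_lexicon)
        assert lfs.lf_ground_colon_heading(_pair(ts, "are", "brain parenchyma"), ctx) == FELabel.GROUND


class TestDiagnosisLFs:
    def test_sentence_final_with_hedge(self, entity_lexicon, trigger_lexicon):
        ts, ctx = _ctx(
            "A patchy area of consolidation is seen within the right lower lobe "
            "concerning for pneumonia.",
            entity_lexicon, trigger_lexicon,
        )
        assert lfs.lf_diagnosis_sentence_final(_pair(ts, "within", "pneumonia"), ctx) == FELabel.DIAGNOSIS

    def test_sentence_final_abstains_without_hedge(self, entity_lexicon, trigger_lexicon):
        ts, ctx = _ctx("There is opacity in the lung.", entity_lexicon, trigger_lexicon)
        assert lfs.lf_diagnosis_sentence_final(_pair(ts, "in", "lung"), ctx) == ABSTAIN

    def test_hedge_window_right_cue(self, entity_lexicon, trigger_lexicon):
        ts, ctx = _ctx(
            "There is stable opacity in the right lower lobe as well as a retrocardiac "
            "opacity, these are likely related to atelactases versus pneumonia.",
            entity_lexicon, trigger_lexicon,
        )
        assert lfs.lf_diagnosis_hedge_window(_pair(ts, "in", "atelactases"), ctx) == FELabel.DIAGNOSIS

    def test_hedge_window_left_cue(self, entity_lexicon, trigger_lexicon):
        ts, ctx = _ctx(
            "There is opacity in the lung consistent with microvascular angiopathy.",
            entity_lexicon, trigger_lexicon,
        )
        assert lfs.lf_diagnosis_hedge_window(
            _pair(ts, "in", "microvascular angiopathy"), ctx
        ) == FELabel.DIAGNOSIS

    def test_hedge_window_abstains_without_cue(self, entity_lexicon, trigger_lexicon):
        ts, ctx = _ctx("There is opacity in the lung.", entity_lexicon, trigger_lexicon)
        assert lfs.lf_diagnosis_hedge_window(_pair(ts, "in", "opacity"), ctx) == ABSTAIN


class TestRegistry:
    def test_exactly_19_lfs_covering_all_labels(self):
        registry = default_registry()
        assert len(registry) == 19
        assert len({lf.name for lf in registry}) == 19
        assert {lf.target_label for lf in registry} == set(FELabel)

    def test_label_purity_and_determinism_on_corpus(self, entity_lexicon, trigger_lexicon):
        corpus = rs.generate(rs.SynthConfig(n_sentences=50, seed=3))
        tagged = [rs.tag_sentence(s, entity_lexicon, trigger_lexicon) for s, _ in corpus]
        registry = default_registry()
        vm1 = lfs.apply_lfs(tagged, registry, entity_lexicon)
        vm2 = lfs.apply_lfs(tagged, registry, entity_lexicon)
        assert (vm1.votes == vm2.votes).all()
        for j, lf in enumerate(registry):
            col = set(vm1.votes[:, j].tolist())
            assert col <= {ABSTAIN, int(lf.target_label)}

    def test_empty_pairs_give_empty_matrix(self, entity_lexicon, trigger_lexicon):
        ts = rs.tag_sentence(rs.tokenize("Normal."), entity_lexicon, trigger_lexicon)
        vm = lfs.apply_lfs([ts], default_registry(), entity_lexicon)
        assert vm.votes.shape == (0, 19)

    def test_emptied_cue_list_yields_abstain_column(self, entity_lexicon, trigger_lexicon):
        cfg = LFConfig(reason_cues=["zzz_no_such_cue"])
        corpus = rs.generate(rs.SynthConfig(n_sentences=40, seed=5))
        tagged = [rs.tag_sentence(s, entity_lexicon, trigger_lexicon) for s, _ in corpus]
        vm = lfs.apply_lfs(tagged, default_registry(), entity_lexicon, cfg)
        j = vm.lf_names.index("reason_cue")
        assert set(vm.votes[:, j].tolist()) == {ABSTAIN}

    def test_duplicate_names_rejected(self, entity_lexicon):
        registry = default_registry()
        registry.append(registry[0])
        with pytest.raises(ValueError, match="duplicate"):
            lfs.apply_lfs([], registry, entity_lexicon)

    def test_table_sentence_vote_profile(self, entity_lexicon, trigger_lexicon):
        ts = rs.tag_sentence(
            rs.tokenize(
                "There is hazy opacity of the lung consistent with hyaline membrane disease."
            ),
            entity_lexicon, trigger_lexicon,
        )
        vm = lfs.apply_lfs([ts], default_registry(), entity_lexicon)
        idx = next(
            i for i, p in enumerate(vm.pair_refs)
            if p.trigger.surface == "of" and p.entity.surface == "lung"
        )
        row = vm.votes[idx]
        assert (row == FELabel.GROUND).sum() >= 1
        assert (row == FELabel.DIAGNOSIS).sum() == 0
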