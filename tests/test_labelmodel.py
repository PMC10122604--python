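"""Generative label aggregation: EM fitting, prediction, simulation oracle."""

import numpy as np
import pytest

from radspatial.labelmodel import (
    ABSTAIN,
    LabelModelConfig,
    LabelModelError,
    LabelModelParams,
    VoteMatrix,
    fit,
    fit_majority,
    predict,
    simulate_votes,
)
from radspatial.lfs import N_LABELS, FELabel

UNIFORM = [1.0 / N_LABELS] * N_LABELS


def _vm(rows, m=None):
    rows = np.array(rows, dtype=np.int8)
    m = m or rows.shape[1]
    return VoteMatrix(votes=rows, lf_names=[f"lf{j}" for j in range(m)])


class TestMajority:
    def test_unanimous(self):
        labs = fit_majority(_vm([[FELabel.GROUND, FELabel.GROUND, ABSTAIN]]))
        assert labs[0].label == FELabel.GROUND and labs[0].prob == 1.0

    def test_tie_breaks_by_label_order(self):
        labs = fit_majority(_vm([[FELabel.GROUND, FELabel.FIGURE]]))
        assert labs[0].distribution[FELabel.FIGURE] == pytest.approx(0.5)
        assert labs[0].label == FELabel.FIGURE  # FIGURE precedes GROUND

    def test_all_abstain(self):
        labs = fit_majority(_vm([[ABSTAIN, ABSTAIN]]))
        assert labs[0].abstained


class TestFit:
    def test_degenerate_consensus(self):
        vm = _vm([[FELabel.HEDGE]] * 100)
        params = fit(vm)
        # 0.7 (= precision_init) is the exact fixed point for a lone LF
        assert params.accuracy[0] >= 0.7 - 1e-9
        labs = predict(params, vm)
        assert all(l.label == FELabel.HEDGE for l in labs)

    def test_contradicting_lfs_are_symmetric(self):
        rows = [[FELabel.FIGURE, FELabel.GROUND]] * 50
        params = fit(_vm(rows))
        assert params.accuracy[0] == pytest.approx(params.accuracy[1], abs=1e-6)
        labs = predict(params, _vm(rows))
        d = labs[0].distribution
        assert d[FELabel.FIGURE] == pytest.approx(d[FELabel.GROUND], abs=1e-6)

    def test_all_abstain_matrix_is_error(self):
        with pytest.raises(LabelModelError):
            fit(_vm([[ABSTAIN, ABSTAIN]] * 5))

    def test_objective_monotone_and_posteriors_normalized(self):
        vm, _ = simulate_votes(800, [0.8, 0.7, 0.6], [0.2] * 3, UNIFORM, seed=9)
        params = fit(vm)
        obj = params.objective_history
        assert all(b >= a - 1e-8 for a, b in zip(obj, obj[1:]))
        for lab in predict(params, vm):
            assert lab.distribution.sum() == pytest.approx(1.0, abs=1e-9)

    def test_accuracy_recovery(self):
        truth_alpha = [0.9, 0.8, 0.65]
        vm, _ = simulate_votes(4000, truth_alpha, [0.25] * 3, UNIFORM, seed=17)
        params = fit(vm)
        assert np.abs(params.accuracy - np.array(truth_alpha)).max() < 0.05


class TestPredict:
    def test_column_mismatch_is_error(self):
        vm, _ = simulate_votes(50, [0.8, 0.7], [0.1] * 2, UNIFORM, seed=1)
        params = fit(vm)
        other = _vm([[FELabel.GROUND]])
        with pytest.raises(LabelModelError):
            predict(params, other)

    def test_single_lf_argmax_follows_votes(self):
        vm, _ = simulate_votes(300, [0.85], [0.3], UNIFORM, seed=5)
        params = fit(vm)
        for lab, row in zip(predict(params, vm), vm.votes):
            if row[0] == ABSTAIN:
                assert lab.abstained
            else:
                assert lab.label == FELabel(int(row[0]))

    def test_higher_accuracy_lf_wins_two_lf_conflict(self):
        # closed form: pi uniform, alpha=(0.9, 0.6); posterior odds favor
        # the high-accuracy LF's label
        params = LabelModelParams(
            accuracy=np.array([0.9, 0.6]),
            prior=np.full(N_LABELS, 1.0 / N_LABELS),
            config=LabelModelConfig(),
            lf_names=["lf0", "lf1"],
        )
        vm = _vm([[FELabel.GROUND, FELabel.FIGURE]])
        labs = predict(params, vm)
        assert labs[0].label == FELabel.GROUND

    def test_symmetric_model_equals_majority(self):
        vm, _ = simulate_votes(500, [0.75] * 4, [0.2] * 4, UNIFORM, seed=3)
        params = LabelModelParams(
            accuracy=np.full(4, 0.75),
            prior=np.full(N_LABELS, 1.0 / N_LABELS),
            config=LabelModelConfig(),
            lf_names=list(vm.lf_names),
        )
        for em, mv in zip(predict(params, vm), fit_majority(vm)):
            assert em.abstained == mv.abstained
            if not em.abstained:
                assert em.label == mv.label


class TestSimulate:
    def test_perfect_lfs_always_agree_with_truth(self):
        vm, truth = simulate_votes(200, [0.999999] * 3, [0.0] * 3, UNIFORM, seed=2)
        assert (vm.votes == truth[:, None]).all()

    def test_seed_determinism(self):
        a, ta = simulate_votes(300, [0.8, 0.6], [0.3, 0.1], UNIFORM, seed=11)
        b, tb = simulate_votes(300, [0.8, 0.6], [0.3, 0.1], UNIFORM, seed=11)
        assert (a.votes == b.votes).all() and (ta == tb).all()

    def test_empirical_agreement_matches_alpha(self):
        alphas = [0.9, 0.7, 0.55]
        vm, truth = simulate_votes(10000, alphas, [0.2] * 3, UNIFORM, seed=21)
        for j, alpha in enumerate(alphas):
            col = vm.votes[:, j]
            mask = col != ABSTAIN
            agree = (col[mask] == truth[mask]).mean()
            assert abs(agree - alpha) < 0.02

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(LabelModelError):
            simulate_votes(10, [1.5], [0.0], UNIFORM, seed=0)
        with pytest.raises(LabelModelError):
            simulate_votes(10, [0.8], [1.0], UNIFORM, seed=0)
        with pytest.raises(LabelModelError):
            simulate_votes(10, [0.8], [0.1], [0.5] * 9, seed=0)


class TestAggregationBeatsBaseline:
    def test_em_label_accuracy_at_least_majority(self):
        wins = 0
        for seed in range(5):
            vm, truth = simulate_votes(
                2000, [0.9, 0.85, 0.8, 0.7, 0.6], [0.3] * 5, UNIFORM, seed=100 + seed
            )
            params = fit(vm)
            em = np.array([l.label for l in predict(params, vm)])
            mv = np.array([l.label for l in fit_majority(vm)])
            wins += (em == truth).mean() >= (mv == truth).mean()
        assert wins >= 4  # stochastic: allow one failure


class TestSerialization:
    def test_tsv_round_trip(self):
        vm, _ = simulate_votes(30, [0.8, 0.6], [0.4, 0.2], UNIFORM, seed=8)
        import tempfile, pathlib

        with tempfile.TemporaryDirectory() as d:
            path = pathlib.Path(d) / "votes.tsv"
            vm.to_tsv(path)
            back = VoteMatrix.from_tsv(path)
        assert back.lf_names == vm.lf_names
        assert (back.votes == vm.votes).all()
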