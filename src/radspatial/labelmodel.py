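"""Generative aggregation of labeling-function votes into probabilistic labels.

Each labeling function (LF) is modeled as a "one-coin" annotator: with its
unobserved accuracy alpha_j it votes the true label, otherwise it votes one
of the other labels uniformly; abstentions are ignored (missing at random).
Given the n x m vote matrix the model estimates per-LF accuracies and class
priors by expectation-maximization and assigns each candidate a posterior
distribution over the nine frame-element labels.

The M-step shrinks each accuracy toward ``precision_init`` with pseudo-count
strength ``l2`` (a MAP estimate), so the EM objective that provably
increases per iteration is the penalized log-likelihood recorded in
``LabelModelParams.objective_history``.

A majority-vote baseline aggregator and a vote simulator (the test oracle
for parameter recovery) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lfs import ABSTAIN, N_LABELS, FELabel


class LabelModelError(ValueError):
    pass


@dataclass
class VoteMatrix:
    """n candidates x m LFs; cells are FELabel values or -1 (abstain)."""

    votes: np.ndarray
    lf_names: list[str]
    target_labels: list[FELabel | None] | None = None
    pair_refs: list | None = None

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=np.int8)
        if self.votes.ndim != 2:
            raise LabelModelError("votes must be 2-dimensional")
        if self.votes.shape[1] != len(self.lf_names):
            raise LabelModelError("lf_names length mismatch")
        if self.votes.size and (self.votes.max() >= N_LABELS or self.votes.min() < ABSTAIN):
            raise LabelModelError("vote values out of range")

    @property
    def n(self) -> int:
        return self.votes.shape[0]

    @property
    def m(self) -> int:
        return self.votes.shape[1]

    # -- serialization (TSV: header = LF names, cells = label name or "-") --

    def to_tsv(self, path) -> None:
        from pathlib import Path

        lines = ["pair_id\t" + "\t".join(self.lf_names)]
        for i in range(self.n):
            cells = [
                FELabel(v).name if v != ABSTAIN else "-" for v in self.votes[i]
            ]
            lines.append(f"{i}\t" + "\t".join(cells))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "VoteMatrix":
        from pathlib import Path

        lines = Path(path).read_text().splitlines()
        names = lines[0].split("\t")[1:]
        rows = []
        for line in lines[1:]:
            if not line.strip():
                continue
            cells = line.split("\t")[1:]
            rows.append([ABSTAIN if c == "-" else FELabel[c].value for c in cells])
        votes = np.array(rows, dtype=np.int8).reshape(len(rows), len(names))
        return cls(votes=votes, lf_names=names)


@dataclass
class LabelModelConfig:
    """Hyperparameters: 100 epochs, l2 0.01 toward precision_init 0.7 (the
    learning rate is kept for interface parity; EM does not use it)."""

    epochs: int = 100
    learning_rate: float = 0.0001
    l2: float = 0.01
    precision_init: float = 0.7
    seed: int = 0
    tol: float = 1e-6
    # Class balance is a fixed uniform distribution by default.  Estimating
    # it by EM is optional: with heavily skewed vote counts it lets frequent
    # classes override rare classes that only a single LF supports.
    estimate_class_prior: bool = False


@dataclass
class LabelModelParams:
    accuracy: np.ndarray  # per-LF alpha_j in (0, 1)
    prior: np.ndarray  # per-label pi_k, sums to 1
    config: LabelModelConfig
    lf_names: list[str] = field(default_factory=list)
    loglik_history: list[float] = field(default_factory=list)
    objective_history: list[float] = field(default_factory=list)
    n_iter: int = 0


@dataclass
class ProbabilisticLabel:
    pair_ref: object
    distribution: np.ndarray  # over the 9 FE labels
    abstained: bool

    @property
    def label(self) -> FELabel:
        # ties (to 1e-12, absorbing log-space roundoff) break toward the
        # lowest index, i.e. FELabel declaration order
        return FELabel(int(np.argmax(np.round(self.distribution, 12))))

    @property
    def prob(self) -> float:
        return float(self.distribution.max())


def _pair_refs(votes: VoteMatrix):
    return votes.pair_refs if votes.pair_refs is not None else [None] * votes.n


def fit_majority(votes: VoteMatrix) -> list[ProbabilisticLabel]:
    """Per-row label distribution proportional to vote counts."""
    out = []
    for ref, row in zip(_pair_refs(votes), votes.votes):
        counts = np.bincount(row[row != ABSTAIN], minlength=N_LABELS).astype(float)
        total = counts.sum()
        if total == 0:
            out.append(ProbabilisticLabel(ref, np.full(N_LABELS, 1.0 / N_LABELS), True))
        else:
            out.append(ProbabilisticLabel(ref, counts / total, False))
    return out


def _posteriors(votes: np.ndarray, alpha: np.ndarray, prior: np.ndarray):
    """Log-space E-step.  Returns (posteriors, total log-likelihood) over
    rows with at least one vote; all-abstain rows get the prior."""
    n, m = votes.shape
    log_prior = np.log(prior)
    log_alpha = np.log(alpha)
    log_wrong = np.log((1.0 - alpha) / (N_LABELS - 1))
    logpost = np.tile(log_prior, (n, 1))
    for j in range(m):
        col = votes[:, j]
        mask = col != ABSTAIN
        if not mask.any():
            continue
        contrib = np.full((mask.sum(), N_LABELS), log_wrong[j])
        contrib[np.arange(mask.sum()), col[mask]] = log_alpha[j]
        logpost[mask] += contrib
    norm = np.logaddexp.reduce(logpost, axis=1)
    post = np.exp(logpost - norm[:, None])
    voted = (votes != ABSTAIN).any(axis=1)
    loglik = float(norm[voted].sum())
    post[~voted] = prior
    return post, loglik


def _penalty(alpha: np.ndarray, lam: np.ndarray, p0: float, prior: np.ndarray) -> float:
    """Log-prior terms of the MAP objective (accuracy pseudo-counts plus the
    Dirichlet(2) prior on the class distribution)."""
    acc = float(np.sum(lam * (p0 * np.log(alpha) + (1 - p0) * np.log(1 - alpha))))
    return acc + float(np.log(prior).sum())


def fit(votes: VoteMatrix, config: LabelModelConfig | None = None) -> LabelModelParams:
    """EM fit of per-LF accuracies and class priors.

    alpha_j starts at ``precision_init``; the prior starts uniform and is
    re-estimated each M-step.  Stops after ``epochs`` iterations or when
    the largest parameter change drops below ``tol``.
    """
    config = config or LabelModelConfig()
    mat = votes.votes
    if mat.size == 0 or not (mat != ABSTAIN).any():
        raise LabelModelError("cannot fit on an all-abstain vote matrix")

    m = votes.m
    n_j = (mat != ABSTAIN).sum(axis=0).astype(float)
    lam = config.l2 * n_j
    p0 = config.precision_init
    eps = 1e-6

    alpha = np.full(m, p0)
    prior = np.full(N_LABELS, 1.0 / N_LABELS)
    loglik_history: list[float] = []
    objective_history: list[float] = []
    it = 0
    for it in range(1, config.epochs + 1):
        post, loglik = _posteriors(mat, alpha, prior)
        loglik_history.append(loglik)
        objective_history.append(loglik + _penalty(alpha, lam, p0, prior))

        # expected correct votes per LF
        correct = np.zeros(m)
        for j in range(m):
            mask = mat[:, j] != ABSTAIN
            if mask.any():
                correct[j] = post[mask, mat[mask, j]].sum()
        denom = np.where(n_j > 0, n_j + lam, 1.0)
        new_alpha = np.where(n_j > 0, (correct + lam * p0) / denom, alpha)
        new_alpha = np.clip(new_alpha, eps, 1 - eps)

        if config.estimate_class_prior:
            # Laplace-smoothed (Dirichlet(2) MAP) prior update.
            voted = (mat != ABSTAIN).any(axis=1)
            counts = post[voted].sum(axis=0) if voted.any() else prior
            new_prior = (counts + 1.0) / (float(voted.sum()) + N_LABELS)
            new_prior = np.clip(new_prior, 1e-12, None)
            new_prior /= new_prior.sum()
        else:
            new_prior = prior

        delta = max(np.abs(new_alpha - alpha).max(), np.abs(new_prior - prior).max())
        alpha, prior = new_alpha, new_prior
        if delta < config.tol:
            break

    return LabelModelParams(
        accuracy=alpha,
        prior=prior,
        config=config,
        lf_names=list(votes.lf_names),
        loglik_history=loglik_history,
        objective_history=objective_history,
        n_iter=it,
    )


def predict(params: LabelModelParams, votes: VoteMatrix) -> list[ProbabilisticLabel]:
    """Posterior label distribution per row under fitted parameters."""
    if votes.m != len(params.accuracy):
        raise LabelModelError("vote matrix has a different number of LF columns")
    if params.lf_names and params.lf_names != list(votes.lf_names):
        raise LabelModelError("LF column names differ from the fitted matrix")
    post, _ = _posteriors(votes.votes, params.accuracy, params.prior)
    voted = (votes.votes != ABSTAIN).any(axis=1)
    return [
        ProbabilisticLabel(ref, post[i], not bool(voted[i]))
        for i, ref in enumerate(_pair_refs(votes))
    ]


def fit_predict(
    votes: VoteMatrix, config: LabelModelConfig | None = None
) -> tuple[LabelModelParams, list[ProbabilisticLabel]]:
    params = fit(votes, config)
    return params, predict(params, votes)


def simulate_votes(
    n: int,
    accuracies: list[float],
    abstain_rates: list[float],
    priors: list[float],
    seed: int = 0,
) -> tuple[VoteMatrix, np.ndarray]:
    """Sample a vote matrix from the one-coin model (test oracle).

    True labels are drawn from ``priors``; LF j abstains with its rate,
    otherwise votes the truth with probability alpha_j, else a uniformly
    random wrong label.
    """
    if len(accuracies) != len(abstain_rates):
        raise LabelModelError("accuracies and abstain_rates must have equal length")
    accuracies = np.asarray(accuracies, dtype=float)
    abstain_rates = np.asarray(abstain_rates, dtype=float)
    priors = np.asarray(priors, dtype=float)
    if ((accuracies <= 0) | (accuracies >= 1)).any():
        raise LabelModelError("accuracies must lie in (0, 1)")
    if ((abstain_rates < 0) | (abstain_rates >= 1)).any():
        raise LabelModelError("abstain rates must lie in [0, 1)")
    if len(priors) != N_LABELS or priors.min() < 0 or not np.isclose(priors.sum(), 1.0):
        raise LabelModelError("priors must be a distribution over the 9 labels")

    rng = np.random.default_rng(seed)
    m = len(accuracies)
    truth = rng.choice(N_LABELS, size=n, p=priors)
    votes = np.full((n, m), ABSTAIN, dtype=np.int8)
    for j in range(m):
        active = rng.random(n) >= abstain_rates[j]
        correct = rng.random(n) < accuracies[j]
        wrong_offset = rng.integers(1, N_LABELS, size=n)
        voted = np.where(correct, truth, (truth + wrong_offset) % N_LABELS)
        votes[active, j] = voted[active]
    vm = VoteMatrix(votes=votes, lf_names=[f"sim_lf_{j}" for j in range(m)])
    return vm, truth
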