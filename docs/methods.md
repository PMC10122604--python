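# Methods

This note documents the models and procedures implemented in `radspatial`,
the parameters that matter, what the synthetic corpus does and does not
emulate, and the design choices made where the design was genuinely open.

## Task and representation

A radiology sentence may assert one or more *spatial frames*. Each frame is
anchored by a **spatial trigger** — usually a preposition or verb (*in*,
*of*, *above*, *terminates*) — and filled by **frame elements (FEs)** drawn
from nine types: Figure (the located finding or device), Ground (the
anatomical location), Hedge (an uncertainty phrase such as *consistent
with*), Diagnosis (the differential introduced by a hedge), Position status
(device position wording), Relative position (orientation descriptors),
Distance (a measured offset), Reason (a causal condition) and Associated
process (an activity linked to the relation). The atomic labeling unit is
the candidate pair {trigger, entity}; the training unit is the trigger
instance (one trigger plus all its labeled FE spans); the tagging unit is a
(sentence, masked trigger) BIO sequence.

## Lexicons

Two surface-form dictionaries drive candidate generation. The packaged
radiological-entity lexicon holds ~150 base terms across nine categories
(finding, anatomy, device, process, location_descriptor,
certainty_descriptor, hedge, position_status, relative_position); users
supply their own TSV term lists for production use — the packaged lexicon is
a self-contained miniature, not a substitute for an ontology-scale
vocabulary. Expansion is rule-based and reproducible:

- **Prepend phrases** (*area(s) of*, *region(s) of*, *focus/foci of*)
  applied to finding terms.
- **Descriptor pairs** concatenating a modifier with an existing target
  term (*petechial* + *hemorrhage*); a configured descriptor whose target
  is absent from the lexicon is a configuration error, not a silent skip.
- **Pluralization** of the final word of each term: a small irregulars
  table (focus→foci, atrium→atria, metastasis→metastases, …) is consulted
  first, then -is→-es, consonant+y→-ies, sibilant endings +es, default +s.

Expansion applies prepend/descriptor rules only to base and manually added
entries, and does not pluralize prepend-derived entries (their plural
variants come from the plural prepend phrases), which makes `expand`
idempotent for a fixed configuration — a property the test suite asserts.

The spatial-trigger dictionary defaults to spatial prepositions plus the
copular verbs used by the Ground adjacency heuristic (*is*, *are*,
*show(s)*, *demonstrate(s)*, *reveal(s)*, *with*, *without*). Position
verbs such as *terminates* are deliberately entities (position_status), not
triggers, in the default dictionary: in the frame representation the
preposition carries the relation and the verb fills the Position-status
slot. `tag_triggers` accepts any user-supplied dictionary.

## Candidate generation

Tokenization splits on whitespace and peels edge punctuation (`.,;:()/`)
into separate tokens while preserving hyphens and internal periods, so
`C5-C7` and `1.5` survive as single tokens. Dictionary tagging is
case-insensitive exact longest-match over token-aligned n-grams; among
overlapping matches the longest wins, ties broken leftmost. One exception:
a selected multi-token anatomy span that *begins* with a location
descriptor (*inferior cerebellar peduncle*) is split into the descriptor
mention plus the remaining anatomy mention, because the descriptor may fill
a Relative-position slot of its own. Two regex matchers add mentions the
dictionary cannot carry: distances (number or range followed by mm/cm/
millimeter(s)/centimeter(s)) and vertebral segments (`[CTL]` + level,
optionally hyphenated). Candidates are the cross product of triggers and
entities within a sentence, minus pairs whose spans overlap.

No stemming, spelling correction or dependency parsing is attempted;
misspellings reduce dictionary coverage by design (the corruption utility
in the synthetic module exists to measure exactly that).

## Labeling functions

The registry holds 19 deterministic LFs, each voting exactly one target
label or abstaining. Shared knobs live in `LFConfig`: the copula list, a
4-token window length, a 2-token Ground gap, hedge/reason/process cue
lists, and the position-verb family. Cues match as lowercase substrings of
the joined window text, so the stem *indicat* hits *indicating* and
*indicative*. Window lengths count tokens and never cross sentence
boundaries.

Coverage by label — Ground: copula-adjacency (anatomy directly left of a
copular trigger), closest-trigger (anatomy right of the trigger with no
other trigger between), and a colon-heading rule for the "location:
finding" reporting style; Diagnosis: sentence-final finding licensed by a
hedge, and hedge-cue windows (left list *represent/suggest/indicat/
consistent with*, right list *ruled out/excluded/vs/versus*); Figure:
finding/device shortly left of the trigger, finding/device immediately
right of a *verbal* copula, and a chained-frame rule for anatomy
left-adjacent to a second trigger; Hedge: hedge-category proximity and
hedge-phrase surface match; Distance: the regex matcher left of the
trigger; Relative position: descriptor proximity and the descriptor-split
rule; Position status: position wording left of the trigger in a device
sentence and the position-verb family; Reason: causal cues (*due to*,
*secondary to*, *from*); Associated process: *during/while* clauses.

Three points were genuinely open and were decided as follows:

- The copula-adjacency Ground rule **requires an anatomy category** on the
  left-adjacent entity. Without the gate, copulas in device sentences
  ("The tube **is** 1 cm above …") acquire spurious Ground votes from the
  device mention and survive filtering as false-positive triggers.
- The Figure-left rule ignores **intervening copulas**: in ordinary report
  syntax the copula sits between the Figure and the true prepositional
  trigger ("ETT tube *is* 1 cm *above* the carina").
- The Figure-after-copula rule is restricted to **verbal** copulas.
  *with*/*without* are prepositional: the finding to their right is
  typically a Diagnosis inside a hedge phrase ("consistent **with**
  pneumonia"), and letting the rule fire there systematically opposed the
  Diagnosis LFs.

## Generative label model

LF votes are aggregated by a one-coin Dawid–Skene model with abstention:
LF j votes the true label with unobserved accuracy `alpha_j`, otherwise a
uniformly random wrong label, and abstains missing-at-random. Fitting is
EM with `alpha_j` initialized at `precision_init = 0.7`, at most
`epochs = 100` iterations, convergence tolerance `1e-6`, and an M-step that
shrinks each accuracy toward the initializer with pseudo-count strength
`l2 = 0.01`:

`alpha_j = (expected correct votes + l2 * n_j * 0.7) / (n_j + l2 * n_j)`

where `n_j` counts LF j's non-abstaining votes. Because the M-step is a
MAP update, the quantity that provably never decreases is the penalized
log-likelihood recorded in `objective_history` (the plain log-likelihood is
recorded alongside).

The class balance is a **fixed uniform prior** by default. Estimating it by
EM is available (`estimate_class_prior=True`, with a Laplace-smoothed
update) but off: when a rare class such as Distance is supported by a
single LF per row, an estimated prior self-reinforces toward frequent
classes and drags that LF's accuracy to zero — a failure mode observed
directly on small corpora. Treating class balance as an input matches the
established data-programming practice.

Two identifiability facts worth knowing: a lone LF whose rows carry no
other votes sits at the `precision_init` fixed point (a singleton row's
posterior equals `alpha` itself, so 0.7 reproduces 0.7) — such spans
surface with probability 0.70; and with equal accuracies and a uniform
prior, the posterior argmax provably equals majority vote, which the test
suite uses as an oracle. Posterior argmax ties break in label declaration
order after rounding to 12 decimals (absorbing log-space roundoff, so
exact-tie cases agree with exact-arithmetic majority voting).

## Filtering and BIO conversion

Two constraints clean the weak training set. First, a frame requires both
Figure and Ground; in evaluation mode only Ground is required, which
raises trigger recall for downstream FE prediction. Second, a
frequent-phrase blocklist around common triggers removes non-spatial uses
(*history of*, *consistent with*, *in place*); the shipped lists are small
documented defaults and pure configuration. Filtering is monotone and
idempotent.

Surviving instances render as CoNLL-style BIO sequences with every trigger
token replaced by the mask symbol `$sptrg$` (one mask token per original
token, preserving alignment; masked positions are tagged O). Cross-label
span overlaps resolve by higher posterior probability, then label order.
Span decoding is the exact inverse on surviving spans, asserted as a
round trip.

## Baseline tagger

The shipped backend is an averaged perceptron over sparse per-token
features (lowercase form, shape, prefix/suffix, mask flag, clipped
distance to the mask, ±2 context tokens, optional lexicon categories, and
the previous tag) with BIO-transition-constrained greedy decoding; invalid
I-continuations from unconstrained backends are repaired by promotion to
B. Training is teacher-forced, shuffled per epoch by a seeded RNG, and
bit-for-bit reproducible. On an exact score tie the trainer still updates
(demanding a strictly positive margin for the gold tag): ties left at zero
would be broken arbitrarily after weight averaging, and the memorization
guarantee on repeated training data depends on it. Default 5 epochs,
`max_seq_len = 128` with per-sequence truncation warnings. A transformer
backend is an adapter contract only (same train/predict surface over the
same BIO files; sub-word alignment policy is the adapter's to document) —
no neural weights ship with the package.

## Evaluation protocol

Matching is strict: exact character offsets (and label, for FEs). Trigger
scoring is set precision/recall/F1 in percent. FE scoring groups instances
by (doc, sentence, trigger span); in `predicted_triggers` mode every FE
predicted under an unmatched trigger is a false positive and every gold FE
under a missed trigger is a false negative, so the pipeline pays for its
trigger errors — this mode can never outscore `gold_triggers` mode on the
same predictions (a tested invariant). The Overall row is micro-averaged;
a macro average is also computed.

## Synthetic corpus

The generator samples seven reporting styles over the packaged vocabulary
— finding-in-location (optionally with an orientation descriptor), the
"location: finding" colon style, device position statements (three
sub-patterns), hedged diagnoses, measured distances, causal attributions
(*due to*), and *during*-clauses — and records gold spans exactly. The
default mix (0.25/0.10/0.15/0.20/0.10/0.10/0.10) keeps every FE above 1%
of frames at n = 1000. A distractor rate of 0.25 prepends out-of-vocabulary
modifiers to findings; a misspelling corruptor applies character edits
(swap/drop/duplicate) to non-gold tokens at a configurable rate up to 0.3,
leaving gold spans intact.

The templates are deliberately within-distribution for the default LFs:
passing end-to-end tests demonstrates that the machinery is correct and
self-consistent, not that the heuristics cover real reporting language.
Real reports bring section headers, negation scope, coordination,
misspellings inside entity spans, cross-sentence frames and vocabulary far
beyond the packaged lexicon; measured synthetic scores (trigger and FE F1
near 100%) are upper bounds with no claim of transfer. Problem sizes used
by the tests and the acceptance script — 500 training sentences, 100
held-out, 5000 simulated vote rows — were chosen as the smallest sizes at
which the measured quantities are stable across seeds.

## Known limitations

- Exact dictionary matching: no robustness to misspellings or unseen
  phrase variants; coverage is bounded by the supplied term lists.
- The label model ignores LF correlations; correlated LFs (the two Reason
  rules often fire together) are over-counted as independent evidence.
- One frame per trigger, no nested or cross-sentence frames.
- The frequent-phrase blocklists and the 15 non-printed heuristics beyond
  the documented four are repo-chosen defaults; deployments with access to
  better cue inventories should replace them via `LFConfig` and
  `FilterConfig`.
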