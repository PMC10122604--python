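# radspatial

Weakly supervised extraction of **spatial frames** from radiology report
text: the spatial trigger (a preposition or verb such as *in*, *of*,
*terminates*) that links a finding or device to an anatomical location, and
the nine frame elements (FEs) that participate in the relation — Figure,
Ground, Hedge, Diagnosis, Position status, Relative position, Distance,
Reason and Associated process.

The package is aimed at clinical-NLP practitioners who need fine-grained
spatial labels from reports **without hand-annotated training data**. It
implements the data-programming recipe end to end:

1. **Lexicons** — category-typed dictionaries of radiological entities
   (findings, anatomy, devices, descriptors, hedges, …) and spatial
   triggers, with rule-based expansion (prepend phrases such as *area of*,
   descriptor concatenations such as *petechial hemorrhage*, plural forms).
2. **Candidate generation** — longest-match dictionary tagging (with the
   location-descriptor exception), distance and vertebral-segment regexes,
   and the cross product of {trigger, entity} pairs per sentence.
3. **Labeling functions (LFs)** — 19 deterministic heuristics that each
   vote one FE label for a candidate pair or abstain.
4. **Generative label model** — a one-coin Dawid–Skene model with
   abstention, fitted by EM, that estimates each LF's unobserved accuracy
   `alpha_j` and aggregates the votes into one probabilistic label per pair:

   `P(y = k | votes) ∝ pi_k * prod_j [ alpha_j if v_j = k else (1 - alpha_j)/(K-1) ]`

   over the K = 9 labels, skipping abstaining LFs.
5. **Filtering and BIO conversion** — trigger-level instances must carry
   both Figure and Ground (or Ground only, in evaluation mode) and pass a
   frequent-phrase blocklist; survivors become BIO tag sequences with the
   trigger masked as `$sptrg$`.
6. **Sequence tagger** — an averaged-perceptron baseline with
   BIO-constrained greedy decoding (a transformer backend is specified as
   an adapter contract).
7. **Evaluation** — strict-span trigger and FE scoring with end-to-end
   accounting: FEs predicted under false-positive triggers count as false
   positives, FEs under missed triggers as false negatives.

A synthetic sentence generator with exact gold frames (module
`radspatial.synth`) makes every stage testable without access to real
reports.

## Worked example

```python
import radspatial as rs

reports = [
    "There is hazy opacity of the lung consistent with hyaline membrane disease.",
    "A right PIC catheter terminates in the mid SVC.",
    "ETT tube is 1 cm above the carina.",
]
sentences = [rs.tokenize(text, "demo", i) for i, text in enumerate(reports)]
result = rs.weak_label(sentences)   # tag -> LFs -> label model -> filters

for inst in result.filtered:
    print(f"trigger {inst.trigger.surface!r} in: {inst.sentence.text}")
    for label, spans in sorted(inst.fe_spans.items()):
        for start, end, prob in spans:
            print(f"  {label.name:17} {inst.sentence.text[start:end]!r}  p={prob:.2f}")
```

prints

```
trigger 'of' in: There is hazy opacity of the lung consistent with hyaline membrane disease.
  FIGURE            'opacity'  p=0.70
  GROUND            'lung'  p=1.00
  HEDGE             'consistent with'  p=1.00
  DIAGNOSIS         'hyaline membrane disease'  p=1.00
trigger 'in' in: A right PIC catheter terminates in the mid SVC.
  FIGURE            'PIC catheter'  p=0.70
  GROUND            'SVC'  p=1.00
  POSITION_STATUS   'terminates'  p=1.00
  RELATIVE_POSITION 'right'  p=0.99
  RELATIVE_POSITION 'mid'  p=1.00
trigger 'above' in: ETT tube is 1 cm above the carina.
  FIGURE            'ETT tube'  p=0.70
  GROUND            'carina'  p=1.00
  DISTANCE          '1 cm'  p=0.70
```

Each surviving trigger instance lists its FE spans with the label model's
posterior probability; a probability of 0.70 marks spans supported by a
single LF whose accuracy stayed at its 0.7 initialization (see
`docs/methods.md`). The instances convert to masked BIO training data with
`radspatial.instances.to_bio`, and `radspatial.tagger.train` fits the
baseline tagger on them.

The same stages are available from the shell:

```bash
radspatial synth --n 500 --seed 7 --out corpus.jsonl --gold gold.json
radspatial bio --in corpus.jsonl --out train.bio
radspatial train --bio train.bio --out model.json
```

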