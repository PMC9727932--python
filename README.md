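# abagkit

A toolkit for building and evaluating annotated corpora of **antibody (AB)**
and **antigen (AG)** mentions in biomedical abstracts. It covers the
semi-automatic corpus-construction workflow — lexicon building and
filtering, dictionary-based pre-annotation for later manual revision,
BioC-XML ↔ CoNLL-IOB conversion, stratified train/dev/test splitting — and
the evaluation side: entity-level precision/recall/F1 under exact and
relaxed matching, and inter-annotator agreement (IAA) with a category
decomposition and strict/relax F1 formulas.

## Who this is for

Groups annotating named entities in literature (here: antibody clone IDs
like `1D05` and antigen names like `PCSK9` or `human ABCC6`) who need
reproducible plumbing around the annotation work itself: a sane lexicon, a
pre-tagger whose output humans correct, reliable format conversions,
stratified splits, and honest scoring of both models and annotators.

## The statistics at the core

**Entity-level scoring.** A predicted mention is matched one-to-one against
gold mentions by *maximum* bipartite matching (never greedily), under one of
four criteria: `strict` (same span and type), `type_relax` (same span, type
ignored), `span_relax` (same type, spans need only overlap by ≥1 character),
`both_relax` (overlap, type ignored). Then

    P = TP/(TP+FP)   R = TP/(TP+FN)   F1 = 2·P·R/(P+R)

with micro scores pooled over types and documents. Optimal matching makes
relaxation provably monotone: relaxing the criterion can only raise F1.

**Inter-annotator agreement.** Annotation pairs between two annotators are
classified as FA (full agreement: same span and type), CA (concept
agreement: same span, different type), PA (partial agreement: overlapping
span, same type) or DA (disagreement: overlapping span, different type);
unpaired annotations are singles (SN). With the five categories as
percentages of all agreement units,

    strict F1 = FA / (100 − SN/2) × 100
    relax  F1 = (FA + CA + PA + DA) / (100 − SN/2) × 100

(SN is the sum of false positives and false negatives, hence the half-SN
correction). With ≥3 annotators, pairwise category counts are micro-pooled.

## Worked example

Everything below runs offline from the built-in synthetic generator, which
plants lexicon surfaces into template sentences at recorded offsets:

```sh
abag synth --seed 42 --n-docs 30 --out corpus.xml --ledger ledger.json
```

```python
import abagkit as ak

docs = ak.read_bioc("corpus.xml")
# simulate an imperfect annotator: 10% missed mentions, 10% boundary
# errors, 5% type confusions
ak.perturb_corpus(docs, ak.PerturbConfig(
    delete_rate=0.1, span_shift_rate=0.1, type_flip_rate=0.05, seed=42))

print(ak.evaluate_documents(docs, "gold", "pred", "strict").table())
```

```
Entity         Precision    Recall        F1   Support
Antibody           70.42     65.79     68.03        76
Antigen            87.25     70.27     77.84       185
Micro average      81.82     68.97     74.84       261
```

Every mention that was deleted, shifted or retyped costs strict TP, so
micro F1 drops to 74.84%. Relaxing both span and type recovers everything
that still overlaps its gold mention:

```python
print(ak.evaluate_documents(docs, "gold", "pred", "both_relax").table())
```

```
Entity         Precision    Recall        F1   Support
Antibody          100.00     82.89     90.65        76
Antigen           100.00     84.86     91.81       185
Micro average     100.00     84.29     91.48       261
```

Treating gold and perturbed sets as two annotators gives the agreement
decomposition — note its strict/relax F1 coincide with the strict and
both-relax micro F1 above, as they should on identical inputs:

```python
gold = [a for d in docs for a in d.annotations["gold"]]
pred = [a for d in docs for a in d.annotations["pred"]]
print(ak.pairwise_agreement(gold, pred).table())
```

```
   FA(%)   CA(%)   PA(%)   DA(%)   SN(%)   Strict F1    Relax F1
   68.97    4.98    9.96    0.38   15.71       74.84       91.48
```

The same workflow is available from the shell: `abag lexicon build`,
`abag tag`, `abag convert`, `abag validate`, `abag split`, `abag stats`,
`abag evaluate`, `abag iaa`, `abag synth`. Each command writes a
`*.manifest.json` recording its config, seed, config hash and version.

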