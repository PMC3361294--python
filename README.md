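# miwsd — supervised word-sense disambiguation for biomedical text

Ambiguous terms are pervasive in biomedical literature: *blood pressure* can
denote an organism function, a diagnostic procedure or a lab result; a gene
mention like *c-myc* may refer to the human or the mouse gene. `miwsd`
implements a supervised disambiguation method for such terms: it learns, from
sense-annotated example documents, which context words discriminate between
the senses, and trains an SVM on signed-weight feature vectors built from
those words. It ships a synthetic corpus generator (annotated benchmark
corpora in this area are access-restricted), a library API, and a CLI.

## The method

For a target term w with senses s₁, s₂, let C₁ and C₂ be the training
instances labeled with each sense. Every instance contributes the *n* tokens
on each side of each occurrence of w (after lowercasing, stopword removal and
Porter stemming; default window n = 5). For each context word wᵢ in the
pooled vocabulary W, count over the N training examples:

- a = examples of C₁ containing wᵢ, b = examples of C₂ containing wᵢ
- c = examples of C₁ lacking wᵢ,  d = examples of C₂ lacking wᵢ

and score each word's discriminating power by mutual information

    MI(wᵢ) = N·a / ((a+b)·(a+c))

or by the alternative ratio **M2**(wᵢ) = (a+d)/(b+c). The top-k words by
score (default k = 200) become the feature vocabulary. Each instance is then
encoded as a dense vector whose i-th entry is **+scoreᵢ** if the i-th ranked
feature word occurs in its context and **−scoreᵢ** otherwise, and an
RBF-kernel SVM is trained on these vectors. Evaluation is stratified 5-fold
cross-validation (accuracy = correct / tested, averaged over folds) against
the most-frequent-sense (mfs) baseline; the species-disambiguation task
additionally reports micro-averaged precision/recall/F1 pooled over entities.

## Worked example

The package ships a 10-instance toy corpus (5 instances per sense) with two
context words, `wp` and `wq`:

```python
from miwsd import (PreprocessConfig, count_contingency, extract_context,
                   score_mi, score_m2, select_features)
from miwsd.toy import toy_corpus

corpus = toy_corpus()
cfg = PreprocessConfig()
bags = {s: [extract_context(i, cfg) for i in corpus.classes[s]]
        for s in corpus.senses}
for c in count_contingency(bags["s1"], bags["s2"]):
    print(c.word, (c.a, c.b, c.c, c.d), "MI =", score_mi(c), " M2 =", score_m2(c))
```

prints

```
wp (4, 1, 1, 4) MI = 1.6  M2 = 4.0
wq (3, 2, 2, 3) MI = 1.2  M2 = 1.5
```

`wp` occurs in 4 of 5 first-sense instances but only 1 of 5 second-sense
instances, so it discriminates better than the more evenly spread `wq`, and
both scores rank it first. From the shell, a full generate-and-evaluate run:

```bash
miwsd simulate --seed 7 --out corpus.tsv
miwsd evaluate --corpus corpus.tsv --seed 1
```

```
fold  accuracy  precision  recall      F1  baseline
   1     1.000      1.000   1.000   1.000     0.500
   2     1.000      1.000   1.000   1.000     0.500
   3     1.000      1.000   1.000   1.000     0.500
   4     0.950      0.950   0.950   0.950     0.500
   5     1.000      1.000   1.000   1.000     0.500
mean     0.990      0.990   0.990   0.990     0.500
instances tested: 100
```

The generated corpus plants five cue words per sense (present with
probability 0.9 in their own sense, 0.1 otherwise) over a shared background
vocabulary; the learned model recovers the planted signal almost perfectly
while the mfs baseline sits at the 0.5 class balance. `miwsd train`,
`miwsd disambiguate` and `miwsd species-evaluate` cover the remaining
workflows (`--help` on any command).

Real corpora are supplied as line-delimited TSV (`id`, `target`, `sense`,
`text`, tabs/newlines in text backslash-escaped; the label `none` marks
unannotated instances, which eligibility filtering removes before training).

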