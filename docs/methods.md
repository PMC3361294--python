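# Methods

## Model and assumptions

`miwsd` treats word-sense disambiguation as supervised binary (or
one-vs-rest) text classification over a small, highly selected feature set.
The assumptions are those of windowed bag-of-words methods: the sense of an
ambiguous term is signalled by nearby content words; word order beyond window
membership is irrelevant; one document contributes one training example per
annotated instance (a document with several occurrences of the term pools the
windows of all occurrences into one context multiset).

Given classes C₁, C₂ with N = |C₁| + |C₂| training examples and per-word
presence counts (a, b, c, d), the two selection scores are

    MI = N·a / ((a+b)(a+c))        M2 = (a+d) / (b+c)

MI is a ratio of the observed co-occurrence of word and class to its
expectation under independence: it is 1 for a word whose presence is
independent of the class, and on balanced classes it reduces to 2a/(a+b),
ranging from 0 (never in C₁) to 2 (never in C₂). M2 is the ratio of
agreeing to disagreeing example counts. Counting is example-level presence:
the definitions of c and d are explicitly example-level, and the worked
example in the package's toy corpus is consistent with example-level a and b;
a per-occurrence toggle (`count_contingency(per_occurrence=True)`) is
provided but off by default (it breaks the a+c = |C₁| identity, which only
holds in presence mode).

Feature vectors are dense and signed: entry i is +scoreᵢ if ranked feature
word i is present in the instance's context, −scoreᵢ otherwise. Magnitudes
are therefore identical across instances; only the sign pattern varies. No
scaling or normalization is applied before the learner.

The learner is an RBF-kernel support-vector machine with library defaults
(scikit-learn `SVC`: C = 1.0, gamma = "scale"); "default parameters" is
implementation-relative, so the resolved values are recorded in every trained
model (`TrainedModel.learner_params`). The learner sits behind a minimal
fit/decide contract (signed margin, positive ⇒ positive sense) so any
margin-producing binary classifier can substitute.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `window` | 5 | context tokens kept on each side of a target occurrence, counted after stopword removal and stemming |
| `k` | 200 | number of selected feature words (100–300 are sensible; `--k 300` and `--scorer m2` give the two alternative configurations) |
| `scorer` | `mi` | feature-selection criterion (`mi` or `m2`) |
| `n_folds` | 5 | cross-validation folds (80/20 train/test) |
| `abstain` | 0.0 | margin threshold below which no sense is issued; 0 disables abstention |

## Numerical and procedural choices

- **Window semantics.** The window is measured in post-filter tokens
  (stopwords and stems applied first), so it always contains content words;
  `window_prefilter=True` measures it in raw tokens instead. The choice
  maximizes informative context at small windows.
- **Multi-word targets** are matched as a normalized token subsequence and
  the whole span is excised before windowing; target tokens never enter a
  context bag.
- **Tie-breaking in selection**: descending score, then descending total
  presence (a+b), then lexicographic word order — selection is invariant to
  corpus input order.
- **M2 zero denominator**: b + c = 0 ⇒ denominator 0.5, keeping the score
  finite and above every word with b + c ≥ 1.
- **Zero margin** predicts the positive (lexicographically first) sense.
- **>2 senses**: one-vs-rest, each submodel with its own sense-vs-rest
  feature selection; prediction is the argmax margin, ties to the
  lexicographically first sense.
- **mfs baseline** ties break lexicographically.
- **Folds** are stratified (class proportions per fold within one instance
  of the corpus proportions) and deterministic per seed. The reported
  accuracy is the unweighted mean over folds even when fold sizes differ by
  one. For species entities the fold count follows the scarcest species:
  exactly 3 occurrences ⇒ 3 repeats (train on 2, test on 1, per species),
  exactly 4 ⇒ leave-one-out over that species, ≥ 5 ⇒ 5-fold CV. Word-level
  reports use fractional accuracies; species reports use percentages (the
  report's `scale` field records which).
- **Abstention** (off by default) exists because precision can exceed or
  fall below recall only when some instances receive no prediction; with it
  disabled, micro precision = recall = F1 = accuracy, an identity the code
  preserves exactly (F1 is set to precision when precision equals recall, so
  no floating-point drift breaks it).
- **Porter stemmer**: implemented in-package from the classic five-step
  algorithm (with the common `bli→ble`, `logi→log` revisions), validated
  against the published example pairs. Note the algorithm is not idempotent
  in general (e.g. `reperfusion → reperfus`, whose final s a second pass
  would strip); normalization is applied exactly once per token.

## The synthetic corpus generator

The generator emulates the statistical structure the method exploits: each
sense owns `planted_words_per_sense` disjoint cue words, present in an
instance's context with probability `p_in` = 0.9 for the instance's own sense
and `p_out` = 0.1 otherwise, over a shared background vocabulary (15 words,
each present independently with probability 0.25) plus neutral filler
padding. Defaults produce 2 senses × 50 instances — the scale of one
benchmark word (100 annotated abstracts) — with `context_len` = 5 tokens a
side, matching the default analysis window. Cue words are placed innermost
(windowed-context methods presuppose that sense-indicative vocabulary
clusters near the term), so any window ≥ `context_len` sees every present
cue; sampled words beyond 2·`context_len` (rare at the defaults) spill
outward past the filler. All emitted pseudo-tokens are lowercase,
stopword-free and Porter-fixed-points, so preprocessing passes them through
unchanged and ground truth stays recoverable.

The background document frequency (0.25) is deliberately *common*, not rare.
This MI variant assigns its maximal score to any word with b = 0 regardless
of frequency (a = 1, b = 0 already gives N·a/(a·|C₁|) = N/|C₁|), so a
background of rare words would let chance class-absences outrank genuinely
planted cues and no feature-recovery guarantee could hold. At 0.25 the
probability a background word misses an entire 50-document class is ≈ 6·10⁻⁷.
This is also the generator's main departure from real corpora, where
hapax-like context words are abundant: passing tests on synthetic data
therefore demonstrate correct mechanics and recoverability of a planted
signal, not robustness of the MI ranking to rare-word noise (a known
limitation of the score itself). Other un-modelled properties of real
abstracts: topical correlation between context words, burstiness, multiple
target occurrences per document, and class imbalance (the generator is
balanced; evaluation code handles imbalance, as the tests exercise by
trimming classes).

## Problem sizes used in the checks

The test suite runs entirely on generated corpora: oracle-equivalence over
50 corpora of N ≤ 200; planted-feature recovery over 100 seeds at 50
instances/sense; separability (p_in = 1, p_out = 0) over 20 seeds and
label-shuffled null corpora over 50 seeds, both under full 5-fold CV; and the
three evaluation configurations (MI k=200, MI k=300, M2 k=300, window 5) end
to end over a generated 31-word suite of 100 instances each. These sizes
mirror the benchmark's shape (31 eligible words × 100 abstracts) at the
generator's default noise level.

## Known limitations

- The MI score's zero-b pathology above: on real corpora, rare context words
  absent by chance from one class saturate the ranking; k large enough to
  wash them out (the 200–300 defaults) mitigates but does not remove this.
- One-vs-rest reduction for >2 senses is this package's choice; the binary
  method itself does not prescribe one.
- The species task's 4-occurrence case (between the defined 3-repeat and
  5-fold rules) uses leave-one-out over that species — a boundary the task
  definition leaves open.
- `read_corpus` ingests only the native TSV; adapters from licensed corpora
  must be written by the data holder (one record per annotated document).
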