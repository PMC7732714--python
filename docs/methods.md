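# Methods

`opirisk` implements a distant-supervision pipeline for detecting posts that
combine suicidal ideation with opioid misuse in community-organized
social-media text. This note documents the models, the synthetic data the
package is validated on, the numerical choices, and the limits of what the
tests show.

## Distant supervision and the transfer protocol

No post-level human labels exist at training time. Instead, the community a
post was filed under serves as its label: posts from a suicide-support
community are treated as positive for suicidal language, posts from a
diverse set of everyday-topic communities as negative; likewise opioid
communities versus a depression community for opioid-misuse language. Two
transfer experiments are built on these proxies:

* **C1** — train suicidal-vs-control, predict on posts from the opioid
  communities. Positives are posts that combine opioid context with
  suicidal language.
* **C2** — train opioid-vs-depression, predict on posts from the
  suicide-support community. Positives combine suicidal context with
  opioid-misuse language.

Training uses a stratified 8:2 train/test split with a further 8:2
train/validation split inside the training part (64/16/20 overall). The
validation part is used only to monitor loss; there is no early stopping —
epoch counts are fixed. Target-group posts never enter training.

Out-of-context evaluation labels come from an annotation process: an odd
number of votes per post (default 3), aggregated by strict majority. Because
positives can be rare in the target group, the evaluation sample is
keyword-stratified: 500 posts of 30–500 words, of which at most 250 contain
a risk keyword or phrase. Word counts are whitespace words of the raw
title+body (punctuation-only runs excluded); this raw-word reading is
deliberate and can be changed by passing tokenized lengths instead.

Prediction records follow one orientation everywhere: **a score near 0 means
the positive / at-risk class**; the decision threshold is 0.5. Label-ratio
curves resample the labeled evaluation set with replacement to a prescribed
positive prevalence r and re-measure accuracy; in expectation the curve is
r·a⁺ + (1−r)·a⁻ for class-conditional accuracies a⁺, a⁻, which the test
suite verifies.

## Text processing

Normalization is minimal, preserving the structure of the language: the text
is lowercased, URLs are removed, and every punctuation mark except
`. , ! ? '` is dropped. Retained marks become standalone tokens; apostrophes
flanked by word characters stay inside the word (`what's` is one token).
There is no stemming, stop-word, or profanity removal. The title is
prepended to the body with a single space. Tokens are integer-encoded
against a frequency-ordered vocabulary (index 0 = padding, 1 =
out-of-vocabulary; ties in frequency break lexicographically) and zero
padded or truncated to a fixed length, default 1500. A rerun restricted to
posts above a word-count threshold is a corpus filter, not a separate
pipeline.

## Input representations

* **TF-IDF** — the 100 most frequent in-sample unigrams+bigrams (ties
  lexicographic), raw term counts × smoothed idf `ln((1+N)/(1+df))+1`,
  L2-normalized rows (scikit-learn's convention). The low dimension is read
  as a max-features cap; an SVD alternative was considered and not adopted.
* **Word embeddings (w2v)** — 100-dimensional skip-gram with negative
  sampling trained on the training split, implemented in numpy: symmetric
  window 5, 5 negatives from the unigram^0.75 distribution, 3 epochs,
  minibatch 4096 with dense Adam updates (lr 0.05). Dense Adam is what
  keeps summed same-token updates inside a vectorized batch stable; corpora
  with more than 2×10⁶ co-occurrence pairs are uniformly subsampled per
  epoch. Traditional classifiers consume the mean-pooled vectors; sequence
  models learn their own embedding layer instead (below).
* **Pretrained vectors (GloVe-style)** — loaded from word-per-line text
  files; all out-of-file tokens share one fixed random vector drawn from
  the seed. Combinations that need a pretrained file are skipped (with a
  logged reason) when none is supplied; no vector file ships with the
  package.
* **char2vec** — fixed random per-character vectors (seeded), mean-pooled
  per token. The token-level dimension is tied to the word-embedding
  dimension so the two concatenate position-wise. The character table is
  not trained: a fixed random projection of character composition is enough
  to separate orthographic variants, keeps determinism trivial, and the
  mean-pooling makes anagrams collide by construction (a documented,
  accepted artifact).

For traditional models a document vector is the concatenation of the TF-IDF
block and the mean-pooled embedding blocks; for sequence models the
per-position input is the learned word embedding (⊕ char vector), and the
TF-IDF block enters as a document-level side vector concatenated before the
final dense layers. Consequently, for sequence models the TFIDF-only
combination and TFIDF+W2V coincide architecturally — the learned embedding
sequence is always present.

## Classifier families

Three traditional families are scikit-learn models on document vectors, with
hyperparameters the data source does not pin down set to common defaults
(all configurable): logistic regression (L2, C=1), random forest (100
trees), SVM (RBF, probability calibration). Four sequence models are
implemented in numpy (`opirisk.nn`) with analytic backpropagation verified
against finite differences in the test suite:

* **CNN** — one convolution layer with filter widths **3 and 8** (the wide
  filter suits long documents), 100 filters per width, ReLU, max pooling
  over time, one dense ReLU layer (100 units), softmax output. The
  embedding layer is 100-dimensional, randomly initialized, learned during
  training, with dropout 0.5; batch size 512, 6 epochs, cross-entropy loss.
  The single dense layer between pooling and output, and 100 filters per
  width, are this package's choices where the architecture is otherwise
  underdetermined.
* **RNN** — a single-layer LSTM (hidden 100); the hidden state at the last
  real token feeds the softmax. Padded steps carry state unchanged.
  Forget-gate biases start at 1.
* **ATTENTION** — bidirectional LSTM (hidden 100 per direction) with
  additive tanh attention over the per-step states; the attention-weighted
  context vector feeds the softmax.
* **FAST** — a fastText-style bag-of-n-grams model: word (and explicit
  bigram; hashing is unnecessary at this scale) embeddings averaged into a
  text vector, then a linear softmax.

All sequence models train with Adam (lr 10⁻³; 5×10⁻² works better for the
shallow FAST model and is its default in examples), float32 arithmetic,
batch 512, 6 epochs, seeded and single-threaded for determinism. A
non-finite loss raises immediately with epoch/batch context. Evaluation
reports accuracy, precision/recall/F1 for the positive class (macro
averaging by flag), and rank-based AUC on the oriented scores; AUC is
reported missing for single-class test sets.

## Boosted ensemble

On out-of-context data the families err at opposite extremes — sequence
models over-call the positive class, traditional models under-call it — so
their probability scores are complementary. Discrete AdaBoost with
depth-1 decision trees (50 rounds) over the score columns, against the
majority-rule reference labels, is refit over 5 reshuffled 8:2 splits; the
mean held-out accuracy is reported. A learner's contribution share is its
column's impurity-based importance summed over rounds and normalized to 1 —
the standard reading of "contribution" for stump ensembles. Raw
probabilities, not thresholded predictions, are boosted.

## Content analysis

Posts a model predicts positive are summarized by a bigram-phrase
embedding: adjacent pairs scoring
`(count(ab) − δ)·N / (count(a)·count(b)) ≥ threshold` (δ = min_count,
default 5; threshold default 10) merge to single underscore-joined tokens;
a skip-gram embedding is trained per model on the merged streams; the top-k
(default 15) cosine neighbours of a seed word (default "suicidal") are
reported, query excluded, ties lexicographic. One embedding per model's
predictions, matching the per-model structure of the analysis.

## The synthetic corpus generator

The real corpora are not redistributable, so the package ships a generator
whose outputs have known ground truth. It is a group-conditioned topic
mixture with unigram-plus-keyphrase emission over five content lexicons
(suicidal, opioid, withdrawal, control-diverse, negative-affect, plus a
small positive register), a function-word stream, and first-person-singular
pronouns. Key behaviours:

* **Latent flags before community.** `is_suicidal`/`is_opioid` are drawn
  first (suicide-community posts are all suicidal; opioid-community posts
  all opioid-flagged; intersections at configurable rates, defaults 0.15
  for suicidal content in the opioid group and 0.2 for opioid content in
  the suicide group — plausible mid-range rates chosen once, since the
  source reports only keyword-enriched sample statistics). Intersection
  posts therefore exist in both directions, so both transfer cases are
  exercisable against truth.
* **Separability** s ∈ (0, 1]: each content word comes from the post's own
  topic mixture with probability s, otherwise from the pooled cross-topic
  lexicon. At s = 1 with disjoint lexicons, a lexicon-lookup classifier is
  exact (verified in the tests); the classifier-floor experiments use
  s = 0.9, leaving genuine lexical noise. The default is 0.8.
* **Registers.** Opioid-group posts sample an emotional register per post
  (anger/negative twice as likely as joy), emulating communities that mix
  active use, relapse anguish and recovery celebration under one label.
* **Pronoun shift** adds extra first-person-singular mass (default +0.10
  over a base rate of 0.08) to suicidal and depressed posts, reproducing
  the elevated first-person-singular usage reported for such communities.
* **Keyphrases.** Flagged posts always contain at least one on-topic
  lexicon word, and multi-word risk phrases ("want to die", drug names) are
  injected at a configurable inclusion rate (default 0.5) as atomic units
  that sentence segmentation cannot split.
* **Lengths** follow a clipped gamma-Poisson (defaults: mean 120,
  dispersion 1.0, bounds 5–1500 words), spanning short notes to long
  essays; titles are 4–10 words from the same mixture.
* **Annotators** are independent Bernoulli raters with shared
  sensitivity/specificity; majority accuracy and pairwise agreement then
  have closed forms (3p²(1−p)+p³ and p²+(1−p)²) that the test suite checks
  empirically. Correlated annotator noise is out of scope.
* Control contamination (suicidal posts misfiled in control) defaults to 0
  and is a config knob.

Everything is drawn from one `numpy` generator seeded by the config, so the
same config yields byte-identical corpora.

**What the generator does not emulate:** real vocabulary statistics (Zipf
tails, misspellings, slang drift), discourse structure beyond random
sentence breaks, topic drift within a post, community-specific style, or
correlated annotation errors. Results on this corpus validate the
*machinery* — that the pipeline recovers structure that is present — not
the real-data difficulty of the task; in particular the near-perfect
synthetic F1 scores say nothing about performance on real communities,
where lexical overlap between groups is far larger.

## Problem sizes and reproduction

The classifier-floor experiment (`scripts/acceptance.py`, and the
corresponding test) uses a 4,000-post suicidal-vs-control corpus at
separability 0.9 with sequences capped at 200 tokens — sizes chosen so the
full seven-family comparison runs on a single CPU in minutes while keeping
every family's behaviour in its asymptotic regime. The traditional families
sweep four input combinations; the sequence families use the learned
word-embedding input (their canonical one). Since the reported quantity is
the minimum over families of each family's *best* F1, restricting a
family's combination set can only lower its best score — the reported floor
is conservative. Pretrained-vector combinations are omitted because no
vector file ships with the package.

## Known limitations

* The numpy sequence models are CPU-bound and sized for corpora of
  thousands of posts; they are faithful small-scale implementations, not a
  deep-learning framework.
* SVM probability calibration uses scikit-learn's internal cross-validation
  (Platt scaling), which adds variance at small sample sizes.
* `keyword_sample` tops up from the keyword stratum when keyword-free posts
  run short, which can exceed the cap only in that degenerate case (the cap
  is otherwise binding and tested).
* The phrase detector is a single pass; phrases of three or more words
  require repeated application and are not exposed.
* Character embeddings being fixed random projections, two tokens with the
  same character multiset collide; learned character embeddings would
  distinguish them.
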