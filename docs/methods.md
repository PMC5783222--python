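# Methods

## Task and data model

An instance is a tuple (*d*, *q*, *a*, *A*): a context document *d* (token
sequence with entity mentions collapsed to single anonymized ID tokens), a
question *q* containing a placeholder token where one entity was removed,
the removed entity *a*, and the candidate set *A* — the entity IDs occurring
in *d*. Alongside *A* the builder stores *I(a,d)*, the set of positions of
each candidate's ID token in *d*; the reader's output layer aggregates
attention over exactly these positions. Candidates are restricted to
entities of the context (a pointer model can only score tokens that are
present in *d*); question-only entities are not added to *A*.

Two variants are built from one article, at most one instance per article
per variant. The title variant uses the abstract as *d* and the title as
*q*; the last-sentence variant uses the final abstract sentence as *q* and
the remaining sentences as *d*, so the question can never be read off the
context verbatim (the validator checks this contiguity property).

### Filters

An instance is kept iff (1) the answer occurs at least once in both the
context and the question and (2) |A| exceeds 20, i.e. is ≥ 21. "Exceeds" is
read strictly; the candidate count is the number of unique entity IDs in
*d*, not surface groups.

### Answer selection

When several entities occur in both *d* and *q*, the blanked entity is by
default the one whose first occurrence in *q* is earliest — a deterministic
rule that gives exactly one instance per article. A seeded `random` policy
is available; the underlying data admits no single "correct" choice, and
published examples of this construction are consistent with an arbitrary
pick. If the chosen entity occurs several times in *q*, every occurrence
becomes the placeholder, preventing answer leakage.

### Entity anonymization

Global mode assigns `@entityN` by first appearance in corpus order, one
corpus-wide injective map shared by train/validation/test — entity IDs are
deliberately **not** permuted per context, letting a model accumulate
knowledge about recurring entities across documents. Local mode renumbers
from `@entity1` inside each instance with a per-instance seeded random
order, which hides cross-context identity and is the harder evaluation
setting.

## Lexicon and tagging

The lexicon maps surface forms to canonical entity IDs; several surfaces
per ID give MeSH-style synonym resolution. Raw type labels come from two
inventories — ten extractor-style labels (Gene, Drug, Disease, Target, …)
and the sixteen top-level MeSH tree categories — and are merged into a
closed representative vocabulary: {Gene, Target, Transcription Factor} →
Gene; {Drug, Toxin, Chemical Compounds, Chemicals and Drugs [D]} →
Chemicals and Drugs [D]; {Disease, Diseases [C]} → Diseases [C]; every
other label maps to itself; anything absent or unrecognized is `Unknown`.
Only the first two merges are forced by the construction; the disease merge
is the one exactly parallel case, and no further semantics were invented.
When one entity carries both an extractor label and a MeSH category, the
extractor label wins (it is more specific) and the conflict is logged;
contradictory labels within one source are a build-time error.

Tagging is dictionary NER: greedy left-to-right longest match over token
n-grams (default cap 6), case-insensitive, anchored at token boundaries so
a surface can never match inside a longer token. The tokenizer splits on
whitespace, detaches leading/trailing punctuation, splits slash-joined
terms while keeping the slash, and preserves internal hyphens and periods
(`SRC-1`, `i.e`, `0.3`); it is idempotent on its own output, which makes
sentence spans and mention indices stable. Sentence boundaries fall after
`.`/`!`/`?` tokens except after a closed abbreviation list (al, Fig, i.e,
e.g, cf, vs, etc).

## The reader

Embedding: one row per vocabulary token (default 200 dimensions; any
configured size works, and the tests run much smaller). Rows found in a
pretrained word2vec text file are copied verbatim (case-insensitive
lookup); all remaining rows — and the per-type rows of the optional
20-dimensional type embedding — are drawn uniformly from the open interval
(−0.25, 0.25). All rows stay trainable. With type embeddings enabled, each
token's type vector (its entity's merged type, `Unknown` for non-entity
tokens and the placeholder) is concatenated to its word vector; disabled,
no type table exists at all and the forward pass is exactly the base
reader. Out-of-vocabulary tokens at prediction time map to a dedicated
`@unk` row.

Encoders: bidirectional GRUs. The context encoder yields
f_i(d) = [→h_i ; ←h_i]; the query encoder's two final states concatenate
to g(q). Attention is softmax(⟨f_i(d), g(q)⟩) over *all* document
positions (computed with max-subtraction), matching the displayed scoring
equations; candidates are then scored only through their own positions via
the pointer sum P(a|d,q) = Σ_{i∈I(a,d)} s_i. Ties in the final ranking go
to the candidate whose first document occurrence is earliest, making
predictions and gold ranks deterministic.

Training minimizes −log P(a|d,q) of the gold candidate, averaged per batch
— the canonical objective for this aggregation scheme — with Adam
(learning rate 1e-3 default, 5e-4 exposed as the documented alternative),
batch size 32, length-bucketed batches in seeded random order, global
gradient-norm clipping at 10, at most 20 epochs and early stopping after 3
epochs without validation improvement; the best-validation epoch snapshot
is returned. Everything is float64 numpy with hand-written backpropagation;
a finite-difference check (relative agreement ≤ 1e-4 on every parameter
tensor) guards the analytic gradients. Runs are bit-reproducible given the
seed on one device.

Checkpoints are JSON (config, vocabulary, type inventory, all weight
tensors): Python's float repr round-trips exactly, so save/load and
repeated CLI runs are byte-identical.

## Ensembles

Members are independently seeded readers over the same training data.
Selection keeps models whose recorded validation accuracy meets a floor
(default 0.70), sorted descending, truncated to a target size (default 8);
an empty selection is an explicit error. Prediction averages the members'
candidate distributions (post pointer-sum — the combination operates on
model outputs, not internal attentions) with equal weights; position-level
attention is averaged too, only for heatmap export. Averaging keeps the
single-model bias while reducing variance, so the ensemble should not be
worse than its best member on a task all members solve — a property the
tests check on the planted-cue task.

## Synthetic corpus generator

The generator emulates the statistical shape of real abstract corpora so
every stage is testable without downloads: per document ≈25 distinct
entities (normal around 25.6, truncated below at 21 so the candidate-count
filter passes by construction) and a configurable token count (defaults to
≈290, the full-scale shape; experiments here run at mean 120 to keep desk
runtimes small — a problem-size choice, the task is the same). Filler
tokens are Zipf-distributed over a filler vocabulary; sentence breaks are
inserted every 8–15 tokens at unit boundaries (never inside a multi-token
mention). Each entity has 1–3 surface forms, including two-token forms, so
resolution and longest-match tagging are exercised; mentions are separated
by at least one filler token, making the planted mention set exactly
recoverable by the tagger (checked against the generator's own record).

The title and the generated last sentence contain exactly one entity of
the abstract — the planted answer. With `cue_strength` *p*, each body
occurrence of the answer is preceded by a fixed cue token with probability
*p*; at *p* = 1 the rule "the entity after the cue" is a perfect oracle, so
the task is realizable and a reader should approach 100%. At *p* = 0 the
answer is drawn uniformly from the document's entities with no
distinguishing statistics **in the last-sentence variant**, whose context
excludes the answer-bearing sentence — accuracy can only be chance (1/|A|).
In the title variant the last sentence stays inside the context, so the
answer's presence there is itself a (realistic) positional signal; the
chance-level control therefore uses the last-sentence variant. Earlier
versions of the generator also gave the answer a guaranteed extra body
mention; that frequency bias was removed for the same reason — extra
mentions now go to a random 20% of entities, answer not favored.

What passing these tests shows: the construction rules, arithmetic and
optimization are correct, and the reader can exploit a localizable lexical
signal. What they do not show: performance on real biomedical language —
the generator has no syntax, semantics, anaphora or discourse structure,
so no claim about real-corpus accuracy follows from it.

## Numerical and degenerate-input choices

- Softmax uses max-subtraction; a one-position document gets probability 1.
- A candidate forced in with an empty position set scores exactly 0 (the
  validator rejects such instances upstream).
- Masked (padded) positions carry hidden state through unchanged, receive
  −∞ logits, and contribute zero gradient.
- Empty documents or questions raise before any encoding.
- Fractional splits floor the train and validation sizes and give the
  remainder to test; 100 instances at (0.8, 0.1, 0.1) split 80/10/10.
  Grouped splits never divide a source file across partitions.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-instance and per-article generators are
  seeded with (seed, index) pairs, so outputs are independent of processing
  order.

## Problem sizes used by the shipped experiments

Tests and the acceptance script run, per experiment: 500 articles at the
full corpus shape for dataset validation; 1,500–2,000 articles at token
mean 120 for learnability, with readers of hidden size 32 and word
dimension 32 (word dimension 200 is the reference configuration for real
corpora); 3-member ensembles. These sizes were chosen once as desk-scale
conditions under which every claimed property is decidable.

## Known limitations

- Dictionary tagging only: no learned NER, no abbreviation expansion, no
  nested or discontinuous mentions; longest-match is greedy, not optimal.
- The word2vec reader handles the text dialect only.
- The MEDLINE XML reader covers a minimal citation subset (PMID, title,
  abstract sections, completion/publication year).
- Training is single-device, dense-batch numpy — appropriate for the
  corpus sizes here, not for millions of instances.
- The candidate set is limited to dictionary-recognized entities; the
  model cannot produce an arbitrary word of the text as an answer.
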