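# Methods

## Problem setting

Antibody variable-region (V-region) sequences from B-cell receptor
repertoire sequencing are frequently incomplete: primer placement and read
quality cause truncation at the N-terminus (often 15 or more positions),
and ambiguous base calls leave isolated unknown residues. `ablm` trains a
masked language model on antibody amino-acid sequences and uses it to
restore these unknowns, alongside a classical baseline that copies
residues from the best-matching IMGT germline allele.

## Model

The encoder is a RoBERTa-style transformer over tokenized V-region
sequences. The vocabulary has 24 tokens: the 20 amino acids (alphabetical
order), a mask token (`*` in external notation), and pad/start/end
sentinels. Tokenized sequences carry start/end sentinels and right
padding, so a model with maximum token length `max_len` handles at most
`max_len - 2` residues; over-length input is an error, never a silent
truncation.

Layout (production defaults): learned token and positional embeddings
(positions index token slots, residue *i* sits at position *i + 1*), an
embedding LayerNorm, then 12 post-norm transformer blocks with 12
attention heads, hidden size 768 and feed-forward inner size 3072;
dropout 0.1 and LayerNorm epsilon 1e-12 throughout. The prediction head
is a hidden-size dense projection with GELU and LayerNorm followed by an
output projection tied to the token-embedding matrix. Post-norm blocks
and weight tying follow the RoBERTa layout this architecture mirrors.

Three representations are exposed:

* **res-codings** — final-block hidden states at residue positions
  (`L x hidden`), special tokens dropped;
* **seq-codings** — the arithmetic mean of a sequence's res-codings, a
  fixed-length representation that needs no alignment;
* **likelihoods** — per-position distributions over the 20 amino acids;
  logits of the non-amino-acid tokens are excluded from the softmax.

## Numerical substrate

The encoder, head and training loop run on a small reverse-mode autodiff
engine over numpy (`ablm._autodiff`) written for this package: fused
primitives (LayerNorm, softmax with an additive key mask, cross-entropy)
with hand-derived vector-Jacobian products, gradient-checked against
central finite differences in the test suite. Parameters and activations
are float32. GELU uses the tanh approximation common to transformer
implementations. Attention masking adds -1e9 to padded key logits, which
makes hidden states at real positions invariant to the amount of padding
(asserted in tests at 1e-5). Inference runs under a no-grad switch and
with dropout disabled, so repeated forward passes are bit-identical.

## Pre-training objective

For each sequence in a batch, a selection fraction is drawn uniformly in
[1%, 25%]; `max(1, round(fraction x length))` positions are selected
without replacement (the lower clamp guarantees at least one supervised
position per sequence — the rounding rule is a package choice). Each
selected position is independently masked with probability 0.80, swapped
to one of the 19 *other* amino acids with 0.10, or left unchanged with
0.10; the assignment is per-position Bernoulli rather than an exact
80/10/10 partition, and corruption is redrawn at every epoch (dynamic
masking). Cross-entropy is computed only at selected positions, against
the pre-corruption residues; the gradient at unsupervised positions is
exactly zero (asserted in tests).

Optimization is Adam with decoupled weight decay 0.01 (not applied to
biases and LayerNorm parameters), betas (0.9, 0.98), eps 1e-6, linear
warm-up from zero over the first 5% of optimizer steps to a peak of
2e-4, then cosine decay to zero. Warm-up is counted in optimizer steps.
These are the production defaults; the desk-scale recipe below overrides
the peak rate.

## Restoration

*Masked-position restoration.* Likelihoods are computed once on the full
input; each `*` receives the argmax amino acid of its row (ties resolve
to the alphabetically first residue via the fixed column order). Known
residues are never altered. An input without `*` is a warned no-op.

*N-terminus length determination.* When the number of missing N-terminal
residues is unknown, a numbering-derived estimate `m` (the standard
missing count relative to IMGT position 1) anchors a candidate search
from `m - 8` to `m + 2` prepended `*`s — eight shorter to two longer,
covering indels and the 5–12-residue span of CDR1. Each candidate is
restored and scored by the likelihood of its restored *first* residue;
the highest-scoring candidate wins. The "first-residue likelihood" is
defined as the probability of the argmax residue at position 0 after that
candidate's restoration. With `rounds=2`, the round-1 additions are
stripped back to `*`, the standard length is re-derived on the round-1
restored sequence (re-centering the window on the round-1 answer), the
search repeats, and the higher-scoring outcome is kept. Negative
candidates (trimming observed leading residues, for the case where the
numbering overshoots the true start) are implemented behind an
`allow_trim` flag, off by default. Candidates are compared by raw
first-residue probability without any length normalization.

*Germline baseline.* The best allele is the one with the highest
fractional identity over IMGT positions shared between the query
numbering and the allele (non-`*` positions only; ties broken by
lexicographic allele name — a whole-V identity assignment, deliberately
simpler than a full VDJ aligner). Unknown positions are filled from the
allele's residues at the corresponding IMGT positions; positions the
allele does not cover stay `*` and are reported. By construction this
baseline predicts the *unmutated* residue, so it is exactly right on
unmutated sequences and exactly wrong at somatically mutated positions —
the property the model comparison tests rely on.

Numbering itself is a pluggable interface (`Numberer`): production users
supply an external tool's output (e.g. via the numbering-CSV adapter in
the CLI, which approximates the standard missing count as the ordinal of
the first assigned position minus one); tests use the synthetic
generator's ground-truth numberer, which also supports injecting a
systematic error to probe the robustness of the search window.

## Data preparation

Curation mirrors standard repertoire practice: records observed fewer
than three times are dropped; sequences are grouped by exact CDR3 string
(IMGT positions 105–117); each group's longest member (ties by
lexicographic id) represents it; representatives are clustered at 70%
whole-sequence identity; training/evaluation splits are seeded uniform
draws. Identity clustering is a deterministic greedy centroid pass —
sequences in descending length (ties by id), each joining the first
centroid at or above the threshold — with identity defined as matches
divided by global-alignment length (gap columns count against identity;
alignment via Biopython's PairwiseAligner, match +1, mismatch -1, gap
open -2, extend -0.5). This stands in for k-mer-based clustering tools at
desk scale: the contract is the clustering semantics, not their
heuristics, and a brute-force small-instance reference defines
correctness in the tests.

## Synthetic data

The generator emulates repertoire reads with known ground truth. Each
sequence picks an allele uniformly from a bundled toy germline set (six
heavy and six light hand-constructed, IMGT-gapped V-region alleles of
105–117 residues; plausible but deliberately *not* copies of any germline
database record), applies independent per-residue substitutions at
`mutation_rate` (default 0.03, uniform over the 19 alternatives), draws
an N-terminal truncation, and with probability `ambiguous_rate` (default
0.01) replaces one internal residue with `*`. The default truncation
distribution puts 0.20 at zero, a geometrically decaying profile over
1–14, and 0.43 total on 15–30 — shaped to the reported prevalence of
N-terminal loss in public repertoire data (~80% missing more than one
residue, ~43% missing the first 15). Truncations are capped so CDR3 and
framework 4 always survive.

What it does **not** emulate: somatic-hypermutation hotspots and
transition bias (mutations here are position-independent), insertions and
deletions, VDJ junction diversity (CDR3 varies only through point
mutations), allele usage imbalance, and paired chains. Passing tests
therefore demonstrate that the algorithms are implemented correctly and
that the model learns the germline/mutation structure the generator
contains — not that production accuracy on real repertoires would match.

## Desk-scale study conditions

The test suite exercises every contract at a reduced scale chosen to keep
the full run on one CPU practical:

* tiny encoder: 2 blocks, 4 heads, hidden 64, inner 256, max length 160;
* training corpus: 2,000 synthetic heavy sequences from 5 germline
  alleles at 3% mutation, drawn with the generator's *default* truncation
  profile and no ambiguous residues (corruption requires `*`-free input);
  200 held-out sequences;
* 30 epochs, batch 64, peak learning rate 1e-3, dropout 0 — the higher
  peak rate and disabled dropout suit the short schedule and small
  corpus; all other optimizer settings as in production.

Training on the truncation mix matters for the N-terminus search, not
just for realism (public repertoire corpora are themselves mostly
truncated). A model trained only on complete sequences learns a
near-deterministic residue prior at position 1 and assigns almost the
same first-residue likelihood to every candidate length, so the search
degenerates into tie-breaking noise. With truncated reads in the corpus
the first residue is genuinely uncertain a priori, the model must infer
it from how the observed suffix aligns with the germline repertoire, and
only the correctly sized candidate reproduces a masked *complete* read —
which is exactly the signal the first-residue likelihood is meant to
carry. A residual ambiguity remains for shallowly truncated reads: the
"already complete" candidate scores the *observed* first residue, which
the model tends to trust, so a few short truncations are mistaken for
complete sequences.

Under these conditions the trained model's held-out masked-residue
accuracy exceeds the positional-consensus baseline, and the two-round
N-terminus search recovers the true truncation length in at least 90 of
100 seeded trials (both asserted in the acceptance tests).

## Degenerate inputs and tie-breaks

Empty sequences, symbols outside the 21-letter alphabet, unknown chain
types, and over-length sequences raise typed errors. Corruption rejects
sequences containing `*`. Restoration of a `*`-free input is a warned
no-op; N-terminus search on an input with internal `*` is an error.
Likelihood rows sum to 1 within 1e-6. All argmax and representative
selections break ties deterministically (alphabet order, lexicographic
id). Every stochastic component takes an explicit seed or Generator;
nothing reads global random state.

## Known limitations

* The autodiff engine implements exactly the operations this model needs;
  it is not a general-purpose framework (no higher-order gradients, CPU
  only).
* Germline assignment ignores the J segment and CDR3 and can tie-break
  arbitrarily between very similar alleles; it is a baseline, not a
  genotyping tool.
* The numbering-CSV adapter's standard-missing estimate ignores scheme
  gaps before the first assigned position; the ±(8, 2) search window is
  designed to absorb this slack, mirroring how the search absorbs
  indel-induced numbering error.
* Identity clustering is quadratic in the number of centroids and meant
  for desk-scale corpora, not millions of sequences.
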