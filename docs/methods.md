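# Methods

## Problem and model

Similarity searching for small molecular fragments (substituents,
R-groups) is hampered by feature sparseness: a methyl or chloro fragment
sets only a handful of fingerprint bits, so conventional descriptor
similarities carry little information. `fragvec` implements
*context-dependent* similarity: substituents are embedded as real-valued
vectors by a word-embedding model trained on analogue series, and
similarity is computed between embeddings rather than between structural
descriptors.

An analogue series (AS) is a set of compounds sharing a scaffold and
differing at one substitution site. Ordered by ascending potency (pIC50),
a series becomes a sequence of substituent tokens; the last token S_0 —
the substituent of the most potent analogue — is the retrieval target, and
S_x denotes the substituent x positions from it. Series are the
"sentences" and substituents the "words" of a CBOW (continuous bag of
words) word2vec model: each token is predicted from its neighbours within
a window, and the trained input-weight matrix W_in yields one *embedded
fragment vector* (EFV) per substituent. Substituents that co-occur in
series — typically because they lead to similar potency in a shared
structure–activity context — end up close in EFV space even when they are
structurally dissimilar.

## Queries

Two query families target S_0 of a held-out series:

- **Single-substituent query**: the EFV of S_x (global context only).
- **Weighted query (wEFV)**: a weighted average over all L non-terminal
  substituents, emphasising local series context:

      w_x  = Pot_x / (1 + exp(x − L/D))
      w'_x = w_x / Σ_{x=1..L} w_x
      wEFV = Σ_{x=1..L} w'_x · EFV_x

  Pot_x is the pIC50 of the analogue bearing S_x; D > 0 is a slope factor.
  Larger D concentrates weight on substituents close to S_0; the
  `average` scheme uses constant weights 1/L. L counts the non-terminal
  members, so the sum ranges exactly over the query substituents. The
  sigmoid is evaluated as Pot_x · σ(L/D − x), which cannot overflow.
  Negative potencies are rejected; a zero potency contributes zero weight
  with a warning; a series whose weights are all zero is an error.

Vector similarity is the Tanimoto coefficient generalised to real vectors,
T(u, v) = u·v / (‖u‖² + ‖v‖² − u·v), which is 1 exactly at u = v and can
be negative for anti-correlated vectors (values are not clamped; only the
ordering matters for search). Cosine similarity is available for
comparison. A query is scored against every vocabulary EFV; ties are
broken by lexicographic canonical SMILES so ranks are deterministic. The
query fragment is not excluded from the ranking by default (an
`exclude` argument flips this).

## Baselines

Conventional representations for the same search task:

- **Morgan**: folded circular fingerprint, bond radius 2, 1024 bits;
  bit-vector Tanimoto (two all-zero fingerprints score 0 by convention).
- **MQN**: the 42 molecular quantum numbers;
  similarity 1 / (1 + mean L1 distance).
- **CFR**: the arithmetic mean of the two.
- **MACCS** keys are exposed behind the same interface as an optional
  control but excluded from default benchmarks.

The attachment-point wildcard atom is kept in all descriptor calculations;
since the same convention applies to every fragment, similarities remain
comparable.

## Training details

The CBOW trainer is implemented in numpy and follows the canonical
word2vec recipe: mean-of-context projection, negative sampling (5 noise
draws per target from the unigram^0.75 distribution), per-token uniformly
reduced window, frequency subsampling (threshold 1e−3, inactive for the
token frequencies typical of fragment corpora), and linear learning-rate
decay from 0.025 to 1e−4 over the planned token count. Input vectors are
initialised uniformly in (−0.5/k, 0.5/k); output vectors start at zero.
All randomness flows from one seeded generator and training is
single-threaded, so a fixed seed reproduces vectors bitwise; every
effective hyperparameter is recorded in the saved model's JSON sidecar.

Defaults pin the standard configuration: vector size k = 100, window 5,
min_count 1, seed 8, single worker. Epochs deserve care: embedding quality
tracks the *total* number of SGD updates, not the number of passes, so the
conventional 5-pass default — adequate for corpora of 10^5 series — badly
underfits a desk-scale corpus of a few hundred series (at 5 passes,
within-cluster and between-cluster EFV similarities on a planted-cluster
corpus are indistinguishable). `scaled_epochs` therefore chooses
`clip(round(7e5 / n_tokens), 5, 300)` passes, which reproduces the 5-pass
convention at large scale and is used by the benchmark driver when no
explicit configuration is given.

## Benchmark protocol

Per trial: 90% of series train the model; from the remainder, up to 1000
series with at least 9 members, all of whose substituents occur in the
training vocabulary, form the test set. For each test series a query is
built (EFV-S1..S4, wEFV-D1/D2/D3, wEFV-Ave, or a descriptor baseline using
the S_1 fragment), the training vocabulary is ranked, and the rank of the
terminal substituent recorded. Five trials by default; the trial seed
drives both the split and the training seed, one model per trial is reused
across query types, and test series shorter than a query position requires
are skipped with a logged count. Ranks are histogrammed in intervals of 50
(interval edges inclusive on the right) and aggregated as mean ± sample
standard deviation across trials; the first bin (top-50) is the headline
statistic, alongside the bin's share of the vocabulary.

## Synthetic corpora

`SyntheticSpec`/`generate_corpus` plant the three statistical signals the
method exploits, with no external data:

1. **Co-occurrence clusters.** The alphabet (enumerated from a fixed
   linker × terminal-group template, canonicalized, deduplicated, then
   shuffled) is partitioned into clusters; each series samples its
   ordinary members mostly from one home cluster. Because the shuffle
   precedes partitioning, cluster membership is uncorrelated with chemical
   structure — a fingerprint baseline cannot exploit it.
2. **Terminal candidates.** The top `terminal_pool_size` members of each
   cluster's internal affinity order form a terminal pool reserved for the
   terminal position; a series draws its terminal from its home pool with
   probability `terminal_enrichment` (otherwise uniformly).
3. **Positional gradient.** The member at distance x from the terminal is
   an uninformative foreign-cluster draw with probability
   `1 − (1 − cross_cluster_noise)^x`: informativeness erodes step by step
   away from the optimised end, mirroring the mild per-position decay of
   retrieval performance observed on real corpora. Home members are
   ordered by affinity rank.

Potencies ascend from `potency_base` in steps of `potency_step` plus a
jitter drawn uniformly below `potency_step/10`, keeping the gradient
strict without ties.

Defaults — 40 clusters × 15 fragments (pool 3), 1000 series of 9–12
members, enrichment 0.9, per-step erosion 0.07, pIC50 from 5.0 in steps of
0.25 — were fixed as the package's study conditions. The erosion rate was
set from the per-position decay ratio reported for ChEMBL-scale corpora
(S_4/S_1 retrieval ≈ 0.86 ≈ 0.95³, bracketed with margin for desk-scale
counting noise); the pool is reserved for terminal positions because
optimised terminal substituents are distinctive in real series, and
allowing them as ordinary members makes the single S_1 query artificially
strong relative to multi-reference averaging.

What passing the synthetic benchmark shows: the pipeline recovers planted
co-occurrence structure and its orderings (single-query decay with
distance, embedding > fingerprint baseline, weighted average ≥ best single
query). What it does not show: absolute top-50 counts comparable to
ChEMBL-scale corpora, robustness to heavy-tailed substituent frequencies,
or chemically meaningful potency–structure relationships — none of which
the generator emulates.

## Numerical and design choices

- Potency ties in input data: stable sort, last element is the terminal.
- Split determinism: a seeded permutation; train size ⌊0.9·N⌋; a shortfall
  of qualifying test series warns and returns all of them.
- Vocabulary order: frequency-descending, then lexicographic SMILES — a
  deterministic total order.
- Out-of-vocabulary lookups raise a named error; never a silent zero
  vector.
- Rankings: deterministic lexicographic tie-break; `target_rank` is
  computed under that total order.
- Attachment points: `[*]` canonical; mapped `[*:1]` accepted and
  normalized on input.
- Weight profiles must sum to 1 within 1e−12 (enforced at construction).

## Known limitations

- The trainer is a faithful but plain-numpy CBOW: single-threaded by
  design (bit-reproducibility), so paper-scale corpora (10^5 series) train
  slowly compared to optimised C implementations.
- Embeddings are transductive: a substituent absent from training has no
  vector; there is no sub-token composition to embed novel fragments.
- The wEFV uses raw pIC50 values as weights; no shifting or normalisation
  is applied, so series with systematically higher potencies contribute
  proportionally larger raw weights (normalisation within a series removes
  this for the final profile).
- `continuous_tanimoto` and `cosine_similarity` agree in ordering for
  unit-norm vectors but differ in general; benchmark results use Tanimoto
  throughout.
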