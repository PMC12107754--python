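# fragvec

Context-dependent similarity searching for small molecular fragments
(substituents / R-groups).

Conventional fingerprint or property descriptors set very few features for
small fragments, so descriptor similarity between substituents is often
uninformative. `fragvec` instead embeds substituents as real-valued
vectors learned from *analogue series* — potency-ordered sequences of
substituents at a single substitution site — using a CBOW word2vec model
in which series are sentences and substituent SMILES tokens are words.
The resulting *embedded fragment vectors* (EFVs) place substituents that
co-occur in structure–activity contexts close together, capturing latent
(property) similarity that structural descriptors miss.

The package is aimed at cheminformatics practitioners who want to search
a substituent vocabulary for candidates likely to improve potency: given
a series S_L < … < S_1 < S_0 ordered by ascending pIC50, it searches for
the terminal (most potent) substituent S_0 using either

- the EFV of a single substituent S_x, or
- a weighted multi-reference query (wEFV) over all L non-terminal members,

      w_x  = Pot_x / (1 + exp(x − L/D)),   w'_x = w_x / Σ w_x,
      wEFV = Σ_{x=1..L} w'_x · EFV_x,

where Pot_x is the pIC50 of the analogue bearing S_x and the slope factor
D controls how strongly weight concentrates near the potent end. The
vocabulary is ranked by the Tanimoto coefficient for real-valued vectors,
T(u, v) = u·v / (‖u‖² + ‖v‖² − u·v). Baselines for comparison: Morgan
fingerprint (radius 2, 1024 bits, bit Tanimoto), the 42 molecular quantum
numbers (MQN, similarity 1/(1 + mean L1 distance)), and their mean (CFR).

A synthetic corpus generator plants the co-occurrence structure the
method exploits (clusters, terminal-candidate pools, and a positional
informativeness gradient), so training, querying and benchmarking are
fully testable without external data. See `docs/methods.md` for the model
and design details.

## Worked example

Weight profiles on an 11-member series (10 query substituents), then a
five-trial terminal-substituent retrieval benchmark on the default
synthetic corpus (1000 series, 600-fragment vocabulary):

```python
import numpy as np
from fragvec import (
    AnalogueSeries, Fragment, SyntheticSpec, WeightScheme,
    generate_corpus, normalized_weights, rank_histogram,
    run_benchmark, top_bin_summary,
)

pool = ["[*]C", "[*]CC", "[*]CCC", "[*]O", "[*]OC", "[*]N", "[*]F",
        "[*]Cl", "[*]Br", "[*]C#N", "[*]c1ccccc1"]
rng = np.random.default_rng(42)
pots = np.sort(5.0 + 4.0 * rng.random(11))
series = AnalogueSeries(
    "ex", [(Fragment.from_smiles(s), float(p)) for s, p in zip(pool, pots)]
)
for d in (1.0, 2.0, 3.0):
    w = normalized_weights(series, WeightScheme("slope", d)).normalized
    print(f"D={d:.0f}  w'_1={w[0]:.3f}  w'_5={w[4]:.3f}  "
          f"w'_10={w[9]:.5f}  sum={sum(w):.1f}")

corpus = generate_corpus(SyntheticSpec(seed=1))
results = run_benchmark(
    corpus, ["efv-s1", "efv-s4", "wefv-d2", "wefv-ave", "morgan"],
    n_trials=5, base_seed=100,
)
vocab = results["efv-s1"][0].vocab_size
n_test = len(results["efv-s1"][0].ranks)
print(f"vocabulary {vocab}, {n_test} test series, "
      f"random top-50 expectation {50 / vocab * n_test:.1f}")
for qt, trials in results.items():
    hist = rank_histogram(trials)
    top, pct = top_bin_summary(hist, vocab)
    print(f"{qt:9s} top-50 mean {top:5.1f} +/- {hist.std[0]:.1f}")
```

Output (a few minutes on one CPU):

```
D=1  w'_1=0.128  w'_5=0.117  w'_10=0.04075  sum=1.0
D=2  w'_1=0.230  w'_5=0.108  w'_10=0.00100  sum=1.0
D=3  w'_1=0.327  w'_5=0.053  w'_10=0.00029  sum=1.0
vocabulary 600, 100 test series, random top-50 expectation 8.3
efv-s1    top-50 mean  83.6 +/- 5.1
efv-s4    top-50 mean  69.0 +/- 3.7
wefv-d2   top-50 mean  90.4 +/- 4.6
wefv-ave  top-50 mean  89.6 +/- 5.1
morgan    top-50 mean   7.8 +/- 2.5
```

Reading the numbers: normalized weights always sum to 1, and a larger
slope factor D shifts weight toward the substituent adjacent to the
target (w'_1 grows, w'_10 vanishes). In the benchmark, a random ranking
would place ~8 of 100 terminal substituents in the top 50; the
single-substituent embedding query finds ~84, decaying with the query's
distance from the target (S_4: 69), the weighted multi-reference queries
do better still (~90), and the Morgan fingerprint baseline stays at
chance — the planted series context is invisible to structural
descriptors.

## Command line

```sh
fragvec simulate --out corpus.csv                 # synthetic corpus (CSV)
fragvec train --corpus corpus.csv --out model.w2v # CBOW training
fragvec search --model model.w2v --query '[*]CCO' --top 10
fragvec benchmark --corpus corpus.csv --query-type efv-s1 \
    --query-type wefv-d2 --trials 5 --seed 0 --out bench/
```

Corpora are CSV long tables (`series_id,smiles,pic50`; a compact
one-series-per-line text format is also supported); models are saved in
the word2vec text format with a JSON sidecar recording every effective
hyperparameter.

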