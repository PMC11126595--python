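# Methods

## Model and scope

`bilink` treats a probiotic–disease association table as an undirected
two-mode network: part A (probiotics) and part B (diseases) with edges only
between parts. Node identifiers are opaque trimmed strings — no ICD-10
parsing or taxonomy normalisation — and isolated nodes are first-class
(holding out all edges of a node must not delete it). Link prediction is
strictly cross-part: within-part similarity (probiotic–probiotic,
disease–disease) is out of scope.

## Scoring

Because Γ(x) and Γ(y) of a cross-part pair lie in opposite parts, each score
uses the two-hop set Γ(Γ(·)) and averages the two one-sided overlap terms,
which makes every score symmetric in its arguments. Conventions that the
formulas alone do not fix:

* **Γ(Γ(x)) retains x itself** whenever x is two-hop reachable. Excluding it
  would change nothing for cross-part scoring — the intersections pair
  Γ(·) of one part with Γ(Γ(·)) of the same part, and x can appear only on
  its own side — so the simplest definition is kept.
* **AA logarithm**: natural log by default (the Adamic/Adar convention); the
  base is an explicit knob (`log_base`). Contributors z with |Γ(z)| ≤ 1 are
  skipped because 1/log 1 is undefined; this preserves non-negativity. The
  alternative smoothing 1/log(1+|Γ(z)|) was considered and rejected to keep
  the score exactly the stated formula wherever it is defined.
* **JC 0/0** (both endpoints isolated) is defined as 0: an isolated pair
  carries no evidence of affinity.
* **Ties** are broken by ascending (x, y) after descending score, everywhere.
  There is no principled ordering among equal scores; determinism of ranked
  lists and of precision@L is what matters.
* Scores of *existing* edges are computable on demand — the evaluator scores
  held-out true edges against the training network, where they are non-edges.

`rank_candidates` enumerates the zero entries of the adjacency lazily and,
when a cut-off is given, selects the top k through a bounded heap
(`heapq.nsmallest` on the key (−score, x, y)), so memory stays proportional
to k plus one streaming pass even when the candidate space has millions of
pairs. `brute_force_score` re-evaluates the formulas set-by-set from the raw
edge list with no caching and exists solely as an independent reference for
the test suite.

## Evaluation protocol

* **Folds**: the edge set is sorted canonically, shuffled once with the fold
  seed, and split into k contiguous chunks whose sizes differ by at most one.
  Nodes are never removed from the training network.
* **AUC**: n independent comparison pairs, each a uniform draw (with
  replacement) of one held-out edge and one *true* non-edge — a cross-part
  pair absent from the original network, i.e. from both the training and the
  test edge sets. AUC = (n′ + 0.5 n″)/n with n′ strict wins and n″ ties for
  the held-out edge. n defaults to 10 × fold size. `auc_exhaustive` computes
  the no-sampling limit over every (held-out edge, non-edge) pair via the
  rank-sum identity; the sampled estimator is unbiased for it, which the
  suite checks at n = 10⁵ against a 3-standard-error band.
* **Precision@L**: all candidate non-edges of the training network are
  ranked; held-out edges are candidates (they are zeros of the training
  adjacency); precision is the fraction of the top L that are held-out
  edges. L defaults to the fold size so the value is comparable across folds.
* **Aggregation**: per-fold values are averaged arithmetically (sd with
  ddof = 1); the pooled AUC (merged win/tie tallies across folds) is reported
  alongside, since either summary convention is defensible. The best method
  maximises mean AUC, ties broken by mean precision then method name.
* **Randomness**: one integer seed per run. Fold splitting and each
  (fold, method) AUC sampler draw from separately derived `SeedSequence`
  substreams, so changing the sample count n never changes the folds, and two
  runs with the same seed produce byte-identical reports.

## Synthetic networks

The generator draws edges independently with pair probability
p_ab ∝ w_a·w_b·(odds if a, b share a planted block), normalised so the
*expected* density equals the target exactly. Weights are log-normal with
sigma = `skew` (a single strictly-positive one-knob heavy-tail family);
blocks are assigned round-robin so they are balanced and seed-independent.
If normalisation would push any pair probability above 1 the configuration is
rejected with an error naming the offending parameters — never silently
truncated, which would quietly lower the expected density.

Two presets:

* `probio_like` emulates the gross statistics of the curated
  probiotic–disease network — density 0.08899 with parts 640/3884 (full) or
  64/388 (reduced, the default working scale) — with skew 0.20/0.25. These
  skews are the heaviest the independent-edge product model safely admits at
  this density: the real network's extremes (a top hub adjacent to almost
  half the opposite part) would require pair probabilities above 1 under a
  product-form model, so the preset reproduces *qualitative* right-skew
  (hubs a few-fold above the mean degree, a population of degree ≤ 1 nodes),
  not the empirical extremes. The reduced preset's realised density is
  calibrated within three binomial standard errors of the target; the
  binomial band is conservative because heterogeneous pair probabilities only
  shrink the variance of the edge count.
* `planted` (40 × 60 nodes, density 0.10, 4 blocks, within-block odds 20) is
  **not** modelled on any real data. It exists because a homogeneous random
  bipartite graph contains no learnable structure: planting blocks gives the
  neighbourhood scores real signal, so evaluation tests can assert that CN
  beats PA and clears chance by a margin (frozen from a seeded pilot at mean
  CN AUC > 0.65; pilot runs across seeds gave CN ≈ 0.70–0.78, PA ≈ 0.41–0.48).

What passing tests on these generators shows — and does not. They verify the
estimator algebra, the protocol plumbing and that the scores detect planted
shared structure. They do not certify performance on the real curated
network: synthetic degree skew is milder than the real one, there is no
correlation structure beyond blocks, and no annotation noise. Headline
metrics on the real database (e.g. AUC near 0.96) are therefore outside what
this repository can or does reproduce.

## Numerical and I/O choices

* All internal arithmetic is at full precision; display rounding (density to
  five decimals, average degree to the nearest integer) is applied only in
  serialisation, mirroring how such tables are conventionally printed.
* TSV serialisation prints floats with `repr`, so round-trips are exact.
* Edge lists are UTF-8 CSV/TSV, delimiter auto-detected (tab beats comma),
  optional header, `#` lines treated as provenance comments. Duplicate rows
  collapse with a logged count; a malformed row fails with its line number; an
  identifier appearing in both columns is a hard error.
* Degenerate inputs: empty part → density undefined error; fewer edges than
  folds → infeasible-split error; no true non-edge → sampling-impossible
  error; AUC with n < 1 or precision with L ≤ 0 or L beyond the candidate
  count → value errors.

## Known limitations

* Only the four neighbourhood formulas are implemented; no path-based,
  stochastic or supervised scorers, and no resource-allocation variant.
* The generator cannot reach the real network's extreme hub degrees at the
  real density (see above) and does not fit the empirical degree sequence.
* Precision on sparse, weak-signal instances is intrinsically small when the
  candidate space dwarfs the fold size; the planted benchmark's precision
  values (~0.03–0.07) reflect that geometry, not a defect of the protocol.
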