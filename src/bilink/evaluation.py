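"""Edge-holdout cross-validation with sampled-pair AUC and precision@L.

The protocol: partition the edge set into k disjoint folds (default 10); in
each round remove one fold from the network, score with a ranking formula on
the remaining edges, and measure

* **AUC** — over n independently sampled comparison pairs, each matching a
  uniformly drawn held-out (test) edge against a uniformly drawn true
  non-edge, AUC = (n' + 0.5 n'') / n where n' counts strict wins for the test
  edge and n'' ties. 0.5 is chance, 1 perfect separation. The non-edge
  universe is the set of cross-part pairs absent from the *original* network
  (never held-out edges), and both draws are with replacement.
* **Precision@L** — rank every candidate non-edge of the training network
  (held-out edges are candidates, being zeros of the training adjacency),
  inspect the top L (default L = |test fold|) and report the fraction that
  are held-out true edges.

``auc_exhaustive`` computes the same AUC without sampling, by comparing every
(test edge, non-edge) pair via the rank-sum identity; the sampled estimator is
unbiased for it.

All randomness flows from explicit integer seeds. Fold splitting and AUC
sampling use separately derived substreams, so changing the number of AUC
samples never changes the folds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import InfeasibleSplitError, SamplingError
from .network import BipartiteNetwork, Edge
from .scoring import ScoreMethod, rank_candidates, score

#: A scorer is either a named formula or any callable (net, x, y) -> float.
Scorer = ScoreMethod | str | Callable[[BipartiteNetwork, str, str], float]


def _resolve_scorer(method: Scorer) -> Callable[[BipartiteNetwork, str, str], float]:
    if callable(method) and not isinstance(method, ScoreMethod):
        return method
    m = ScoreMethod.parse(method) if isinstance(method, str) else method
    return lambda net, x, y: score(net, x, y, m)


def _child_seed(seed: int, *key: int) -> int:
    """Derive a deterministic 31-bit child seed from a root seed and a key path."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


# -- fold plans ------------------------------------------------------------


@dataclass(frozen=True)
class FoldPlan:
    """k disjoint edge subsets whose union is the full edge set."""

    k: int
    folds: tuple[frozenset[Edge], ...]
    seed: int

    def __post_init__(self):
        sizes = [len(f) for f in self.folds]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes differ by more than 1")


def make_folds(net: BipartiteNetwork, k: int = 10, seed: int = 0) -> FoldPlan:
    """Uniformly random partition of the edges into k near-equal folds.

    Deterministic given (network, k, seed); independent of edge iteration
    order because edges are canonically sorted before shuffling.
    """
    if k < 2:
        raise ValueError("fold count k must be >= 2")
    if net.m < k:
        raise InfeasibleSplitError(
            f"cannot split {net.m} edges into {k} non-empty folds"
        )
    edges = sorted(net.edges)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    folds = tuple(
        frozenset(edges[i] for i in chunk) for chunk in np.array_split(order, k)
    )
    return FoldPlan(k=k, folds=folds, seed=seed)


def training_network(net: BipartiteNetwork, held_out: Iterable[Edge]) -> BipartiteNetwork:
    """The network with held-out edges removed; all nodes retained, even if isolated."""
    return net.without_edges(held_out)


# -- AUC -------------------------------------------------------------------


@dataclass(frozen=True)
class AUCResult:
    """Tallies and value of the sampled-pair AUC."""

    n: int
    n_win: int
    n_tie: int
    auc: float

    def __post_init__(self):
        if self.n_win + self.n_tie > self.n:
            raise ValueError("n_win + n_tie exceeds n")
        if not math.isclose(self.auc, (self.n_win + 0.5 * self.n_tie) / self.n):
            raise ValueError("auc inconsistent with tallies")

    def to_json_dict(self) -> dict:
        return {"n": self.n, "n_win": self.n_win, "n_tie": self.n_tie, "auc": self.auc}


def _check_test_edges(
    train: BipartiteNetwork, test_edges: Sequence[Edge]
) -> list[Edge]:
    test = sorted(set(test_edges))
    for e in test:
        if train.has_edge(*e):
            raise ValueError(f"test edge {e} is still present in the training network")
    return test


def auc_sampled(
    train: BipartiteNetwork,
    test_edges: Iterable[Edge],
    method: Scorer,
    n: int,
    seed: int = 0,
) -> AUCResult:
    """Sampled-pair AUC of a scorer on held-out edges versus true non-edges.

    Draws n independent pairs (uniform test edge, uniform true non-edge, both
    with replacement), scores both on the training network and tallies strict
    wins and ties for the test edge. True non-edges are cross-part pairs absent
    from both the training and the test edge sets.
    """
    if n < 1:
        raise ValueError("sample count n must be >= 1")
    scorer = _resolve_scorer(method)
    test = _check_test_edges(train, test_edges)
    if not test:
        raise SamplingError("no test edges to sample")
    forbidden = train.edges | set(test)
    a_ids = sorted(train.part_a)
    b_ids = sorted(train.part_b)
    if len(a_ids) * len(b_ids) <= len(forbidden):
        raise SamplingError("no true non-edge exists to compare against")

    rng = np.random.default_rng(seed)
    cache: dict[Edge, float] = {}

    def cached_score(pair: Edge) -> float:
        s = cache.get(pair)
        if s is None:
            s = scorer(train, pair[0], pair[1])
            cache[pair] = s
        return s

    n_win = n_tie = 0
    for _ in range(n):
        te = test[rng.integers(len(test))]
        while True:
            pair = (a_ids[rng.integers(len(a_ids))], b_ids[rng.integers(len(b_ids))])
            if pair not in forbidden:
                break
        s_test = cached_score(te)
        s_non = cached_score(pair)
        if s_test > s_non:
            n_win += 1
        elif s_test == s_non:
            n_tie += 1
    return AUCResult(n=n, n_win=n_win, n_tie=n_tie, auc=(n_win + 0.5 * n_tie) / n)


def auc_exhaustive(
    train: BipartiteNetwork, test_edges: Iterable[Edge], method: Scorer
) -> float:
    """Exact AUC over every (test edge, true non-edge) comparison.

    Uses the rank-sum identity: with the two score samples pooled and
    mid-ranked, AUC = (R_test - n_t(n_t+1)/2) / (n_t * n_0).
    """
    scorer = _resolve_scorer(method)
    test = _check_test_edges(train, test_edges)
    if not test:
        raise SamplingError("no test edges")
    forbidden = train.edges | set(test)
    non = [p for p in ((a, b) for a in sorted(train.part_a) for b in sorted(train.part_b))
           if p not in forbidden]
    if not non:
        raise SamplingError("no true non-edge exists to compare against")
    s_test = np.array([scorer(train, *p) for p in test], dtype=float)
    s_non = np.array([scorer(train, *p) for p in non], dtype=float)
    ranks = rankdata(np.concatenate([s_test, s_non]), method="average")
    r_test = ranks[: len(s_test)].sum()
    u = r_test - len(s_test) * (len(s_test) + 1) / 2
    return float(u / (len(s_test) * len(s_non)))


# -- precision -------------------------------------------------------------


@dataclass(frozen=True)
class PrecisionResult:
    """Top-L inspection outcome: predictions inspected, hits, precision."""

    l: int
    hits: int
    precision: float

    def __post_init__(self):
        if not (0 <= self.hits <= self.l):
            raise ValueError("hits out of range")

    def to_json_dict(self) -> dict:
        return {"l": self.l, "hits": self.hits, "precision": self.precision}


def precision_at(
    train: BipartiteNetwork,
    test_edges: Iterable[Edge],
    method: Scorer,
    l: int | None = None,
) -> PrecisionResult:
    """Precision of the top-l ranked candidate non-edges against held-out edges.

    Candidates are all zero entries of the training adjacency, so held-out
    edges are rankable. Default l = |test_edges|. Deterministic under the
    score-then-lexicographic tie rule.
    """
    test = set(_check_test_edges(train, test_edges))
    if l is None:
        l = len(test)
    if l <= 0:
        raise ValueError("precision is undefined for l <= 0")
    n_candidates = train.n_a * train.n_b - train.m
    if l > n_candidates:
        raise ValueError(f"l={l} exceeds the {n_candidates} available candidates")
    if callable(method) and not isinstance(method, (ScoreMethod, str)):
        scorer = method
        import heapq

        chosen = heapq.nsmallest(
            l, ((-scorer(train, a, b), a, b) for a, b in train.non_edges())
        )
        top = [(a, b) for _, a, b in chosen]
    else:
        ranked = rank_candidates(train, method, top_k=l)
        top = [(p.x, p.y) for p in ranked]
    hits = sum(1 for pair in top if pair in test)
    return PrecisionResult(l=l, hits=hits, precision=hits / l)


# -- full protocol ---------------------------------------------------------


@dataclass(frozen=True)
class FoldOutcome:
    fold: int
    method: ScoreMethod
    auc: AUCResult
    precision: PrecisionResult


@dataclass(frozen=True)
class EvaluationReport:
    """Per-fold and aggregate results of the k-fold holdout protocol.

    ``summary`` maps method name to mean/sd of AUC and precision across folds
    (sd with ddof=1) plus the pooled AUC obtained by merging the win/tie
    tallies of all folds. ``best_method`` maximises mean AUC, ties broken by
    mean precision then method name.
    """

    outcomes: tuple[FoldOutcome, ...]
    k: int
    n_per_fold: dict[int, int]
    seed: int
    best_method: ScoreMethod
    provenance: dict = field(default_factory=dict)

    def per_method(self, method: ScoreMethod) -> list[FoldOutcome]:
        return [o for o in self.outcomes if o.method is method]

    @property
    def methods(self) -> list[ScoreMethod]:
        seen: list[ScoreMethod] = []
        for o in self.outcomes:
            if o.method not in seen:
                seen.append(o.method)
        return seen

    def summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for m in self.methods:
            rows = self.per_method(m)
            aucs = np.array([o.auc.auc for o in rows])
            precs = np.array([o.precision.precision for o in rows])
            pooled_n = sum(o.auc.n for o in rows)
            pooled = sum(o.auc.n_win + 0.5 * o.auc.n_tie for o in rows) / pooled_n
            out[m.value] = {
                "mean_auc": float(aucs.mean()),
                "sd_auc": float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
                "pooled_auc": float(pooled),
                "mean_precision": float(precs.mean()),
                "sd_precision": float(precs.std(ddof=1)) if len(precs) > 1 else 0.0,
            }
        return out

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "k": self.k,
            "seed": self.seed,
            "n_per_fold": {str(k): v for k, v in self.n_per_fold.items()},
            "best_method": self.best_method.value,
            "summary": self.summary(),
            "folds": [
                {
                    "fold": o.fold,
                    "method": o.method.value,
                    "auc": o.auc.to_json_dict(),
                    "precision": o.precision.to_json_dict(),
                }
                for o in self.outcomes
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2, sort_keys=True)

    def summary_tsv(self, provenance: str | None = None) -> str:
        lines = []
        if provenance:
            lines += [f"# {ln}" for ln in provenance.splitlines()]
        lines.append("method\tmean_auc\tsd_auc\tpooled_auc\tmean_precision\tsd_precision")
        for m, row in self.summary().items():
            lines.append(
                f"{m}\t{row['mean_auc']!r}\t{row['sd_auc']!r}\t{row['pooled_auc']!r}"
                f"\t{row['mean_precision']!r}\t{row['sd_precision']!r}"
            )
        return "\n".join(lines) + "\n"

    def long_tsv(self, provenance: str | None = None) -> str:
        """Plot-ready long format: one row per (fold, method, metric)."""
        lines = []
        if provenance:
            lines += [f"# {ln}" for ln in provenance.splitlines()]
        lines.append("fold\tmethod\tmetric\tvalue")
        for o in self.outcomes:
            lines.append(f"{o.fold}\t{o.method.value}\tauc\t{o.auc.auc!r}")
            lines.append(
                f"{o.fold}\t{o.method.value}\tprecision\t{o.precision.precision!r}"
            )
        return "\n".join(lines) + "\n"


def evaluate(
    net: BipartiteNetwork,
    methods: Sequence[ScoreMethod | str] = tuple(ScoreMethod),
    k: int = 10,
    n: int | None = None,
    seed: int = 0,
    l: int | None = None,
) -> EvaluationReport:
    """Run the full k-fold holdout protocol for the given ranking formulas.

    ``n`` is the AUC comparison-pair count per fold (default 10 x fold size);
    ``l`` the precision inspection depth (default fold size). Fully
    deterministic given the seed: two runs produce byte-identical reports.
    """
    method_list = [
        ScoreMethod.parse(m) if isinstance(m, str) else m for m in methods
    ]
    plan = make_folds(net, k=k, seed=_child_seed(seed, 0))
    outcomes: list[FoldOutcome] = []
    n_per_fold: dict[int, int] = {}
    for fi, fold in enumerate(plan.folds):
        train = training_network(net, fold)
        n_fold = n if n is not None else 10 * len(fold)
        n_per_fold[fi] = n_fold
        for mi, m in enumerate(method_list):
            auc = auc_sampled(
                train, fold, m, n=n_fold, seed=_child_seed(seed, 1, fi, mi)
            )
            prec = precision_at(train, fold, m, l=l)
            outcomes.append(FoldOutcome(fold=fi, method=m, auc=auc, precision=prec))

    # best by mean AUC, ties by mean precision, then name order
    tmp = EvaluationReport(
        outcomes=tuple(outcomes),
        k=k,
        n_per_fold=n_per_fold,
        seed=seed,
        best_method=method_list[0],
    )
    summary = tmp.summary()
    best = min(
        method_list,
        key=lambda m: (
            -summary[m.value]["mean_auc"],
            -summary[m.value]["mean_precision"],
            m.value,
        ),
    )
    provenance = {
        "k": k,
        "n": n,
        "l": l,
        "seed": seed,
        "methods": [m.value for m in method_list],
        "n_a": net.n_a,
        "n_b": net.n_b,
        "m": net.m,
    }
    return EvaluationReport(
        outcomes=tuple(outcomes),
        k=k,
        n_per_fold=n_per_fold,
        seed=seed,
        best_method=best,
        provenance=provenance,
    )
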