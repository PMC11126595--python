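"""Two-sided neighbourhood similarity scores for bipartite link prediction.

In a two-mode network a candidate pair (x, y) spans the two parts, so Γ(x) and
Γ(y) live in opposite parts and never intersect directly. The scores here use
the two-hop set Γ(Γ(·)) to measure shared structure from both sides and
average the two one-sided terms:

* CN  — (|Γ(x) ∩ Γ(Γ(y))| + |Γ(y) ∩ Γ(Γ(x))|) / 2
* JC  — CN normalised by |Γ(x) ∪ Γ(y)| (= |Γ(x)| + |Γ(y)| across parts)
* AA  — like CN but each contributing node z is weighted 1/log|Γ(z)|,
        favouring rare shared structure; degree-1 contributors are skipped
        (1/log 1 is undefined) and the log base defaults to e
* PA  — |Γ(x)| · |Γ(y)|, pure degree product, no shared structure

All four are symmetric in (x, y) and non-negative; JC is bounded by 1/2.
``brute_force_score`` re-evaluates the same formulas literally from the raw
edge set with no indexing or caching and exists as an independent reference
for testing the fast paths.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable, Iterator, Optional

from .errors import InvalidCandidateError, PartError
from .network import PART_A, BipartiteNetwork, Edge


class ScoreMethod(str, Enum):
    """The closed set of ranking formulas."""

    CN = "CN"
    JC = "JC"
    AA = "AA"
    PA = "PA"

    @classmethod
    def parse(cls, name: str) -> "ScoreMethod":
        try:
            return cls(name.upper())
        except ValueError:
            raise ValueError(
                f"unknown method {name!r}; choose from "
                + ", ".join(m.value for m in cls)
            ) from None


def _orient(net: BipartiteNetwork, x: str, y: str) -> tuple[str, str]:
    """Validate a cross-part pair and return it as (part-A node, part-B node).

    The scores are symmetric, so callers may pass the pair in either order.
    """
    px, py = net.part_of(x), net.part_of(y)
    if px == py:
        raise PartError(f"{x!r} and {y!r} are both in part {px}; need a cross-part pair")
    return (x, y) if px == PART_A else (y, x)


def score_cn(net: BipartiteNetwork, x: str, y: str) -> float:
    """Balanced common-neighbour count for a cross-part pair."""
    a, b = _orient(net, x, y)
    t1 = len(net.neighbors(a) & net.second_neighbors(b))
    t2 = len(net.neighbors(b) & net.second_neighbors(a))
    return (t1 + t2) / 2.0


def score_jc(net: BipartiteNetwork, x: str, y: str) -> float:
    """CN normalised by |Γ(x) ∪ Γ(y)|; 0 when both endpoints are isolated."""
    a, b = _orient(net, x, y)
    denom = net.degree(a) + net.degree(b)  # parts disjoint, union = sum
    if denom == 0:
        return 0.0
    return score_cn(net, a, b) / denom


def score_aa(net: BipartiteNetwork, x: str, y: str, log_base: float = math.e) -> float:
    """Balanced Adamic/Adar: contributors weighted 1/log of their degree.

    Contributors of degree <= 1 are skipped (log 1 = 0). The logarithm base is
    configurable; natural log is the conventional default.
    """
    a, b = _orient(net, x, y)

    def side(first: str, second: str) -> float:
        contributors = net.neighbors(second) & net.second_neighbors(first)
        return sum(
            1.0 / math.log(net.degree(z), log_base)
            for z in contributors
            if net.degree(z) > 1
        )

    return (side(a, b) + side(b, a)) / 2.0


def score_pa(net: BipartiteNetwork, x: str, y: str) -> float:
    """Preferential attachment: the degree product |Γ(x)|·|Γ(y)|."""
    a, b = _orient(net, x, y)
    return float(net.degree(a) * net.degree(b))


def score(
    net: BipartiteNetwork,
    x: str,
    y: str,
    method: ScoreMethod | str,
    log_base: float = math.e,
) -> float:
    """Score a cross-part pair with the chosen method (argument order agnostic)."""
    method = ScoreMethod.parse(method) if isinstance(method, str) else method
    if method is ScoreMethod.CN:
        return score_cn(net, x, y)
    if method is ScoreMethod.JC:
        return score_jc(net, x, y)
    if method is ScoreMethod.AA:
        return score_aa(net, x, y, log_base=log_base)
    return score_pa(net, x, y)


def brute_force_score(
    net: BipartiteNetwork,
    x: str,
    y: str,
    method: ScoreMethod | str,
    log_base: float = math.e,
) -> float:
    """Literal set-by-set evaluation of the ranking formulas, no caching.

    Reference implementation for testing: neighbour sets are rebuilt from the
    raw edge set on every call.
    """
    method = ScoreMethod.parse(method) if isinstance(method, str) else method
    a, b = _orient(net, x, y)
    edges = net.edges

    def nb(u: str) -> set[str]:
        out = set()
        for ea, eb in edges:
            if ea == u:
                out.add(eb)
            elif eb == u:
                out.add(ea)
        return out

    def nb2(u: str) -> set[str]:
        out: set[str] = set()
        for z in nb(u):
            out |= nb(z)
        return out

    if method is ScoreMethod.PA:
        return float(len(nb(a)) * len(nb(b)))
    if method is ScoreMethod.CN:
        return (len(nb(a) & nb2(b)) + len(nb(b) & nb2(a))) / 2.0
    if method is ScoreMethod.JC:
        union = nb(a) | nb(b)
        if not union:
            return 0.0
        return (len(nb(a) & nb2(b)) + len(nb(b) & nb2(a))) / 2.0 / len(union)
    # AA
    total = 0.0
    for z in nb(b) & nb2(a):
        if len(nb(z)) > 1:
            total += 1.0 / math.log(len(nb(z)), log_base)
    for z in nb(a) & nb2(b):
        if len(nb(z)) > 1:
            total += 1.0 / math.log(len(nb(z)), log_base)
    return total / 2.0


# -- ranked candidate generation -------------------------------------------


@dataclass(frozen=True)
class Prediction:
    """A scored candidate pair: part-A node, part-B node, method, score."""

    x: str
    y: str
    method: ScoreMethod
    score: float


TIE_RULE = "descending score, then ascending (x, y)"


@dataclass(frozen=True)
class RankedPredictions:
    """Predictions in rank order: scores non-increasing, ties by (x, y)."""

    method: ScoreMethod
    predictions: tuple[Prediction, ...]
    tie_rule: str = TIE_RULE

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self) -> Iterator[Prediction]:
        return iter(self.predictions)

    def to_tsv(self, provenance: str | None = None) -> str:
        lines = []
        if provenance:
            lines += [f"# {ln}" for ln in provenance.splitlines()]
        lines.append("x\ty\tmethod\tscore\trank")
        for rank, p in enumerate(self.predictions, start=1):
            lines.append(f"{p.x}\t{p.y}\t{p.method.value}\t{p.score!r}\t{rank}")
        return "\n".join(lines) + "\n"

    def to_json_dict(self) -> dict:
        return {
            "method": self.method.value,
            "tie_rule": self.tie_rule,
            "predictions": [
                {"x": p.x, "y": p.y, "score": p.score, "rank": r}
                for r, p in enumerate(self.predictions, start=1)
            ],
        }

    @classmethod
    def from_tsv(cls, stream: IO[str] | str) -> "RankedPredictions":
        text = stream if isinstance(stream, str) else stream.read()
        rows = [
            ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
        ]
        header, rows = rows[0], rows[1:]
        if header.split("\t") != ["x", "y", "method", "score", "rank"]:
            raise ValueError(f"unexpected prediction table header: {header!r}")
        preds = []
        method: ScoreMethod | None = None
        for ln in rows:
            x, y, m, s, _rank = ln.split("\t")
            method = ScoreMethod.parse(m)
            preds.append(Prediction(x=x, y=y, method=method, score=float(s)))
        if method is None:
            raise ValueError("prediction table has no rows")
        return cls(method=method, predictions=tuple(preds))


def rank_candidates(
    net: BipartiteNetwork,
    method: ScoreMethod | str,
    top_k: int | None = None,
    candidates: Optional[Iterable[Edge]] = None,
    log_base: float = math.e,
) -> RankedPredictions:
    """Score candidate non-edges and return them in rank order.

    By default the candidate set is every zero entry of the cross-part
    adjacency, enumerated lazily; with ``top_k`` set, selection streams through
    a bounded heap so the full candidate list is never materialised. Explicit
    ``candidates`` must be cross-part non-edges of ``net``.
    """
    method = ScoreMethod.parse(method) if isinstance(method, str) else method

    if candidates is None:
        cand_iter: Iterable[Edge] = net.non_edges()
    else:
        def checked() -> Iterator[Edge]:
            for x, y in sorted(set(candidates)):
                a, b = _orient(net, x, y)
                if net.has_edge(a, b):
                    raise InvalidCandidateError(
                        f"candidate ({a!r}, {b!r}) is an existing edge"
                    )
                yield (a, b)

        cand_iter = checked()

    def scored() -> Iterator[tuple[float, str, str]]:
        for a, b in cand_iter:
            yield (-score(net, a, b, method, log_base=log_base), a, b)

    if top_k is None:
        chosen = sorted(scored())
    elif top_k == 0:
        chosen = []
        for _ in cand_iter:  # still validate explicit candidates
            pass
    else:
        chosen = heapq.nsmallest(top_k, scored())

    return RankedPredictions(
        method=method,
        predictions=tuple(
            Prediction(x=a, y=b, method=method, score=-negscore)
            for negscore, a, b in chosen
        ),
    )
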