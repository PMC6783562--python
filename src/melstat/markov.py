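"""Per-piece nth-order transition-probability estimation and pattern ranking.

The transition probability (TP) of an interval pattern is the conditional
relative frequency of its target offset given its context: the count of the
full pattern divided by the total count of windows sharing the context.  No
smoothing of any kind is applied — an unseen pattern has probability 0 and an
obligatory continuation probability 1, which is why downstream analyses use
the empirical logit rather than the plain log-odds.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from melstat.encoding import IntervalPattern, format_pattern

__all__ = [
    "TPDistribution",
    "PieceByPatternMatrix",
    "estimate_tp",
    "empirical_logit",
    "universal_patterns",
    "tp_matrix",
    "representative_patterns",
]


@dataclass
class TPDistribution:
    """Conditional interval-transition distribution of one piece at one order.

    ``table[context][target] = (count, probability)`` with probability equal
    to count over the context's total count, exactly.  Contexts never
    observed are absent.
    """

    order: int
    piece_id: str
    table: dict[tuple[int, ...], dict[int, tuple[int, float]]]

    def context_total(self, context: tuple[int, ...]) -> int:
        return sum(c for c, _ in self.table.get(context, {}).values())

    def probability(self, pattern: IntervalPattern) -> float:
        """P(target | context) for this piece; 0.0 if never observed."""
        entry = self.table.get(pattern.context, {}).get(pattern.target)
        return entry[1] if entry is not None else 0.0

    def count(self, pattern: IntervalPattern) -> int:
        entry = self.table.get(pattern.context, {}).get(pattern.target)
        return entry[0] if entry is not None else 0

    def patterns(self) -> Iterable[IntervalPattern]:
        for context, targets in self.table.items():
            for target in targets:
                yield IntervalPattern(context + (target,))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: piece_id, order, context, target, count, probability, logit."""
        rows = []
        for context in sorted(self.table):
            total = self.context_total(context)
            for target in sorted(self.table[context]):
                count, prob = self.table[context][target]
                rows.append(
                    {
                        "piece_id": self.piece_id,
                        "order": self.order,
                        "context": "[" + ", ".join(map(str, context)) + "]",
                        "target": target,
                        "count": count,
                        "probability": prob,
                        "logit": empirical_logit(prob, total),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["piece_id", "order", "context", "target", "count", "probability", "logit"],
        )


def estimate_tp(
    ngrams: Mapping[IntervalPattern, int], order: int, piece_id: str = ""
) -> TPDistribution:
    """Conditional relative frequencies from an order-n pattern multiset.

    Every pattern in ``ngrams`` must have the given order; zero-count
    contexts are simply absent from the result.
    """
    table: dict[tuple[int, ...], dict[int, int]] = {}
    for pattern, count in ngrams.items():
        if pattern.order != order:
            raise ValueError(
                f"pattern {pattern} has order {pattern.order}, expected {order}"
            )
        table.setdefault(pattern.context, {})[pattern.target] = (
            table.get(pattern.context, {}).get(pattern.target, 0) + count
        )
    out: dict[tuple[int, ...], dict[int, tuple[int, float]]] = {}
    for context, targets in table.items():
        total = sum(targets.values())
        out[context] = {t: (c, c / total) for t, c in targets.items()}
    return TPDistribution(order=order, piece_id=piece_id, table=out)


def empirical_logit(p: float, n: int) -> float:
    """Finite log-odds of a proportion observed over ``n`` trials.

    ``ln((p*n + 0.5) / ((1 - p)*n + 0.5))`` — the half-count continuity
    correction keeps the transform finite at p = 0 and p = 1, the values raw
    TPs frequently take.  Strictly increasing in p at fixed n and odd about
    p = 0.5.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return math.log((p * n + 0.5) / ((1.0 - p) * n + 0.5))


def universal_patterns(
    distributions: Sequence[TPDistribution], order: int
) -> list[IntervalPattern]:
    """Patterns observed at least once in *every* piece of the corpus.

    Returned sorted lexicographically on offsets so the downstream sequence
    factor has a deterministic level order.  Higher orders typically return
    an empty list on realistic corpora: the pattern space grows
    exponentially and no single window survives in all pieces.
    """
    if len(distributions) < 2:
        raise ValueError("universal patterns need a corpus of >= 2 pieces")
    common: set[IntervalPattern] | None = None
    for dist in distributions:
        if dist.order != order:
            raise ValueError(
                f"distribution {dist.piece_id!r} has order {dist.order}, expected {order}"
            )
        observed = set(dist.patterns())
        common = observed if common is None else (common & observed)
        if not common:
            break
    return sorted(common, key=lambda p: p.offsets)


@dataclass
class PieceByPatternMatrix:
    """Pieces x pattern-vocabulary matrix of transition probabilities.

    ``values[i, j]`` is piece i's conditional probability of vocabulary
    pattern j (0 where the piece never saw the context or target), or its
    empirical logit when ``scale == "logit"``.  The vocabulary is the union
    over the corpus, arranged in descending mean TP (ties lexicographic).
    """

    order: int
    piece_ids: list[str]
    vocabulary: list[IntervalPattern]
    values: np.ndarray
    scale: Literal["raw", "logit"] = "raw"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.piece_ids, name="piece_id"),
            columns=[format_pattern(p) for p in self.vocabulary],
        )


def tp_matrix(
    distributions: Sequence[TPDistribution],
    order: int,
    scale: Literal["raw", "logit"] = "raw",
) -> PieceByPatternMatrix:
    """Assemble the corpus piece-by-pattern TP matrix at one order.

    On the logit scale each entry is transformed with that piece's own
    context count; a context the piece never saw contributes n = 1, giving
    the most conservative finite zero, ln(0.5/1.5).
    """
    if scale not in ("raw", "logit"):
        raise ValueError(f"scale must be 'raw' or 'logit', got {scale!r}")
    vocab: set[IntervalPattern] = set()
    for dist in distributions:
        if dist.order != order:
            raise ValueError(
                f"distribution {dist.piece_id!r} has order {dist.order}, expected {order}"
            )
        vocab.update(dist.patterns())
    vocab_list = sorted(vocab, key=lambda p: p.offsets)

    raw = np.zeros((len(distributions), len(vocab_list)))
    for i, dist in enumerate(distributions):
        for j, pattern in enumerate(vocab_list):
            raw[i, j] = dist.probability(pattern)

    # vocabulary in descending mean TP, ties lexicographic (already the
    # secondary sort order because the lexicographic sort above is stable
    # under the subsequent stable mean sort)
    mean_tp = raw.mean(axis=0)
    order_idx = np.argsort(-mean_tp, kind="stable")
    vocab_list = [vocab_list[j] for j in order_idx]
    raw = raw[:, order_idx]

    if scale == "raw":
        values = raw
    else:
        values = np.empty_like(raw)
        for i, dist in enumerate(distributions):
            for j, pattern in enumerate(vocab_list):
                n = dist.context_total(pattern.context)
                values[i, j] = empirical_logit(raw[i, j], max(n, 1))
    return PieceByPatternMatrix(
        order=order,
        piece_ids=[d.piece_id for d in distributions],
        vocabulary=vocab_list,
        values=values,
        scale=scale,
    )


def representative_patterns(
    matrix: PieceByPatternMatrix,
    k: int,
    mean_over: Literal["all", "present"] = "all",
) -> tuple[list[tuple[IntervalPattern, float]], list[tuple[IntervalPattern, float]]]:
    """Top-k and bottom-k vocabulary patterns by mean TP across pieces.

    With ``mean_over="all"`` (default) absences count as 0 in the mean; with
    ``"present"`` the mean runs only over pieces containing the pattern.
    Ties break lexicographically on offsets.  Bottom-k is drawn from the
    vocabulary, i.e. patterns with at least one corpus occurrence.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(matrix.vocabulary):
        warnings.warn(
            f"k={k} exceeds vocabulary size {len(matrix.vocabulary)}; truncating",
            stacklevel=2,
        )
        k = len(matrix.vocabulary)
    vals = matrix.values
    if mean_over == "all":
        means = vals.mean(axis=0)
    elif mean_over == "present":
        present = vals != 0
        with np.errstate(invalid="ignore"):
            means = np.where(
                present.any(axis=0), vals.sum(axis=0) / np.maximum(present.sum(axis=0), 1), 0.0
            )
    else:
        raise ValueError(f"mean_over must be 'all' or 'present', got {mean_over!r}")

    keyed = sorted(
        zip(matrix.vocabulary, means), key=lambda pm: (-pm[1], pm[0].offsets)
    )
    top = [(p, float(m)) for p, m in keyed[:k]]
    keyed_low = sorted(
        zip(matrix.vocabulary, means), key=lambda pm: (pm[1], pm[0].offsets)
    )
    bottom = [(p, float(m)) for p, m in keyed_low[:k]]
    return top, bottom
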