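"""Entity-level evaluation under the four DDI-style matching criteria.

A predicted mention counts as a true positive under:

* **strict**  — boundary and type both exactly match a gold mention;
* **exact**   — boundary exactly matches, type ignored;
* **type**    — overlaps a gold mention of the same type (>= 1 character);
* **partial** — overlaps a gold mention, type ignored.

Matching is one-to-one: each gold and each predicted mention participates in
at most one pair.  The default assignment is greedy — gold mentions in
document order, each taking the first unconsumed qualifying prediction in
start order; an exhaustive maximum assignment is available as an oracle.
Precision, recall and F1 are reported as percentages, micro-averaged over
documents, with the zero-denominator convention P = R = F1 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .corpus import EntityMention

CRITERIA = ("strict", "exact", "type", "partial")


def _overlap(a: EntityMention, b: EntityMention) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _qualifies(criterion: str) -> Callable[[EntityMention, EntityMention], bool]:
    if criterion == "strict":
        return lambda g, p: g.start == p.start and g.end == p.end and g.type == p.type
    if criterion == "exact":
        return lambda g, p: g.start == p.start and g.end == p.end
    if criterion == "type":
        return lambda g, p: _overlap(g, p) >= 1 and g.type == p.type
    if criterion == "partial":
        return lambda g, p: _overlap(g, p) >= 1
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")


@dataclass(frozen=True)
class MatchResult:
    """Counts plus the explicit one-to-one pair assignment (gold, pred) indices."""

    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int], ...]


def match(
    gold: Sequence[EntityMention],
    pred: Sequence[EntityMention],
    criterion: str = "strict",
) -> MatchResult:
    """Greedy one-to-one matching of predictions to gold mentions."""
    ok = _qualifies(criterion)
    gold_order = sorted(range(len(gold)), key=lambda i: (gold[i].start, gold[i].end))
    pred_order = sorted(range(len(pred)), key=lambda i: (pred[i].start, pred[i].end))
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for gi in gold_order:
        for pi in pred_order:
            if pi not in used and ok(gold[gi], pred[pi]):
                used.add(pi)
                pairs.append((gi, pi))
                break
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp, pairs=tuple(pairs))


def match_optimal(
    gold: Sequence[EntityMention],
    pred: Sequence[EntityMention],
    criterion: str = "strict",
) -> MatchResult:
    """Maximum one-to-one assignment (Kuhn's augmenting-path algorithm).

    Exact for any input size; the greedy matcher is expected to agree on
    well-formed data and this serves as its oracle.
    """
    ok = _qualifies(criterion)
    adj = [
        [pi for pi in range(len(pred)) if ok(g, pred[pi])] for g in gold
    ]
    match_of_pred: dict[int, int] = {}

    def augment(gi: int, seen: set[int]) -> bool:
        for pi in adj[gi]:
            if pi in seen:
                continue
            seen.add(pi)
            if pi not in match_of_pred or augment(match_of_pred[pi], seen):
                match_of_pred[pi] = gi
                return True
        return False

    for gi in sorted(range(len(gold)), key=lambda i: (gold[i].start, gold[i].end)):
        augment(gi, set())
    pairs = tuple(sorted((gi, pi) for pi, gi in match_of_pred.items()))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp, pairs=pairs)


@dataclass(frozen=True)
class EvalScores:
    """TP/FP/FN counts with derived precision, recall and F1 (percent)."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "EvalScores") -> "EvalScores":
        return EvalScores(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def score(
    gold_docs: Sequence[Sequence[EntityMention]],
    pred_docs: Sequence[Sequence[EntityMention]],
    criterion: str = "strict",
    matcher: Callable[..., MatchResult] = match,
) -> EvalScores:
    """Micro-averaged scores over parallel per-document mention lists."""
    if len(gold_docs) != len(pred_docs):
        raise ValueError("gold/pred document count mismatch")
    total = EvalScores(0, 0, 0)
    for gold, pred in zip(gold_docs, pred_docs):
        m = matcher(gold, pred, criterion)
        total = total + EvalScores(m.tp, m.fp, m.fn)
    return total


def per_type(
    gold_docs: Sequence[Sequence[EntityMention]],
    pred_docs: Sequence[Sequence[EntityMention]],
    entity_types: Iterable[str] | None = None,
) -> dict[str, EvalScores]:
    """Strict-criterion scores restricted to each entity type."""
    if entity_types is None:
        entity_types = sorted(
            {m.type for doc in gold_docs for m in doc}
            | {m.type for doc in pred_docs for m in doc}
        )
    out = {}
    for t in entity_types:
        out[t] = score(
            [[m for m in doc if m.type == t] for doc in gold_docs],
            [[m for m in doc if m.type == t] for doc in pred_docs],
            "strict",
        )
    return out


def report(
    gold_docs: Sequence[Sequence[EntityMention]],
    pred_docs: Sequence[Sequence[EntityMention]],
) -> str:
    """TSV report: the four criteria plus per-type strict rows (P/R/F1 in %)."""
    lines = ["criterion\tP\tR\tF1"]
    for c in CRITERIA:
        s = score(gold_docs, pred_docs, c)
        lines.append(f"{c}\t{s.precision:.2f}\t{s.recall:.2f}\t{s.f1:.2f}")
    for t, s in per_type(gold_docs, pred_docs).items():
        lines.append(f"{t} (strict)\t{s.precision:.2f}\t{s.recall:.2f}\t{s.f1:.2f}")
    return "\n".join(lines)
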