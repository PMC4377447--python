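"""Feature selection by association with the coarse BILOU tag variable.

Every instantiated feature f is scored against the 5-valued coarse tag
T in {B, I, L, O, U} over token events of the training corpus (one event per
token: the set of features the token carries, and its tag):

* **Chi-square** — for each tag t, the 2x2 independence statistic over
  (feature present/absent) x (tag = t / tag != t); the feature's importance
  is the maximum over the five tags.
* **Mutual information** — the plug-in MI (in bits) of the same 2x2 table,
  again maximized over tags.
* **Information gain** — H(T) - H(T | feature present/absent) over the full
  5-valued tag variable; used directly as the importance.

Selection keeps the top fraction p of features by importance, with a stable
deterministic tie order.  Counts come from training data only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Mapping, Sequence

import numpy as np

from .corpus import TypedTag

COARSE_TAGS: tuple[str, ...] = ("B", "I", "L", "O", "U")


def collapse_tag(tag: TypedTag) -> str:
    """Drop the entity type, keeping the BILOU position letter."""
    return tag.letter


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 event counts for one (feature, tag) pair.

    ``n11``: feature present and tag = t; ``n10``: present, tag != t;
    ``n01``: absent, tag = t; ``n00``: absent, tag != t.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("negative count")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def count_contingency(
    token_features: Sequence[Collection[str]],
    tags: Sequence[str],
    feature: str,
    tag: str,
) -> ContingencyTable:
    """Count the 2x2 table for one feature and one coarse tag."""
    if len(token_features) != len(tags):
        raise ValueError("feature/tag length mismatch")
    if not token_features:
        raise ValueError("empty training data")
    n11 = n10 = n01 = n00 = 0
    for feats, t in zip(token_features, tags):
        has_f, has_t = feature in feats, t == tag
        if has_f and has_t:
            n11 += 1
        elif has_f:
            n10 += 1
        elif has_t:
            n01 += 1
        else:
            n00 += 1
    return ContingencyTable(n11, n10, n01, n00)


def chi_square(table: ContingencyTable) -> float:
    """Four-cell chi-square with expectations from the marginals.

    Zero by convention when any marginal is zero (the statistic is undefined
    and the feature or tag carries no contrast).
    """
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    obs = np.array(
        [[table.n11, table.n10], [table.n01, table.n00]], dtype=float
    )
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return 0.0
    expected = np.outer(row, col) / n
    return float(((obs - expected) ** 2 / expected).sum())


def _xlogy2(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """p * log2(p/q) with the 0*log(0) := 0 convention."""
    out = np.zeros_like(p, dtype=float)
    mask = p > 0
    out[mask] = p[mask] * np.log2(p[mask] / q[mask])
    return out


def mutual_information(table: ContingencyTable) -> float:
    """Plug-in mutual information of the 2x2 table, in bits."""
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    joint = np.array(
        [[table.n11, table.n10], [table.n01, table.n00]], dtype=float
    ) / n
    pf = joint.sum(axis=1, keepdims=True)  # P(feature present/absent)
    pt = joint.sum(axis=0, keepdims=True)  # P(tag = t / != t)
    return float(_xlogy2(joint, pf * pt).sum())


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def information_gain(
    token_features: Sequence[Collection[str]],
    tags: Sequence[str],
    feature: str,
) -> float:
    """H(T) - H(T | feature) over the 5-valued coarse tag variable, in bits."""
    if not token_features:
        raise ValueError("empty training data")
    tag_idx = {t: i for i, t in enumerate(COARSE_TAGS)}
    present = np.zeros(len(COARSE_TAGS))
    absent = np.zeros(len(COARSE_TAGS))
    for feats, t in zip(token_features, tags):
        (present if feature in feats else absent)[tag_idx[t]] += 1
    n = present.sum() + absent.sum()
    total = present + absent
    h_t = _entropy(total / n)
    h_cond = 0.0
    for part in (present, absent):
        m = part.sum()
        if m > 0:
            h_cond += (m / n) * _entropy(part / m)
    return h_t - h_cond


# ---------------------------------------------------------------------------
# Corpus-level scoring
# ---------------------------------------------------------------------------

STATISTICS = ("chi2", "mi", "ig")


@dataclass
class ImportanceTable:
    """Per-feature importance scores I(f) for one statistic."""

    statistic: str
    scores: dict[str, float]
    tag_set: tuple[str, ...] = COARSE_TAGS

    def __len__(self) -> int:
        return len(self.scores)

    def ranked(self) -> list[str]:
        """Features by score descending, serialized form ascending on ties."""
        return sorted(self.scores, key=lambda f: (-self.scores[f], f))

    def top_fraction(self, p: float) -> list[str]:
        return select_top_fraction(self, p)

    # -- TSV round-trip ---------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for f in self.ranked():
                fh.write(f"{f}\t{self.statistic}\t{self.scores[f]:.12g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ImportanceTable":
        scores: dict[str, float] = {}
        statistic = ""
        with Path(path).open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    feature, statistic, score = line.rstrip("\n").split("\t")
                    scores[feature] = float(score)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed row") from exc
        return cls(statistic=statistic, scores=scores)


def _count_matrix(
    token_features: Sequence[Collection[str]],
    tags: Sequence[str],
    tag_values: Sequence[str],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-feature x per-tag co-occurrence counts over token events."""
    tag_idx = {t: i for i, t in enumerate(tag_values)}
    feat_idx: dict[str, int] = {}
    rows: list[list[int]] = []
    tag_totals = np.zeros(len(tag_values))
    for feats, t in zip(token_features, tags):
        ti = tag_idx[t]
        tag_totals[ti] += 1
        for f in set(feats):
            i = feat_idx.setdefault(f, len(rows))
            if i == len(rows):
                rows.append([0] * len(tag_values))
            rows[i][ti] += 1
    features = [f for f, _ in sorted(feat_idx.items(), key=lambda kv: kv[1])]
    counts = np.asarray(rows, dtype=float) if rows else np.zeros((0, len(tag_values)))
    return features, counts, tag_totals


def score_features(
    token_features: Sequence[Collection[str]],
    tags: Sequence[TypedTag] | Sequence[str],
    statistic: str = "ig",
    typed: bool = False,
) -> ImportanceTable:
    """Score every feature occurring in the training tokens.

    ``tags`` may be TypedTags (collapsed to coarse letters unless
    ``typed=True``) or pre-collapsed strings.  Scoring is vectorized over the
    full feature vocabulary.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if len(token_features) != len(tags):
        raise ValueError("feature/tag length mismatch")
    if not token_features:
        raise ValueError("empty training data")

    if tags and isinstance(tags[0], TypedTag):
        labels = [str(t) if typed else collapse_tag(t) for t in tags]
    else:
        labels = [str(t) for t in tags]
    tag_values = tuple(sorted(set(labels))) if typed else COARSE_TAGS
    features, counts, tag_totals = _count_matrix(token_features, labels, tag_values)

    n = float(len(labels))
    n_f = counts.sum(axis=1)  # tokens carrying each feature

    if statistic == "ig":
        h_t = _entropy(tag_totals / n)
        present = counts
        absent = tag_totals[None, :] - counts
        scores_vec = np.full(len(features), h_t)
        for part, m in ((present, n_f), (absent, n - n_f)):
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(m[:, None] > 0, part / np.maximum(m[:, None], 1e-300), 0.0)
            h = -np.where(p > 0, p * np.log2(np.maximum(p, 1e-300)), 0.0).sum(axis=1)
            scores_vec -= (m / n) * h
        scores_vec = np.maximum(scores_vec, 0.0)  # clip float negatives
    else:
        # per-tag 2x2 tables, vectorized: dimensions (features, tags)
        n11 = counts
        n10 = n_f[:, None] - counts
        n01 = tag_totals[None, :] - counts
        n00 = n - n_f[:, None] - tag_totals[None, :] + counts
        if statistic == "chi2":
            num = n * (n11 * n00 - n10 * n01) ** 2
            den = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
            with np.errstate(divide="ignore", invalid="ignore"):
                per_tag = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        else:  # mi
            per_tag = np.zeros_like(n11)
            pf1, pf0 = n_f[:, None] / n, 1 - n_f[:, None] / n
            pt1, pt0 = tag_totals[None, :] / n, 1 - tag_totals[None, :] / n
            for cell, pf, pt in (
                (n11, pf1, pt1), (n10, pf1, pt0), (n01, pf0, pt1), (n00, pf0, pt0),
            ):
                p = cell / n
                with np.errstate(divide="ignore", invalid="ignore"):
                    term = np.where(
                        p > 0,
                        p * np.log2(np.maximum(p, 1e-300) / np.maximum(pf * pt, 1e-300)),
                        0.0,
                    )
                per_tag = per_tag + term
        scores_vec = per_tag.max(axis=1) if per_tag.size else np.zeros(0)

    return ImportanceTable(
        statistic=statistic,
        scores={f: float(s) for f, s in zip(features, scores_vec)},
        tag_set=tag_values,
    )


def importance(
    token_features: Sequence[Collection[str]],
    tags: Sequence[str],
    feature: str,
    statistic: str,
) -> float:
    """I(f) for a single feature: max-over-tags chi2/MI, or IG directly."""
    if statistic == "ig":
        return information_gain(token_features, tags, feature)
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    fn = chi_square if statistic == "chi2" else mutual_information
    return max(
        fn(count_contingency(token_features, tags, feature, t)) for t in COARSE_TAGS
    )


def fraction_to_count(n_features: int, p: float) -> int:
    """Round-to-nearest, half away from zero: 294782 at p=0.4 gives 117913."""
    if not (0 < p <= 1):
        raise ValueError(f"fraction p={p} outside (0, 1]")
    import math

    return int(math.floor(n_features * p + 0.5))


def select_top_fraction(table: ImportanceTable | Mapping[str, float], p: float) -> list[str]:
    """The top round(p * |features|) features by importance.

    Deterministic under ties: stable sort by (score descending, serialized
    feature ascending), so the subset at p1 is contained in the one at
    p2 >= p1.
    """
    if isinstance(table, ImportanceTable):
        ranked = table.ranked()
    else:
        ranked = sorted(table, key=lambda f: (-table[f], f))
    return ranked[: fraction_to_count(len(ranked), p)]
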