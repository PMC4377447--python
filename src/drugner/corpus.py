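"""Annotated-corpus containers, BILOU tag codec, and CoNLL/standoff I/O.

Drug name recognition is cast as sequence labeling: each token of a sentence
receives a BILOU tag (Begin / Inside / Last / Outside / Unit-length),
optionally typed with one of the four DDI-style entity types ``drug``,
``brand``, ``group`` and ``no-human``.  With four types the full inventory
has 4 x 4 + 1 = 17 tags.

Offsets are 0-based, half-open ``[start, end)`` character positions into the
sentence text.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: The four entity types of the DDI-style annotation scheme, in canonical order.
DEFAULT_ENTITY_TYPES: tuple[str, ...] = ("drug", "brand", "group", "no-human")

_BILOU_LETTERS = ("B", "I", "L", "U")  # O handled separately


class CorpusError(ValueError):
    """Raised for malformed annotations, tags or corpus files."""


@dataclass(frozen=True, order=True)
class Token:
    """A surface token with its character span inside the sentence."""

    text: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if not self.text:
            raise CorpusError("empty token")
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"invalid token span [{self.start}, {self.end}) for {self.text!r}"
            )


@dataclass(frozen=True, order=True)
class EntityMention:
    """A typed entity span in sentence character coordinates."""

    start: int
    end: int
    type: str
    text: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CorpusError(f"invalid mention span [{self.start}, {self.end})")

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TypedTag:
    """A BILOU position letter, typed with an entity type unless it is O."""

    letter: str
    entity_type: str | None = None

    def __post_init__(self) -> None:
        if self.letter == "O":
            if self.entity_type is not None:
                raise CorpusError("O tag carries no entity type")
        elif self.letter in _BILOU_LETTERS:
            if not self.entity_type:
                raise CorpusError(f"{self.letter} tag requires an entity type")
        else:
            raise CorpusError(f"unknown BILOU letter {self.letter!r}")

    def __str__(self) -> str:
        if self.letter == "O":
            return "O"
        return f"{self.letter}-{self.entity_type}"

    @classmethod
    def parse(cls, s: str) -> "TypedTag":
        if s == "O":
            return cls("O")
        if "-" not in s:
            raise CorpusError(f"malformed tag {s!r}")
        letter, entity_type = s.split("-", 1)
        return cls(letter, entity_type)


OUTSIDE = TypedTag("O")


@dataclass
class AnnotatedSentence:
    """A sentence with its tokens and (non-overlapping) entity mentions."""

    text: str
    tokens: list[Token]
    mentions: list[EntityMention] = field(default_factory=list)
    doc_id: str | None = None

    def __post_init__(self) -> None:
        self.mentions.sort(key=lambda m: (m.start, m.end))
        for a, b in zip(self.mentions, self.mentions[1:]):
            if a.overlaps(b):
                raise CorpusError(
                    f"overlapping mentions [{a.start},{a.end}) and "
                    f"[{b.start},{b.end}) cannot be represented with one tag per token"
                )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def words(self) -> list[str]:
        return [t.text for t in self.tokens]


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

_PUNCT_RUN = re.compile(r"([^\w\s])\1*")  # run of one repeated symbol
_ALNUM = re.compile(r"[A-Za-z0-9]")


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into tokens with character offsets.

    Whitespace-delimited chunks are kept whole when they contain letters or
    digits, except that punctuation runs are peeled off both edges.  Hyphens
    and brackets *inside* an alphanumeric chunk stay attached, so
    ``interleukin-2`` and bracketed IUPAC names survive as single tokens.
    """
    tokens: list[Token] = []

    def emit(piece: str, offset: int) -> None:
        tokens.append(Token(piece, offset, offset + len(piece), len(tokens)))

    for m in re.finditer(r"\S+", text):
        chunk, base = m.group(), m.start()
        if not _ALNUM.search(chunk):
            # pure symbols: one token per punctuation run
            for pm in _PUNCT_RUN.finditer(chunk):
                emit(pm.group(), base + pm.start())
            continue
        lo, hi = 0, len(chunk)
        while lo < hi and not chunk[lo].isalnum():
            lo += 1
        while hi > lo and not chunk[hi - 1].isalnum():
            hi -= 1
        for pm in _PUNCT_RUN.finditer(chunk[:lo]):
            emit(pm.group(), base + pm.start())
        emit(chunk[lo:hi], base + lo)
        for pm in _PUNCT_RUN.finditer(chunk[hi:]):
            emit(pm.group(), base + hi + pm.start())
    return tokens


def sentence_from_text(
    text: str,
    mentions: Iterable[tuple[int, int, str]] = (),
    doc_id: str | None = None,
) -> AnnotatedSentence:
    """Tokenize ``text`` and attach mentions given as (start, end, type)."""
    ments = [EntityMention(s, e, t, text[s:e]) for s, e, t in mentions]
    return AnnotatedSentence(text, tokenize(text), ments, doc_id=doc_id)


# ---------------------------------------------------------------------------
# Tag inventory and BILOU codec
# ---------------------------------------------------------------------------


def tag_inventory(entity_types: Sequence[str] = DEFAULT_ENTITY_TYPES) -> list[TypedTag]:
    """The ordered label space: B/I/L/U per type, plus a single O.

    For T entity types the inventory has 4T + 1 tags; the four DDI types give
    the 17-tag space.
    """
    types = list(entity_types)
    if not types:
        raise CorpusError("entity type set must be non-empty")
    if len(set(types)) != len(types):
        raise CorpusError("duplicate entity types")
    tags = [TypedTag(letter, t) for t in types for letter in _BILOU_LETTERS]
    tags.append(OUTSIDE)
    return tags


def encode_bilou(sentence: AnnotatedSentence) -> list[TypedTag]:
    """Map a sentence's mentions to one BILOU tag per token.

    A single-token mention becomes U-type; a multi-token mention becomes
    B-type, I-type*, L-type; every other token is O.  Mentions must align
    with token boundaries.
    """
    tags: list[TypedTag] = [OUTSIDE] * len(sentence.tokens)
    starts = {t.start: t.index for t in sentence.tokens}
    ends = {t.end: t.index for t in sentence.tokens}
    for m in sentence.mentions:
        if m.start not in starts or m.end not in ends:
            raise CorpusError(
                f"mention [{m.start},{m.end}) {m.text!r} crosses a token boundary"
            )
        first, last = starts[m.start], ends[m.end]
        if first == last:
            tags[first] = TypedTag("U", m.type)
        else:
            tags[first] = TypedTag("B", m.type)
            for i in range(first + 1, last):
                tags[i] = TypedTag("I", m.type)
            tags[last] = TypedTag("L", m.type)
    return tags


def decode_bilou(
    tags: Sequence[TypedTag],
    tokens: Sequence[Token],
    text: str | None = None,
    strict: bool = True,
) -> list[EntityMention]:
    """Recover entity mentions from a BILOU tag sequence.

    Inverse of :func:`encode_bilou` on valid sequences.  In strict mode an
    ill-formed sequence (I/L without an open entity, type change mid-entity,
    B/I left unclosed) raises; in lenient mode a stray I/L opens a new entity
    and an inconsistent continuation closes the entity at the last consistent
    token, with a log record per repair.
    """
    if len(tags) != len(tokens):
        raise CorpusError("tag/token length mismatch")

    mentions: list[EntityMention] = []
    open_start: int | None = None  # token index of current entity start
    open_type: str | None = None

    def span_text(i: int, j: int) -> str:
        if text is not None:
            return text[tokens[i].start : tokens[j].end]
        return " ".join(t.text for t in tokens[i : j + 1])

    def close(last_idx: int) -> None:
        nonlocal open_start, open_type
        assert open_start is not None and open_type is not None
        mentions.append(
            EntityMention(
                tokens[open_start].start,
                tokens[last_idx].end,
                open_type,
                span_text(open_start, last_idx),
            )
        )
        open_start = open_type = None

    def bad(idx: int, why: str) -> None:
        if strict:
            raise CorpusError(f"invalid BILOU sequence at token {idx}: {why}")
        logger.warning("BILOU repair at token %d: %s", idx, why)

    for i, tag in enumerate(tags):
        if tag.letter == "O":
            if open_start is not None:
                bad(i, "entity left unclosed before O")
                close(i - 1)
        elif tag.letter == "B":
            if open_start is not None:
                bad(i, "B inside an open entity")
                close(i - 1)
            open_start, open_type = i, tag.entity_type
        elif tag.letter == "U":
            if open_start is not None:
                bad(i, "U inside an open entity")
                close(i - 1)
            open_start, open_type = i, tag.entity_type
            close(i)
        elif tag.letter == "I":
            if open_start is None:
                bad(i, "I without a preceding B")
                open_start, open_type = i, tag.entity_type
            elif tag.entity_type != open_type:
                bad(i, f"type change {open_type}->{tag.entity_type} mid-entity")
                close(i - 1)
                open_start, open_type = i, tag.entity_type
        elif tag.letter == "L":
            if open_start is None:
                bad(i, "L without a preceding B")
                open_start, open_type = i, tag.entity_type
            elif tag.entity_type != open_type:
                bad(i, f"type change {open_type}->{tag.entity_type} at L")
                close(i - 1)
                open_start, open_type = i, tag.entity_type
            close(i)
    if open_start is not None:
        bad(len(tags) - 1, "entity left unclosed at sentence end")
        close(len(tags) - 1)
    return mentions


# ---------------------------------------------------------------------------
# CoNLL-style TSV
# ---------------------------------------------------------------------------


def write_conll(sentences: Iterable[AnnotatedSentence], path: str | Path) -> None:
    """Write one token per line as ``token TAB start TAB end TAB tag``.

    Sentences are separated by blank lines.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sent in sentences:
            tags = encode_bilou(sent)
            for tok, tag in zip(sent.tokens, tags):
                fh.write(f"{tok.text}\t{tok.start}\t{tok.end}\t{tag}\n")
            fh.write("\n")


def read_conll(
    path: str | Path,
    entity_types: Sequence[str] = DEFAULT_ENTITY_TYPES,
) -> list[AnnotatedSentence]:
    """Read a CoNLL-style TSV written by :func:`write_conll`.

    Sentence text is reconstructed from token offsets (gaps become spaces).
    Unknown entity types in the tag column raise with the line number.
    """
    path = Path(path)
    known = set(entity_types)
    sentences: list[AnnotatedSentence] = []
    rows: list[tuple[str, int, int, TypedTag]] = []

    def flush() -> None:
        if not rows:
            return
        length = max(end for _, _, end, _ in rows)
        chars = [" "] * length
        for text, start, end, _ in rows:
            chars[start:end] = list(text)
        sent_text = "".join(chars)
        tokens = [
            Token(text, start, end, i)
            for i, (text, start, end, _) in enumerate(rows)
        ]
        tags = [tag for *_, tag in rows]
        mentions = decode_bilou(tags, tokens, text=sent_text, strict=True)
        sentences.append(AnnotatedSentence(sent_text, tokens, mentions))
        rows.clear()

    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise CorpusError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            text, s, e, tag_s = parts
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise CorpusError(f"{path}:{lineno}: bad offsets {s!r}/{e!r}") from exc
            try:
                tag = TypedTag.parse(tag_s)
            except CorpusError as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from exc
            if tag.entity_type is not None and tag.entity_type not in known:
                raise CorpusError(
                    f"{path}:{lineno}: unknown entity type in tag {tag_s!r}"
                )
            rows.append((text, start, end, tag))
    flush()
    return sentences


# ---------------------------------------------------------------------------
# Standoff (brat-like) annotation
# ---------------------------------------------------------------------------


def write_standoff(
    sentences: Iterable[AnnotatedSentence],
    text_path: str | Path,
    ann_path: str | Path,
) -> None:
    """Write one sentence per line plus a mention TSV.

    The annotation file has one mention per line:
    ``doc-id TAB start TAB end TAB type TAB text``; offsets are relative to
    the sentence line.  Document ids default to the sentence's line number.
    """
    sentences = list(sentences)
    with Path(text_path).open("w", encoding="utf-8") as fh:
        for sent in sentences:
            fh.write(sent.text.replace("\n", " ") + "\n")
    with Path(ann_path).open("w", encoding="utf-8") as fh:
        for i, sent in enumerate(sentences):
            doc = sent.doc_id if sent.doc_id is not None else f"s{i}"
            for m in sent.mentions:
                fh.write(f"{doc}\t{m.start}\t{m.end}\t{m.type}\t{m.text}\n")


def read_standoff(
    text_path: str | Path,
    ann_path: str | Path,
    entity_types: Sequence[str] = DEFAULT_ENTITY_TYPES,
) -> list[AnnotatedSentence]:
    """Read sentences and brat-like standoff mentions back into objects."""
    known = set(entity_types)
    lines = Path(text_path).read_text(encoding="utf-8").splitlines()
    by_doc: dict[str, list[EntityMention]] = {}
    doc_order: list[str] = []
    with Path(ann_path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise CorpusError(
                    f"{ann_path}:{lineno}: expected 5 columns, got {len(parts)}"
                )
            doc, s, e, typ, text = parts
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise CorpusError(f"{ann_path}:{lineno}: bad offsets") from exc
            if typ not in known:
                raise CorpusError(f"{ann_path}:{lineno}: unknown entity type {typ!r}")
            by_doc.setdefault(doc, []).append(EntityMention(start, end, typ, text))
            if doc not in doc_order:
                doc_order.append(doc)

    # doc ids map to text lines either by the default "s{i}" naming or, for
    # externally produced files, by order of first appearance
    if not set(by_doc) <= {f"s{i}" for i in range(len(lines))}:
        if len(doc_order) > len(lines):
            raise CorpusError(f"{ann_path}: more document ids than text lines")
        by_doc = {f"s{i}": by_doc[d] for i, d in enumerate(doc_order)}

    sentences = []
    for i, text in enumerate(lines):
        doc = f"s{i}"
        mentions = by_doc.pop(doc, [])
        for m in mentions:
            if text[m.start : m.end] != m.text and m.text:
                raise CorpusError(
                    f"{ann_path}: mention text {m.text!r} does not match "
                    f"document {doc} span [{m.start},{m.end})"
                )
        sentences.append(AnnotatedSentence(text, tokenize(text), mentions, doc_id=doc))
    if by_doc:
        raise CorpusError(f"{ann_path}: annotations for unknown documents {sorted(by_doc)}")
    return sentences
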