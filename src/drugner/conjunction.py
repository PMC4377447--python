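"""Conjunction feature templates: pairing singleton features into 2-tuples.

A conjunction template names an ordered pair of (singleton template, window
offset) slots; its instantiated value is the two member values joined with
``_``.  Two stock template sets are provided:

* **S1** — same-type bigrams in the window: ``f_i[m]_f_i[m+1]`` for
  i in {1, 2, 3} (word, POS, chunk) and m in {-2, -1, 0, 1}; 12 templates.
* **S2** — cross-type pairs on the target word: every unordered pair over
  f2..f8 at offset 0 (21 pairs), plus the word paired with POS and with
  chunk; 23 templates.

Member values containing ``_`` or ``\\`` are escaped before joining so the
serialized conjunction stays unambiguous.  A conjunction whose member is
missing (a short-word affix, a disabled template) is suppressed rather than
emitted half-empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from .corpus import AnnotatedSentence
from .features import FeatureString, SentenceFeatureExtractor, TEMPLATE_IDS, WINDOW_OFFSETS

logger = logging.getLogger(__name__)

JOIN = "_"


def escape_member(value: str) -> str:
    return value.replace("\\", "\\\\").replace(JOIN, "\\_")


@dataclass(frozen=True)
class ConjunctionTemplate:
    """An ordered pair of (singleton template id, window offset) members."""

    members: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.members) != 2:
            raise ValueError("only 2-tuple conjunction templates are supported")
        for tid, off in self.members:
            if tid not in TEMPLATE_IDS:
                raise ValueError(f"unknown singleton template {tid!r}")
            if off not in WINDOW_OFFSETS:
                raise ValueError(f"offset {off} outside the [-2, 2] window")

    def __str__(self) -> str:
        return JOIN.join(f"{tid}[{off}]" for tid, off in self.members)


@dataclass
class ConjunctionTemplateSet:
    """A named list of conjunction templates (S1, S2 or custom)."""

    name: str
    templates: list[ConjunctionTemplate]

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def __add__(self, other: "ConjunctionTemplateSet") -> "ConjunctionTemplateSet":
        return ConjunctionTemplateSet(
            f"{self.name}+{other.name}", self.templates + other.templates
        )


def build_S1() -> ConjunctionTemplateSet:
    """Same-type adjacent bigrams of word, POS and chunk in the window."""
    templates = [
        ConjunctionTemplate(((f"f{i}", m), (f"f{i}", m + 1)))
        for i in (1, 2, 3)
        for m in (-2, -1, 0, 1)
    ]
    return ConjunctionTemplateSet("S1", templates)


def build_S2() -> ConjunctionTemplateSet:
    """Cross-type pairs of the target word's own features.

    All unordered pairs over f2..f8 at offset 0; the word feature f1 joins
    only with POS (f2) and chunk (f3).
    """
    templates = [
        ConjunctionTemplate((("f1", 0), ("f2", 0))),
        ConjunctionTemplate((("f1", 0), ("f3", 0))),
    ]
    templates += [
        ConjunctionTemplate(((f"f{i}", 0), (f"f{j}", 0)))
        for i in range(2, 9)
        for j in range(i + 1, 9)
    ]
    return ConjunctionTemplateSet("S2", templates)


def apply_conjunctions(
    extractor: SentenceFeatureExtractor,
    sentence: AnnotatedSentence,
    template_set: ConjunctionTemplateSet,
    base: list[dict[str, list[str]]] | None = None,
) -> list[list[FeatureString]]:
    """Instantiate every conjunction template for every token.

    ``base`` may pass pre-computed per-token singleton values to avoid
    re-extraction.  Members use the primary singleton value (BOS/EOS at the
    sentence edges); a missing member suppresses that conjunction for that
    token, with a debug log record.
    """
    if base is None:
        base = extractor.base_values(sentence)
    out: list[list[FeatureString]] = []
    for i in range(len(base)):
        feats: list[FeatureString] = []
        for tmpl in template_set:
            values = []
            for tid, off in tmpl.members:
                v = extractor.member_value(base, i, tid, off)
                if v is None:
                    logger.debug(
                        "conjunction %s suppressed at token %d: member %s[%d] missing",
                        tmpl, i, tid, off,
                    )
                    values = None
                    break
                values.append(escape_member(v))
            if values is None:
                continue
            tids = tuple(tid for tid, _ in tmpl.members)
            offs = tuple(off for _, off in tmpl.members)
            feats.append(FeatureString(tids, offs, JOIN.join(values)))
        out.append(feats)
    return out


# ---------------------------------------------------------------------------
# Custom template-set config files
# ---------------------------------------------------------------------------


def parse_template_set(spec: str, name: str = "custom") -> ConjunctionTemplateSet:
    """Parse a text spec of conjunction templates, one per line.

    Each line holds two whitespace-separated members ``fI[J]``, e.g.::

        f1[-1] f1[0]
        f15[0] f15[1]

    Blank lines and ``#`` comments are ignored.
    """
    templates = []
    for lineno, line in enumerate(spec.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected two members, got {len(parts)}")
        members = []
        for p in parts:
            if "[" not in p or not p.endswith("]"):
                raise ValueError(f"line {lineno}: malformed member {p!r}")
            tid, off_s = p[:-1].split("[", 1)
            members.append((tid, int(off_s)))
        templates.append(ConjunctionTemplate(tuple(members)))
    return ConjunctionTemplateSet(name, templates)


def load_template_set(path: str | Path, name: str | None = None) -> ConjunctionTemplateSet:
    path = Path(path)
    return parse_template_set(
        path.read_text(encoding="utf-8"), name=name or path.stem
    )
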