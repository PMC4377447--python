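"""Singleton feature templates and their expansion over the context window.

Sixteen templates are defined, mirroring the standard feature set for
CRF-based drug name recognition:

====  =========================================
id    template
====  =========================================
f1    word (the surface form itself)
f2    part-of-speech tag
f3    chunk tag
f4    orthographic class + hyphen flag
f5    DrugBank dictionary membership (Y/N)
f6    FDA dictionary membership (Y/N)
f7    Jochem dictionary membership (Y/N)
f8    word-embedding cluster id
f9    prefix of length 3
f10   prefix of length 4
f11   prefix of length 5
f12   suffix of length 3
f13   suffix of length 4
f14   suffix of length 5
f15   generalized word class (per-character shape)
f16   brief word class (run-collapsed shape)
====  =========================================

Each template is instantiated at every offset of the five-token window
(-2..+2) centered on the target word; ``f1[-1]`` is "the word before the
target".  Positions beyond the sentence edge carry BOS/EOS sentinel values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .corpus import AnnotatedSentence

WINDOW_OFFSETS: tuple[int, ...] = (-2, -1, 0, 1, 2)
TEMPLATE_IDS: tuple[str, ...] = tuple(f"f{i}" for i in range(1, 17))
BOS = "__BOS__"
EOS = "__EOS__"

#: Default number of embedding clusters; tunable over the 100..1000 grid.
DEFAULT_N_CLUSTERS = 400
CLUSTER_GRID: tuple[int, ...] = tuple(range(100, 1001, 100))

OOV_CLUSTER = "OOV"


@dataclass(frozen=True)
class FeatureString:
    """One instantiated feature: template id(s), window offset(s), value.

    The serialized form (``str(fs)``) is the unit the selection statistics
    score and the CRF consumes, e.g. ``f1[-1]=luteolin`` or the conjunction
    ``f1[-1]_f1[0]=and_apigenin``.
    """

    template: tuple[str, ...]
    offsets: tuple[int, ...]
    value: str

    def __post_init__(self) -> None:
        if len(self.template) != len(self.offsets):
            raise ValueError("one offset per member template required")

    def __str__(self) -> str:
        slots = "_".join(
            f"{tid}[{off}]" for tid, off in zip(self.template, self.offsets)
        )
        return f"{slots}={self.value}"


def singleton(template_id: str, offset: int, value: str) -> FeatureString:
    return FeatureString((template_id,), (offset,), value)


# ---------------------------------------------------------------------------
# Surface-level extractors (f1, f4, f9-f16)
# ---------------------------------------------------------------------------


def extract_word(token: str) -> FeatureString:
    """f1 — the word itself."""
    if not token:
        raise ValueError("empty token")
    return singleton("f1", 0, token)


_ALL_CAP = re.compile(r"^[A-Z]+$")
_ALL_DIGIT = re.compile(r"^[0-9]+$")

ORTHO_CLASSES = (
    "All-capitalized",
    "Is-capitalized",
    "All-digits",
    "Alphanumeric",
    "Other",
)


def orthographic_class(token: str) -> str:
    """First matching class in fixed precedence order.

    ``Alphanumeric`` is read as "contains both letters and digits", possibly
    with internal symbols (drug names routinely mix the three).
    """
    if _ALL_CAP.fullmatch(token):
        return "All-capitalized"
    if token[0].isupper() and token[0].isalpha():
        return "Is-capitalized"
    if _ALL_DIGIT.fullmatch(token):
        return "All-digits"
    if any(c.isalpha() for c in token) and any(c.isdigit() for c in token):
        return "Alphanumeric"
    return "Other"


def extract_orthographic(token: str) -> list[FeatureString]:
    """f4 — orthographic class plus a separate hyphen flag.

    The class label is the template's primary value (the one conjunction
    templates combine); the hyphen flag rides along as a second f4 string.
    """
    if not token:
        raise ValueError("empty token")
    hyphen = "Y" if "-" in token else "N"
    return [
        singleton("f4", 0, orthographic_class(token)),
        singleton("f4", 0, f"hyphen:{hyphen}"),
    ]


_AFFIX_TEMPLATES = (
    ("f9", 3, False),
    ("f10", 4, False),
    ("f11", 5, False),
    ("f12", 3, True),
    ("f13", 4, True),
    ("f14", 5, True),
)


def extract_affixes(token: str) -> list[FeatureString]:
    """f9-f14 — prefixes and suffixes of length 3, 4 and 5.

    A token shorter than the affix length omits that feature entirely.
    """
    if not token:
        raise ValueError("empty token")
    feats = []
    for tid, length, is_suffix in _AFFIX_TEMPLATES:
        if len(token) < length:
            continue
        value = token[-length:] if is_suffix else token[:length]
        feats.append(singleton(tid, 0, value))
    return feats


def _char_class(c: str) -> str:
    if c.isupper():
        return "X"
    if c.islower():
        return "x"
    if c.isdigit():
        return "0"
    return "O"


def word_shape(token: str, mode: str = "generalized") -> FeatureString:
    """f15/f16 — character-category word shape.

    ``generalized`` maps every character (upper -> X, lower -> x, digit -> 0,
    other -> O); ``brief`` collapses runs of the same category, so
    ``Aspirin1+`` gives ``Xxxxxxx0O`` and ``Xx0O``.
    """
    if not token:
        raise ValueError("empty token")
    shape = "".join(_char_class(c) for c in token)
    if mode == "generalized":
        return singleton("f15", 0, shape)
    if mode == "brief":
        brief = re.sub(r"(.)\1+", r"\1", shape)
        return singleton("f16", 0, brief)
    raise ValueError(f"unknown shape mode {mode!r}")


# ---------------------------------------------------------------------------
# Dictionary features (f5-f7)
# ---------------------------------------------------------------------------


@dataclass
class Dictionary:
    """A drug term list with case-insensitive per-word membership.

    A token matches when it equals a single-word term or any
    whitespace-delimited word of a multiword term.
    """

    name: str
    words: set[str]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError(f"dictionary {self.name!r} is empty")
        self.words = {w.lower() for w in self.words}

    @classmethod
    def from_terms(cls, name: str, terms: Iterable[str]) -> "Dictionary":
        words = {w for term in terms for w in term.split()}
        return cls(name, words)

    @classmethod
    def from_file(cls, name: str, path: str | Path) -> "Dictionary":
        terms = [
            line.strip()
            for line in Path(path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        return cls.from_terms(name, terms)

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.words


#: Template slot per dictionary position (DrugBank-like, FDA-like, Jochem-like).
DICT_TEMPLATE_IDS = ("f5", "f6", "f7")


def extract_dictionary(token: str, dictionary: Dictionary, template_id: str = "f5") -> FeatureString:
    """f5-f7 — Y/N membership of the token in one dictionary."""
    return singleton(template_id, 0, "Y" if token in dictionary else "N")


# ---------------------------------------------------------------------------
# Word-embedding cluster feature (f8)
# ---------------------------------------------------------------------------


def read_embeddings(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a word2vec-style text table: ``word v1 v2 ... vD`` per line.

    An optional leading ``count dim`` header line is accepted.  The dimension
    is inferred from the first data line and enforced afterwards.
    """
    words: list[str] = []
    rows: list[list[float]] = []
    dim: int | None = None
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2 and all(p.isdigit() for p in parts):
                continue  # word2vec header
            word, *vals = parts
            try:
                vec = [float(v) for v in vals]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric vector entry") from exc
            if dim is None:
                dim = len(vec)
                if dim < 1:
                    raise ValueError(f"{path}:{lineno}: empty vector")
            elif len(vec) != dim:
                raise ValueError(
                    f"{path}:{lineno}: dimension {len(vec)} != {dim}"
                )
            words.append(word)
            rows.append(vec)
    if not words:
        raise ValueError(f"{path}: empty embedding table")
    return words, np.asarray(rows, dtype=float)


@dataclass
class EmbeddingClusterModel:
    """k-means clustering of word vectors into discrete semantic classes.

    The cluster id replaces the dense vector as a categorical feature; words
    outside the embedding vocabulary share the designated OOV id.
    """

    n_clusters: int
    assignments: dict[str, int]
    oov_id: str = OOV_CLUSTER

    def cluster_of(self, token: str) -> str:
        idx = self.assignments.get(token.lower())
        return self.oov_id if idx is None else f"c{idx}"


def fit_embedding_clusters(
    words: Sequence[str],
    vectors: np.ndarray,
    k: int = DEFAULT_N_CLUSTERS,
    seed: int = 0,
) -> EmbeddingClusterModel:
    """Cluster the embedding vocabulary with k-means (k-means++ init).

    Deterministic for a fixed seed; ``k`` must lie in [2, vocabulary size].
    """
    if not (2 <= k <= len(words)):
        raise ValueError(f"k={k} outside [2, {len(words)}]")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=10, max_iter=300, tol=1e-4,
        random_state=seed,
    )
    labels = km.fit_predict(np.asarray(vectors, dtype=float))
    assignments = {w.lower(): int(c) for w, c in zip(words, labels)}
    return EmbeddingClusterModel(n_clusters=k, assignments=assignments)


def extract_embedding_cluster(
    token: str, model: EmbeddingClusterModel
) -> FeatureString:
    """f8 — the token's semantic-class (cluster) id."""
    return singleton("f8", 0, model.cluster_of(token))


# ---------------------------------------------------------------------------
# Rule-based POS/chunk tagger (f2, f3 provider)
# ---------------------------------------------------------------------------


class RuleBasedTagger:
    """Deterministic suffix-rule POS tagger with simple noun/verb-phrase chunking.

    Fulfils the tagger contract (one POS and one chunk label per token,
    deterministic for fixed input); any external tagger exposing
    ``pos_tags(words)`` and ``chunk_tags(words)`` can stand in for it.
    """

    CLOSED = {
        "the": "DT", "a": "DT", "an": "DT", "this": "DT", "these": "DT",
        "and": "CC", "or": "CC", "but": "CC",
        "of": "IN", "in": "IN", "with": "IN", "on": "IN", "for": "IN",
        "by": "IN", "during": "IN", "after": "IN", "before": "IN",
        "to": "TO", "not": "RB",
        "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD",
        "be": "VB", "been": "VBN", "may": "MD", "should": "MD", "can": "MD",
    }
    _ADJ_SUFFIX = ("ive", "ous", "ic", "al", "ar", "ary")
    _NOUN_PHRASE_POS = ("NN", "JJ", "CD", "DT")

    def pos_tags(self, words: Sequence[str]) -> list[str]:
        tags = []
        for w in words:
            lw = w.lower()
            if lw in self.CLOSED:
                tags.append(self.CLOSED[lw])
            elif not any(c.isalnum() for c in w):
                tags.append("PUNCT")
            elif w.isdigit():
                tags.append("CD")
            elif w[0].isupper() and w[0].isalpha():
                tags.append("NNP")
            elif lw.endswith("ing") and len(lw) > 4:
                tags.append("VBG")
            elif lw.endswith("ed") and len(lw) > 3:
                tags.append("VBD")
            elif lw.endswith("ly") and len(lw) > 3:
                tags.append("RB")
            elif lw.endswith(self._ADJ_SUFFIX) and len(lw) > 4:
                tags.append("JJ")
            elif lw.endswith("s") and len(lw) > 3:
                tags.append("NNS")
            else:
                tags.append("NN")
        return tags

    def chunk_tags(self, words: Sequence[str]) -> list[str]:
        pos = self.pos_tags(words)
        chunks = []
        prev = "O"
        for p in pos:
            if p.startswith(self._NOUN_PHRASE_POS):
                cur = "I-NP" if prev.endswith("NP") else "B-NP"
            elif p.startswith("VB") or p == "MD":
                cur = "I-VP" if prev.endswith("VP") else "B-VP"
            else:
                cur = "O"
            chunks.append(cur)
            prev = cur
        return chunks


# ---------------------------------------------------------------------------
# Sentence-level extraction over the window
# ---------------------------------------------------------------------------


@dataclass
class FeatureTemplate:
    """Registry entry: a template id, its name, and its per-token extractor."""

    id: str
    name: str


def default_template_registry() -> list[FeatureTemplate]:
    """The 16 default singleton templates in Table-order."""
    names = {
        "f1": "word", "f2": "POS", "f3": "chunk", "f4": "orthographic",
        "f5": "DrugBank", "f6": "FDA", "f7": "Jochem",
        "f8": "word embeddings cluster",
        "f9": "prefix-3", "f10": "prefix-4", "f11": "prefix-5",
        "f12": "suffix-3", "f13": "suffix-4", "f14": "suffix-5",
        "f15": "generalized word class", "f16": "brief word class",
    }
    return [FeatureTemplate(tid, names[tid]) for tid in TEMPLATE_IDS]


class SentenceFeatureExtractor:
    """Instantiates the enabled singleton templates over the 5-token window.

    Parameters
    ----------
    tagger : POS/chunk provider satisfying the tagger contract (default:
        :class:`RuleBasedTagger`).
    dictionaries : up to three :class:`Dictionary` objects filling template
        slots f5, f6, f7 in order.
    cluster_model : fitted :class:`EmbeddingClusterModel` for f8.
    templates : iterable of template ids to enable (default: all 16; f2/f3
        require a tagger, f5-f7 their dictionary, f8 the cluster model —
        a template whose resource is missing is silently disabled).
    """

    def __init__(
        self,
        tagger=None,
        dictionaries: Sequence[Dictionary] = (),
        cluster_model: EmbeddingClusterModel | None = None,
        templates: Iterable[str] | None = None,
    ) -> None:
        if len(dictionaries) > len(DICT_TEMPLATE_IDS):
            raise ValueError("at most three dictionary slots (f5-f7)")
        self.tagger = tagger if tagger is not None else RuleBasedTagger()
        self.dictionaries = list(dictionaries)
        self.cluster_model = cluster_model
        enabled = set(templates) if templates is not None else set(TEMPLATE_IDS)
        unknown = enabled - set(TEMPLATE_IDS)
        if unknown:
            raise ValueError(f"unknown template ids {sorted(unknown)}")
        avail = {tid for tid, _ in zip(DICT_TEMPLATE_IDS, self.dictionaries)}
        for tid in DICT_TEMPLATE_IDS:
            if tid in enabled and tid not in avail:
                enabled.discard(tid)
        if self.cluster_model is None:
            enabled.discard("f8")
        self.templates: tuple[str, ...] = tuple(
            tid for tid in TEMPLATE_IDS if tid in enabled
        )

    # -- per-token values at offset 0 ------------------------------------

    def base_values(self, sentence: AnnotatedSentence) -> list[dict[str, list[str]]]:
        """For each token, the list of values per enabled template.

        The first value of a template is its *primary* value (the one used
        as a conjunction member); f4 additionally carries the hyphen flag as
        a secondary value.  Affix templates may be empty for short tokens.
        """
        words = sentence.words
        n = len(words)
        pos = chunk = None
        if "f2" in self.templates or "f3" in self.templates:
            pos = self.tagger.pos_tags(words)
            chunk = self.tagger.chunk_tags(words)
            if len(pos) != n or len(chunk) != n:
                raise ValueError("tagger output length mismatch")

        out: list[dict[str, list[str]]] = []
        for i, w in enumerate(words):
            vals: dict[str, list[str]] = {}
            for tid in self.templates:
                if tid == "f1":
                    vals[tid] = [w]
                elif tid == "f2":
                    vals[tid] = [pos[i]]
                elif tid == "f3":
                    vals[tid] = [chunk[i]]
                elif tid == "f4":
                    vals[tid] = [fs.value for fs in extract_orthographic(w)]
                elif tid in DICT_TEMPLATE_IDS:
                    d = self.dictionaries[DICT_TEMPLATE_IDS.index(tid)]
                    vals[tid] = ["Y" if w in d else "N"]
                elif tid == "f8":
                    vals[tid] = [self.cluster_model.cluster_of(w)]
                elif tid in ("f15", "f16"):
                    mode = "generalized" if tid == "f15" else "brief"
                    vals[tid] = [word_shape(w, mode).value]
                else:  # affixes f9-f14
                    vals[tid] = [
                        fs.value for fs in extract_affixes(w) if fs.template[0] == tid
                    ]
            out.append(vals)
        return out

    def member_value(
        self,
        base: list[dict[str, list[str]]],
        index: int,
        template_id: str,
        offset: int,
    ) -> str | None:
        """Primary value of ``template_id`` at window ``offset`` from token
        ``index``; BOS/EOS past the edges; None when the member is missing
        (disabled template or omitted short-word affix)."""
        j = index + offset
        if j < 0:
            return BOS
        if j >= len(base):
            return EOS
        vals = base[j].get(template_id)
        if not vals:
            return None
        return vals[0]

    def extract(self, sentence: AnnotatedSentence) -> list[list[FeatureString]]:
        """All window-expanded singleton features, one list per token."""
        base = self.base_values(sentence)
        n = len(base)
        per_token: list[list[FeatureString]] = []
        for i in range(n):
            feats: list[FeatureString] = []
            for off in WINDOW_OFFSETS:
                j = i + off
                if j < 0 or j >= n:
                    sentinel = BOS if j < 0 else EOS
                    feats.extend(
                        singleton(tid, off, sentinel) for tid in self.templates
                    )
                    continue
                for tid in self.templates:
                    feats.extend(
                        singleton(tid, off, v) for v in base[j].get(tid, ())
                    )
            per_token.append(feats)
        return per_token
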