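"""Seeded generator for DDI-style annotated corpora, dictionaries, embeddings.

The generator emulates the structure a drug-interaction corpus offers a
sequence tagger, without any linguistic realism claims:

* four entity types with a skewed mixture (drug-dominant, ``no-human`` rare,
  echoing the real corpus' class imbalance);
* type-characteristic surface morphology — drugs as lowercase coinages with
  pharmacological suffixes (``-mab``, ``-vir``, ``-cillin`` ...), brands as
  capitalized coinages, groups as plural class nouns of 1-3 tokens,
  ``no-human`` agents with agrochemical-style morphology;
* drug dictionaries covering a configurable fraction of the drug vocabulary
  (plus common-word distractors), three of them with different overlap;
* an embedding table whose vectors cluster by entity type, so the k-means
  semantic-class feature is informative;
* ambiguous terms that occur both as mentions and as plain words, so context
  (and conjunction features) carries signal beyond the lexicon.

Everything is deterministic under the config seed; one global seed fans out
to independent per-component streams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import AnnotatedSentence, sentence_from_text
from .features import Dictionary

DEFAULT_TYPE_MIXTURE: dict[str, float] = {
    "drug": 0.64,
    "group": 0.23,
    "brand": 0.09,
    "no-human": 0.04,
}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_sentences: int = 400
    type_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIXTURE)
    )
    dictionary_coverage: float = 0.8
    embedding_dim: int = 50
    noise_token_rate: float = 0.1     # chance of an extra filler word per slot
    ambiguity_rate: float = 0.08      # chance a sentence uses a drug word as plain text
    embedding_oov_rate: float = 0.1   # corpus words left out of the embedding table

    def __post_init__(self) -> None:
        total = sum(self.type_mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"type mixture sums to {total}, expected 1")
        if any(v < 0 for v in self.type_mixture.values()):
            raise ValueError("negative mixture weight")
        if not (0.0 <= self.dictionary_coverage <= 1.0):
            raise ValueError("coverage outside [0, 1]")
        if self.embedding_dim < 2:
            raise ValueError("embedding dimension must be >= 2")


# ---------------------------------------------------------------------------
# Name morphology
# ---------------------------------------------------------------------------

_DRUG_STEMS = (
    "ami", "dexa", "flu", "cefa", "lora", "meto", "keta", "rito", "vala",
    "oxa", "peni", "tri", "zido", "lami", "ribo", "ator", "sima", "beva",
    "niv", "pembro", "erlo", "gefi", "soraf", "doce", "pacli",
)
_DRUG_SUFFIXES = (
    "mab", "vir", "cillin", "olol", "pril", "azole", "statin", "micin",
    "parin", "idone", "tinib", "taxel", "vudine", "profen",
)
_DRUG_SALTS = ("sodium", "hydrochloride", "sulfate", "citrate", "acetate")
_BRAND_STEMS = ("Xel", "Prav", "Zyr", "Nex", "Cort", "Valt", "Gluc", "Amb", "Sero", "Lam")
_BRAND_SUFFIXES = ("ix", "ra", "eon", "axa", "orin", "uma", "ide", "ol")
_GROUP_NAMES = (
    "beta-blockers", "corticosteroids", "anticoagulants", "diuretics",
    "macrolide antibiotics", "NSAIDs", "ACE inhibitors",
    "calcium channel blockers", "iodinated contrast media",
    "tricyclic antidepressants", "proton pump inhibitors", "statins",
    "opioid analgesics", "aminoglycosides", "antihistamines",
)
_NOHUMAN_STEMS = ("per", "cy", "mala", "fen", "di", "chlor", "carbo", "endo")
_NOHUMAN_SUFFIXES = ("thrin", "phos", "carb", "uron", "toxin", "fluran")

_FILLERS = (
    "the patient received concurrent administration of increased plasma "
    "levels in elderly patients clinical studies showed that treatment "
    "with may reduce the effect and risk of severe reactions when used "
    "together during therapy a significant interaction was observed "
    "between doses should be adjusted carefully monitored for signs of "
    "toxicity renal function can decrease absorption metabolism is "
    "mediated by hepatic enzymes".split()
)

_TEMPLATES = (
    ("the patient received", 1, "and", 1, "during therapy ."),
    ("treatment with", 1, "increased the plasma levels of", 1, "."),
    ("concurrent use of", 1, "and", 1, "is not recommended ."),
    ("administration of", 1, "may reduce the effect of", 1, "."),
    ("", 1, "interacts with", 1, "in elderly patients ."),
    ("clinical studies showed that", 1, "decreased absorption of", 1, "."),
    ("caution is advised when", 1, "is combined with", 1, "."),
    ("", 1, "did not alter the pharmacokinetics of", 1, "."),
)


def _build_lexicons(rng: np.random.Generator) -> dict[str, list[str]]:
    """Seeded pools of surface names per type (multiword names included)."""
    drugs: list[str] = []
    for stem in _DRUG_STEMS:
        for suf in rng.choice(len(_DRUG_SUFFIXES), size=4, replace=False):
            drugs.append(stem + _DRUG_SUFFIXES[suf])
    # some combination products and alphanumeric names
    multi = [
        f"{d} {rng.choice(_DRUG_SALTS)}" for d in rng.choice(drugs, size=15, replace=False)
    ]
    numbered = [f"interleukin-{i}" for i in (2, 6, 11)]
    drugs = sorted(set(drugs)) + multi + numbered
    brands = sorted(
        {s + e for s in _BRAND_STEMS for e in rng.choice(_BRAND_SUFFIXES, 3, replace=False)}
    )
    nohuman = sorted(
        {s + e for s in _NOHUMAN_STEMS for e in rng.choice(_NOHUMAN_SUFFIXES, 2, replace=False)}
    )
    return {
        "drug": drugs,
        "brand": brands,
        "group": list(_GROUP_NAMES),
        "no-human": nohuman,
    }


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[AnnotatedSentence], dict[str, list[str]]]:
    """Generate annotated sentences plus the name lexicons used.

    Mentions are 1-3 tokens, always whitespace-aligned so BILOU encoding
    never errors.  Deterministic under ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_lex, rng_sent = [np.random.default_rng(s) for s in ss.spawn(2)]
    lexicons = _build_lexicons(rng_lex)
    types = sorted(config.type_mixture)
    probs = np.array([config.type_mixture[t] for t in types])
    probs = probs / probs.sum()
    ambiguous = [n for n in lexicons["drug"] if " " not in n][:4]

    sentences: list[AnnotatedSentence] = []
    for i in range(config.n_sentences):
        template = _TEMPLATES[rng_sent.integers(len(_TEMPLATES))]
        words: list[str] = []
        mention_spans: list[tuple[int, int, str]] = []  # word-index spans
        for part in template:
            if part == 1:
                etype = types[rng_sent.choice(len(types), p=probs)]
                name = lexicons[etype][rng_sent.integers(len(lexicons[etype]))]
                name_words = name.split()
                mention_spans.append((len(words), len(words) + len(name_words), etype))
                words.extend(name_words)
            else:
                words.extend(part.split())
            if rng_sent.random() < config.noise_token_rate:
                words.append(_FILLERS[rng_sent.integers(len(_FILLERS))])
        if rng_sent.random() < config.ambiguity_rate:
            # an ambiguous drug word used as a plain (O-tagged) modifier
            amb = ambiguous[rng_sent.integers(len(ambiguous))]
            words.extend(["regarding", "the", amb, "assay"])

        text = ""
        starts: list[int] = []
        for w in words:
            if text:
                text += " "
            starts.append(len(text))
            text += w
        mentions = [
            (starts[a], starts[b - 1] + len(words[b - 1]), etype)
            for a, b, etype in mention_spans
        ]
        sentences.append(sentence_from_text(text, mentions, doc_id=f"s{i}"))
    return sentences, lexicons


def generate_dictionaries(
    corpus: Sequence[AnnotatedSentence],
    coverage: float = 0.8,
    seed: int = 0,
) -> list[Dictionary]:
    """Three partially overlapping drug dictionaries from the corpus mentions.

    Each dictionary holds exactly round(coverage * n) of the distinct
    drug-mention words plus common-word distractors; the three differ in
    which extra entity types they also cover (none / brand / brand+group),
    mimicking lexicons of different breadth.
    """
    if not (0.0 <= coverage <= 1.0):
        raise ValueError("coverage outside [0, 1]")
    words_by_type: dict[str, set[str]] = {}
    for sent in corpus:
        for m in sent.mentions:
            words_by_type.setdefault(m.type, set()).update(
                w.lower() for w in m.text.split()
            )
    drug_words = sorted(words_by_type.get("drug", set()))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD1C7)))
    extras = (set(), {"brand"}, {"brand", "group"})
    dictionaries = []
    for name, extra in zip(("drugbank-like", "fda-like", "jochem-like"), extras):
        n_keep = int(round(coverage * len(drug_words)))
        keep = set(
            rng.choice(drug_words, size=n_keep, replace=False)
        ) if n_keep else set()
        for t in extra:
            for w in sorted(words_by_type.get(t, set())):
                if rng.random() < coverage:
                    keep.add(w.lower())
        distractors = set(rng.choice(_FILLERS, size=8, replace=False))
        terms = keep | distractors
        if not terms:
            terms = distractors or {"placebo"}
        dictionaries.append(Dictionary(name, terms))
    return dictionaries


def generate_embeddings(
    corpus: Sequence[AnnotatedSentence],
    dim: int = 50,
    seed: int = 0,
    oov_rate: float = 0.1,
) -> tuple[list[str], np.ndarray]:
    """A word2vec-style table whose vectors cluster by entity type.

    Each entity type (plus the common-word background) gets a Gaussian
    center; every vocabulary word is sampled near its group's center, and a
    seeded ``oov_rate`` fraction of words is left out of the table.
    """
    if dim < 2:
        raise ValueError("dimension must be >= 2")
    group_of: dict[str, str] = {}
    for sent in corpus:
        mention_token_idx = set()
        tags_by_token: dict[int, str] = {}
        for m in sent.mentions:
            for tok in sent.tokens:
                if tok.start >= m.start and tok.end <= m.end:
                    tags_by_token[tok.index] = m.type
                    mention_token_idx.add(tok.index)
        for tok in sent.tokens:
            w = tok.text.lower()
            grp = tags_by_token.get(tok.index, "common")
            # entity morphology wins over incidental common usage
            if group_of.get(w, "common") == "common":
                group_of[w] = grp
    words = sorted(group_of)
    groups = sorted(set(group_of.values()))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xE3B)))
    centers = {g: rng.normal(0.0, 5.0, size=dim) for g in groups}
    keep = rng.random(len(words)) >= oov_rate
    kept_words = [w for w, k in zip(words, keep) if k]
    vectors = np.stack(
        [centers[group_of[w]] + rng.normal(0.0, 0.5, size=dim) for w in kept_words]
    )
    return kept_words, vectors


def write_embeddings(words: Sequence[str], vectors: np.ndarray, path: str | Path) -> None:
    """Write the table in word2vec text format (with a ``count dim`` header)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(words)} {vectors.shape[1]}\n")
        for w, vec in zip(words, vectors):
            fh.write(w + " " + " ".join(f"{v:.6f}" for v in vec) + "\n")


def write_dictionary(dictionary: Dictionary, path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(sorted(dictionary.words)) + "\n", encoding="utf-8"
    )
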