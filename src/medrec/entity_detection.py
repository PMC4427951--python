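"""Medication entity detection: tokenization, featurization and CRF tagging.

The first pipeline stage reads a clinical note and emits character-offset
entity spans over the eight categories (medication name plus seven
attributes).  Notes are tokenized with a rule tokenizer (whitespace plus
letter/digit/punctuation boundaries, decimals kept intact), encoded as BIO
tag sequences, featurized with token-shape, affix, context-window and
lexicon-gazetteer features, and labeled by a linear-chain CRF.

The gazetteer flags (does the token occur in a drug-lexicon description /
unit table / route table ...) provide the dictionary evidence that a concept
extractor would supply in a full clinical deployment; here the drug lexicon
is the sole dictionary.
"""

from __future__ import annotations

import pickle
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .corpus_io import ClinicalNote, EntitySpan
from .crf import OUTSIDE, CRFParams, LinearChainCRF, valid_bio
from .errors import ConfigError, IntegrityError, UsageError
from .lexicon import Lexicon

FEATURE_TEMPLATE_VERSION = "medrec-features-1"

_TOKEN_RE = re.compile(r"\d+\.\d+|\d+|[A-Za-z]+|[^\sA-Za-z0-9]")

# small gazetteers for shape-level dictionary flags
_UNIT_TOKENS = frozenset({"mg", "ml", "mcg", "g", "units"})
_ROUTE_TOKENS = frozenset({"po", "oral", "pr", "rectal", "topical", "inhaled", "iv", "sublingual"})
_FORM_TOKENS = frozenset(
    {"tab", "tablet", "capsule", "solution", "gel", "suspension", "syrup", "cream", "patch", "powder"}
)
_FREQ_TOKENS = frozenset({"daily", "bid", "tid", "qid", "qhs", "prn", "nightly", "weekly"})


@dataclass(frozen=True)
class Token:
    """One surface token with offsets into its note."""

    text: str
    start: int
    end: int
    index: int
    pos: Optional[str] = None


@dataclass
class LabeledSequence:
    """A token sequence with aligned BIO labels."""

    tokens: list[Token]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise UsageError("token and label sequences differ in length")
        if not valid_bio(self.labels):
            raise IntegrityError("label sequence violates BIO constraints")


def tokenize(text: str) -> list[Token]:
    """Split on whitespace and letter/digit/punctuation boundaries.

    Decimal numbers stay one token; every punctuation character is its own
    token.  Offsets index into the original text.
    """
    return [
        Token(m.group(), m.start(), m.end(), i)
        for i, m in enumerate(_TOKEN_RE.finditer(text))
    ]


def spans_to_bio(spans: Sequence[EntitySpan], tokens: Sequence[Token]) -> list[str]:
    """Project character spans onto BIO token labels.

    A token belongs to a span when its midpoint falls inside the span, so
    spans that cut a token still label it.  Overlapping gold spans of the
    same category are rejected.
    """
    by_cat: dict[str, list[EntitySpan]] = {}
    for s in spans:
        group = by_cat.setdefault(s.category, [])
        for other in group:
            if s.start < other.end and other.start < s.end:
                raise IntegrityError(
                    f"overlapping {s.category} spans at [{s.start},{s.end}) and "
                    f"[{other.start},{other.end}) in note {s.note_id}"
                )
        group.append(s)
    labels = [OUTSIDE] * len(tokens)
    for s in sorted(spans, key=lambda s: (s.start, s.end)):
        inside = [
            t.index for t in tokens if s.start <= (t.start + t.end) / 2 < s.end
        ]
        for k, idx in enumerate(inside):
            labels[idx] = ("B-" if k == 0 else "I-") + s.category
    return labels


def bio_to_spans(
    tokens: Sequence[Token], labels: Sequence[str], note: ClinicalNote
) -> list[EntitySpan]:
    """Convert BIO labels back to maximal character spans over the note."""
    if len(tokens) != len(labels):
        raise UsageError("token and label sequences differ in length")
    spans: list[EntitySpan] = []
    i = 0
    while i < len(labels):
        lab = labels[i]
        if lab == OUTSIDE:
            i += 1
            continue
        cat = lab[2:]
        j = i + 1
        while j < len(labels) and labels[j] == "I-" + cat:
            j += 1
        start, end = tokens[i].start, tokens[j - 1].end
        spans.append(EntitySpan(note.note_id, start, end, cat, note.text[start:end]))
        i = j
    return spans


# ---------------------------------------------------------------------------
# features


@dataclass
class FeatureConfig:
    window: int = 2  # context offsets -window..+window
    affix_lengths: tuple[int, ...] = (2, 3)
    use_gazetteer: bool = True


def _shape(text: str) -> str:
    if text.isdigit() or re.fullmatch(r"\d+\.\d+", text):
        return "digit"
    if text.isupper():
        return "upper"
    if text[0].isupper():
        return "capitalized"
    if text.isalpha():
        return "lower"
    return "mixed"


def _token_features(
    tok: Token, lexicon_terms: frozenset[str], config: FeatureConfig
) -> list[str]:
    low = tok.text.lower()
    feats = [
        "bias",
        f"lower={low}",
        f"shape={_shape(tok.text)}",
    ]
    if any(ch.isdigit() for ch in tok.text):
        feats.append("hasdigit")
    if tok.text.isdigit():
        feats.append("isdigit")
    if not any(ch.isalnum() for ch in tok.text):
        feats.append(f"punct={tok.text}")
    for n in config.affix_lengths:
        if len(low) > n:
            feats.append(f"pre{n}={low[:n]}")
            feats.append(f"suf{n}={low[-n:]}")
    feats.append(f"pos={tok.pos or 'UNK'}")
    if config.use_gazetteer:
        if low in lexicon_terms:
            feats.append("gaz=drug_term")
        if low in _UNIT_TOKENS:
            feats.append("gaz=unit")
        if low in _ROUTE_TOKENS:
            feats.append("gaz=route")
        if low in _FORM_TOKENS:
            feats.append("gaz=form")
        if low in _FREQ_TOKENS:
            feats.append("gaz=frequency")
    return feats


def featurize(
    tokens: Sequence[Token],
    lexicon: Optional[Lexicon] = None,
    config: Optional[FeatureConfig] = None,
) -> list[list[str]]:
    """Per-token feature sets: shape, affixes, context window, gazetteer flags."""
    config = config or FeatureConfig()
    terms: frozenset[str] = frozenset()
    if lexicon is not None:
        terms = frozenset(t for e in lexicon.entries.values() for t in e.terms)
    base = [_token_features(t, terms, config) for t in tokens]
    out: list[list[str]] = []
    for i, feats in enumerate(base):
        feats = list(feats)
        for off in range(-config.window, config.window + 1):
            if off == 0:
                continue
            j = i + off
            if 0 <= j < len(tokens):
                low = tokens[j].text.lower()
                feats.append(f"ctx[{off}]={low}")
                if low in terms:
                    feats.append(f"ctx[{off}]gaz=drug_term")
            else:
                feats.append(f"ctx[{off}]=__BOUNDARY__")
        out.append(feats)
    return out


# ---------------------------------------------------------------------------
# tagger


@dataclass
class TaggerModel:
    """A trained CRF with its feature template pinned by a version string."""

    crf: LinearChainCRF
    feature_config: FeatureConfig
    template_version: str = FEATURE_TEMPLATE_VERSION
    seed: int = 0

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TaggerModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if model.template_version != FEATURE_TEMPLATE_VERSION:
            raise ConfigError(
                f"model was built with feature template {model.template_version!r}; "
                f"this package expects {FEATURE_TEMPLATE_VERSION!r}"
            )
        return model


def train_tagger(
    notes: Sequence[ClinicalNote],
    annotations: dict[str, Sequence[EntitySpan]],
    lexicon: Optional[Lexicon] = None,
    params: Optional[CRFParams] = None,
    feature_config: Optional[FeatureConfig] = None,
    seed: int = 0,
) -> TaggerModel:
    """Train the entity tagger on gold-annotated notes."""
    if not notes:
        raise UsageError("cannot train a tagger on an empty corpus")
    feature_config = feature_config or FeatureConfig()
    X, y = [], []
    for note in notes:
        tokens = tokenize(note.text)
        if not tokens:
            continue
        X.append(featurize(tokens, lexicon, feature_config))
        y.append(spans_to_bio(annotations.get(note.note_id, []), tokens))
    crf = LinearChainCRF(params or CRFParams()).fit(X, y)
    return TaggerModel(crf, feature_config, seed=seed)


def predict_spans(
    model: TaggerModel, note: ClinicalNote, lexicon: Optional[Lexicon] = None
) -> list[EntitySpan]:
    """Decode one note into entity spans (the input of attribute linkage)."""
    tokens = tokenize(note.text)
    if not tokens:
        return []
    labels = model.crf.predict(featurize(tokens, lexicon, model.feature_config))
    return bio_to_spans(tokens, labels, note)


def predict_labels(
    model: TaggerModel, note: ClinicalNote, lexicon: Optional[Lexicon] = None
) -> LabeledSequence:
    """Decode one note, returning the token-aligned BIO labels."""
    tokens = tokenize(note.text)
    labels = model.crf.predict(featurize(tokens, lexicon, model.feature_config)) if tokens else []
    return LabeledSequence(list(tokens), labels)
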