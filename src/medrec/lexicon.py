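"""Drug dictionary (RxNorm-style) used by gazetteer features and the matching cascade.

A :class:`Lexicon` holds coded entries — ingredients, clinical drugs, brands —
each with a free-text description (e.g. ``diazepam rectal gel [diastat]``)
and the set of lowercase alphabetic terms appearing in it, plus an unordered
set of trade-name/generic code relations.

Two on-disk dialects are supported:

``simple_tsv``
    Four tab-separated columns: ``code  term_type  description  related_code``
    (``related_code`` optional; a non-empty value declares a trade relation).

``rrf_subset``
    A pair of pipe-delimited files shaped like the RxNorm RRF release:
    ``<stem>CONSO.RRF`` with the concept code at column 0, term type at
    column 12 and description string at column 14, and ``<stem>REL.RRF``
    with the two codes at columns 0 and 4 and the relation tag
    (``has_tradename`` / ``tradename_of``) at column 7.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .errors import ConfigError, IntegrityError, UsageError

TERM_TYPES = ("ingredient", "clinical_drug", "brand", "description")

_ALPHA_TOKEN = re.compile(r"[a-z]+")
# delimiters treated as spaces before tokenization
_DELIMS = str.maketrans({"-": " ", "–": " ", "/": " "})


def default_stop_tokens() -> frozenset[str]:
    """The shipped stop-token table (units, forms, routes, frequency words)."""
    text = resources.files("medrec.data").joinpath("stop_tokens.txt").read_text("utf-8")
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def description_terms(description: str) -> frozenset[str]:
    """All lowercase alphabetic tokens of a description (digits, brackets dropped)."""
    return frozenset(_ALPHA_TOKEN.findall(description.lower().translate(_DELIMS)))


def extract_mention_terms(
    medication_text: str, stop_tokens: Optional[frozenset[str]] = None
) -> frozenset[str]:
    """Extract drug terms from a medication mention or prescription name.

    Numbers, units, dose-form/route/frequency stop tokens and delimiter
    characters (hyphen, en dash, slash) are removed; what remains are the
    lowercase drug-name tokens, e.g. ``{"ipratropium", "albuterol"}`` from
    ``"ipratropium 500 mg/2.5 ml – albuterol 2.5 mg/0.5 ml nebulizer solution"``.
    """
    if stop_tokens is None:
        stop_tokens = _DEFAULT_STOPS
    return frozenset(t for t in description_terms(medication_text) if t not in stop_tokens)


@dataclass(frozen=True)
class LexiconEntry:
    code: str
    description: str
    term_type: str
    terms: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if self.term_type not in TERM_TYPES:
            raise IntegrityError(f"unknown term type {self.term_type!r}")
        if not self.terms:
            object.__setattr__(self, "terms", description_terms(self.description))
        if not self.terms:
            raise IntegrityError(f"entry {self.code} has no alphabetic terms")


class Lexicon:
    """A collection of coded drug entries plus trade-name relations."""

    def __init__(
        self,
        entries: Iterable[LexiconEntry] = (),
        trade_relations: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.entries: dict[str, LexiconEntry] = {}
        for e in entries:
            if e.code in self.entries:
                raise IntegrityError(f"duplicate lexicon code {e.code}")
            self.entries[e.code] = e
        self.trade_relations: set[frozenset[str]] = set()
        for a, b in trade_relations:
            self.add_trade_relation(a, b)
        # inverted index: term -> codes of entries containing it
        self._term_index: dict[str, set[str]] = {}
        for e in self.entries.values():
            for t in e.terms:
                self._term_index.setdefault(t, set()).add(e.code)

    def add_trade_relation(self, code_a: str, code_b: str) -> None:
        for c in (code_a, code_b):
            if c not in self.entries:
                raise IntegrityError(f"trade relation references unknown code {c}")
        if code_a != code_b:
            self.trade_relations.add(frozenset((code_a, code_b)))

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return self.entries == other.entries and self.trade_relations == other.trade_relations

    # -- queries ----------------------------------------------------------

    def codes_containing(self, term: str) -> set[str]:
        return set(self._term_index.get(term, ()))

    def co_occur(self, term_a: str, term_b: str) -> bool:
        """True iff some single entry's description contains both terms."""
        return bool(self.codes_containing(term_a) & self.codes_containing(term_b))

    def trade_name_related(self, code_a: str, code_b: str) -> bool:
        for c in (code_a, code_b):
            if c not in self.entries:
                raise UsageError(f"unknown lexicon code {c}")
        return frozenset((code_a, code_b)) in self.trade_relations

    def map_to_codes(
        self, medication_text: str, stop_tokens: Optional[frozenset[str]] = None
    ) -> set[str]:
        """Map a mention or prescription name to the lexicon codes it could denote.

        An entry qualifies when its drug terms are a subset of the mention's
        extracted terms or vice versa (bag-of-words containment).  All
        qualifying codes are returned; ambiguity is the caller's to resolve.
        """
        if stop_tokens is None:
            stop_tokens = _DEFAULT_STOPS
        mention_terms = extract_mention_terms(medication_text, stop_tokens)
        if not mention_terms:
            return set()
        candidates: set[str] = set()
        for t in mention_terms:
            candidates |= self.codes_containing(t)
        out: set[str] = set()
        for code in candidates:
            entry_terms = self.entries[code].terms - stop_tokens
            if entry_terms and (
                entry_terms <= mention_terms or mention_terms <= self.entries[code].terms
            ):
                out.add(code)
        return out

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize as simple_tsv (round-trips with :func:`load_lexicon`)."""
        related: dict[str, str] = {}
        extra: list[tuple[str, str]] = []
        for pair in sorted(self.trade_relations, key=sorted):
            a, b = sorted(pair)
            if a not in related:
                related[a] = b
            elif b not in related:
                related[b] = a
            else:
                extra.append((a, b))
        with open(path, "w", encoding="utf-8") as fh:
            for code in sorted(self.entries):
                e = self.entries[code]
                fh.write(f"{e.code}\t{e.term_type}\t{e.description}\t{related.get(code, '')}\n")
            for a, b in extra:
                fh.write(f"REL\t{a}\t{b}\n")


_DEFAULT_STOPS = default_stop_tokens()


# ---------------------------------------------------------------------------
# module-level operation wrappers


def co_occur_in_description(term_a: str, term_b: str, lexicon: Lexicon) -> bool:
    return lexicon.co_occur(term_a, term_b)


def trade_name_related(code_a: str, code_b: str, lexicon: Lexicon) -> bool:
    return lexicon.trade_name_related(code_a, code_b)


def map_to_codes(medication_text: str, lexicon: Lexicon) -> set[str]:
    return lexicon.map_to_codes(medication_text)


# ---------------------------------------------------------------------------
# loading


def _load_simple_tsv(path: Path) -> Lexicon:
    entries: list[LexiconEntry] = []
    relations: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "REL":
                if len(parts) != 3:
                    raise IntegrityError(f"{path}:{lineno}: REL line needs exactly two codes")
                relations.append((parts[1], parts[2]))
                continue
            if len(parts) not in (3, 4):
                raise IntegrityError(f"{path}:{lineno}: expected 3-4 tab-separated fields")
            code, term_type, description = parts[0], parts[1], parts[2]
            entries.append(LexiconEntry(code, description, term_type))
            if len(parts) == 4 and parts[3]:
                relations.append((code, parts[3]))
    return Lexicon(entries, relations)


_RRF_TTY_MAP = {"IN": "ingredient", "SCD": "clinical_drug", "BN": "brand", "SBD": "brand"}


def _load_rrf_subset(path: Path) -> Lexicon:
    stem = str(path)
    if stem.endswith("CONSO.RRF"):
        conso, rel = Path(stem), Path(stem.replace("CONSO.RRF", "REL.RRF"))
    else:
        conso, rel = Path(stem + "CONSO.RRF"), Path(stem + "REL.RRF")
    entries: dict[str, LexiconEntry] = {}
    with open(conso, encoding="utf-8") as fh:
        for line in fh:
            cols = line.rstrip("\n").split("|")
            code, tty, desc = cols[0], cols[12], cols[14]
            if code not in entries:  # first atom per concept wins
                entries[code] = LexiconEntry(code, desc, _RRF_TTY_MAP.get(tty, "description"))
    relations: list[tuple[str, str]] = []
    if rel.exists():
        with open(rel, encoding="utf-8") as fh:
            for line in fh:
                cols = line.rstrip("\n").split("|")
                if cols[7] in ("has_tradename", "tradename_of"):
                    relations.append((cols[0], cols[4]))
    return Lexicon(entries.values(), relations)


def load_lexicon(path: str | Path, dialect: str = "simple_tsv") -> Lexicon:
    """Load a drug lexicon in the named dialect."""
    if dialect == "simple_tsv":
        return _load_simple_tsv(Path(path))
    if dialect == "rrf_subset":
        return _load_rrf_subset(Path(path))
    raise ConfigError(f"unknown lexicon dialect {dialect!r}")
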