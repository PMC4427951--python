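"""Medication matching: the four-step cascade plus attribute comparison.

Each medication mention from the notes is compared against every
prescription in the encounter's discharge list, trying four steps strictly
in order and stopping at the first success:

1. **Substring** — the normalized mention is identical to, or a substring
   of, the prescription name (or vice versa); also tried against the
   generic name.
2. **Pair memory** — the extracted term sets of mention and prescription
   were previously observed as a gold matched pair in the training data.
3. **Description co-occurrence** — a mention term and a prescription term
   co-occur in one drug-lexicon description (probable synonyms, e.g.
   ``diastat`` / ``diazepam`` in ``diazepam rectal gel [diastat]``).
4. **Trade name** — mention and prescription map to lexicon codes related
   by a trade-name/generic relation.

If no step fires the medication is *discrepant*.  A matched medication's
attributes are then compared to the prescription fields by normalized
string matching (no semantic inference: ``AM`` never matches
``twice a day``).  The final bucket is discrepant when either the
medication or any of its attributes is discrepant.

Reconciliation is strictly note→list: prescriptions with no note-side
mention never produce a result, which avoids false discrepancies from
prescriptions ordered by providers outside the collected notes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from .attribute_linkage import MedicationMention
from .corpus_io import DISCREPANT, MATCHED, EntitySpan, GoldLink, Prescription
from .errors import UsageError
from .lexicon import Lexicon, extract_mention_terms

STEP_SUBSTRING = "1_substring"
STEP_PAIR_MEMORY = "2_pair_memory"
STEP_COOCCURRENCE = "3_description_cooccurrence"
STEP_TRADE_NAME = "4_trade_name"
STEP_NONE = "none"
CASCADE_STEPS = (STEP_SUBSTRING, STEP_PAIR_MEMORY, STEP_COOCCURRENCE, STEP_TRADE_NAME)


@dataclass(frozen=True)
class MatchDecision:
    label: str
    step: str
    prescription_id: Optional[str]

    def __post_init__(self) -> None:
        if (self.label == MATCHED) != (self.step != STEP_NONE):
            raise UsageError("label is 'matched' iff some cascade step fired")
        if self.label == MATCHED and self.prescription_id is None:
            raise UsageError("a matched decision requires a prescription_id")


@dataclass
class ReconciliationResult:
    """Outcome for one mention: match decision plus per-attribute verdicts."""

    mention: MedicationMention
    decision: MatchDecision
    attribute_labels: dict[EntitySpan, str] = field(default_factory=dict)

    @property
    def final_bucket(self) -> str:
        if self.decision.label == DISCREPANT:
            return DISCREPANT
        if any(v == DISCREPANT for v in self.attribute_labels.values()):
            return DISCREPANT
        return MATCHED

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReconciliationResult):
            return NotImplemented
        return (
            self.mention == other.mention
            and self.decision == other.decision
            and self.attribute_labels == other.attribute_labels
        )


@dataclass
class MatchConfig:
    """Cascade switches; defaults reproduce the reference behavior."""

    enabled_steps: frozenset[str] = frozenset(CASCADE_STEPS)
    route_must_match: bool = False  # optional stricter rule: route mismatch voids a match


class PairMemory:
    """Mention/prescription term-set pairs observed as gold matches in training.

    Built exclusively from training folds; queries are symmetric in the two
    term sets.
    """

    def __init__(self) -> None:
        self._pairs: set[frozenset[frozenset[str]]] = set()

    def __len__(self) -> int:
        return len(self._pairs)

    def add(self, terms_a: frozenset[str], terms_b: frozenset[str]) -> None:
        if terms_a and terms_b:
            self._pairs.add(frozenset((terms_a, terms_b)))

    def query(self, terms_a: frozenset[str], terms_b: frozenset[str]) -> bool:
        if not terms_a or not terms_b:
            return False
        return frozenset((terms_a, terms_b)) in self._pairs

    @property
    def pairs(self) -> frozenset[frozenset[frozenset[str]]]:
        return frozenset(self._pairs)


def build_pair_memory(
    training_links: Iterable[GoldLink],
    prescriptions_by_id: Mapping[str, Prescription],
) -> PairMemory:
    """Collect term-set pairs from gold matched links of the training folds."""
    memory = PairMemory()
    for link in training_links:
        if link.label != MATCHED or link.prescription_id is None:
            continue
        rx = prescriptions_by_id.get(link.prescription_id)
        if rx is None:
            continue
        mention_terms = extract_mention_terms(link.mention.name_span.text)
        memory.add(mention_terms, extract_mention_terms(rx.name))
        if rx.generic_name:
            memory.add(mention_terms, extract_mention_terms(rx.generic_name))
    return memory


# ---------------------------------------------------------------------------
# string normalization for comparisons

_WS = re.compile(r"\s+")
_PUNCT = re.compile(r"[^\w\s.]")
_STRAY_DOT = re.compile(r"(?<!\d)\.|\.(?!\d)")  # keep dots only inside numbers
_DIGIT_ALPHA = re.compile(r"(?<=\d)(?=[a-z])|(?<=[a-z])(?=\d)")


def _load_unit_table() -> dict[str, str]:
    text = resources.files("medrec.data").joinpath("unit_normalization.tsv").read_text("utf-8")
    table = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        surface, canonical = line.split("\t")
        table[surface] = canonical
    return table


_UNIT_TABLE = _load_unit_table()


def normalize_name(text: str) -> str:
    """Lowercase and collapse whitespace (medication-name comparison)."""
    return _WS.sub(" ", text.lower()).strip()


def normalize_attribute(text: str) -> str:
    """Normalization for attribute comparison.

    Lowercase, strip punctuation, split digit/letter boundaries (``5mg`` →
    ``5 mg``) and collapse unit synonyms through the shipped table.
    """
    low = _PUNCT.sub(" ", text.lower())
    low = _STRAY_DOT.sub(" ", low)
    low = _DIGIT_ALPHA.sub(" ", low)
    tokens = [_UNIT_TABLE.get(t, t) for t in low.split()]
    return " ".join(tokens)


def _token_sublist(needle: str, haystack: str) -> bool:
    """True iff needle's tokens occur contiguously among haystack's tokens."""
    n, h = needle.split(), haystack.split()
    if not n or len(n) > len(h):
        return False
    return any(h[i : i + len(n)] == n for i in range(len(h) - len(n) + 1))


# ---------------------------------------------------------------------------
# the cascade


def _substring_match(mention: str, rx: Prescription) -> bool:
    for target in (rx.name, rx.generic_name):
        if not target:
            continue
        t = normalize_name(target)
        if mention and t and (mention in t or t in mention):
            return True
    return False


def _pair_memory_match(
    mention_terms: frozenset[str], rx: Prescription, memory: Optional[PairMemory]
) -> bool:
    if memory is None:
        return False
    for target in (rx.name, rx.generic_name):
        if target and memory.query(mention_terms, extract_mention_terms(target)):
            return True
    return False


def _cooccurrence_match(
    mention_terms: frozenset[str], rx: Prescription, lexicon: Optional[Lexicon]
) -> bool:
    if lexicon is None or not mention_terms:
        return False
    for target in (rx.name, rx.generic_name):
        if not target:
            continue
        for rx_term in extract_mention_terms(target):
            for m_term in mention_terms:
                if lexicon.co_occur(m_term, rx_term):
                    return True
    return False


def _trade_name_match(
    mention_text: str, rx: Prescription, lexicon: Optional[Lexicon]
) -> bool:
    if lexicon is None:
        return False
    mention_codes = lexicon.map_to_codes(mention_text)
    if not mention_codes:
        return False
    rx_codes: set[str] = set()
    for target in (rx.name, rx.generic_name):
        if target:
            rx_codes |= lexicon.map_to_codes(target)
    return any(
        frozenset((a, b)) in lexicon.trade_relations
        for a in mention_codes
        for b in rx_codes
    )


def _best_candidate(mention: str, candidates: list[Prescription]) -> Prescription:
    """Longest common substring with the mention wins; ties keep list order."""
    if len(candidates) == 1:
        return candidates[0]

    def lcs_len(rx: Prescription) -> int:
        m = SequenceMatcher(None, mention, normalize_name(rx.name))
        return m.find_longest_match(0, len(mention), 0, len(rx.name)).size

    best, best_len = candidates[0], lcs_len(candidates[0])
    for rx in candidates[1:]:
        n = lcs_len(rx)
        if n > best_len:
            best, best_len = rx, n
    return best


def match_medication(
    mention_text: str,
    prescriptions: Sequence[Prescription],
    lexicon: Optional[Lexicon] = None,
    memory: Optional[PairMemory] = None,
    config: Optional[MatchConfig] = None,
) -> MatchDecision:
    """Run the four-step cascade for one mention against a prescription list."""
    config = config or MatchConfig()
    mention = normalize_name(mention_text)
    mention_terms = extract_mention_terms(mention_text)
    testers = {
        STEP_SUBSTRING: lambda rx: _substring_match(mention, rx),
        STEP_PAIR_MEMORY: lambda rx: _pair_memory_match(mention_terms, rx, memory),
        STEP_COOCCURRENCE: lambda rx: _cooccurrence_match(mention_terms, rx, lexicon),
        STEP_TRADE_NAME: lambda rx: _trade_name_match(mention_text, rx, lexicon),
    }
    for step in CASCADE_STEPS:
        if step not in config.enabled_steps:
            continue
        hits = [rx for rx in prescriptions if testers[step](rx)]
        if hits:
            winner = _best_candidate(mention, hits)
            return MatchDecision(MATCHED, step, winner.prescription_id)
    return MatchDecision(DISCREPANT, STEP_NONE, None)


# ---------------------------------------------------------------------------
# attribute comparison


def _duration_from_dates(rx: Prescription) -> Optional[str]:
    if rx.start_date is not None and rx.end_date is not None:
        days = (rx.end_date - rx.start_date).days
        return f"for {days} days"
    return None


def match_attributes(
    mention: MedicationMention, prescription: Prescription
) -> dict[EntitySpan, str]:
    """Compare each linked attribute to the matched prescription, string-wise.

    The attribute is matched when its normalized form equals, or occurs as a
    contiguous token run inside, the corresponding prescription field.
    Categories without a structured field (amount, dosage) are compared
    against the instruction text; duration against a string synthesized from
    the start/end dates when present, else the instruction.  An attribute
    whose counterpart field is blank is discrepant.
    """
    labels: dict[EntitySpan, str] = {}
    for attr in mention.attributes:
        target = prescription.attribute_field(attr.category)
        if attr.category == "duration":
            target = _duration_from_dates(prescription) or prescription.instruction
        if target is None:
            target = prescription.instruction
        if target is None:
            labels[attr] = DISCREPANT
            continue
        a, t = normalize_attribute(attr.text), normalize_attribute(target)
        ok = bool(a) and (a == t or _token_sublist(a, t) or _token_sublist(t, a))
        labels[attr] = MATCHED if ok else DISCREPANT
    return labels


def reconcile_encounter(
    mentions: Sequence[MedicationMention],
    prescriptions: Sequence[Prescription],
    lexicon: Optional[Lexicon] = None,
    memory: Optional[PairMemory] = None,
    config: Optional[MatchConfig] = None,
) -> list[ReconciliationResult]:
    """Reconcile one encounter's mentions against its prescription list.

    Every mention receives exactly one result; an unmatched mention (or one
    with any discrepant attribute) lands in the discrepant bucket.  An empty
    prescription list makes every mention discrepant — it is not an error.
    """
    config = config or MatchConfig()
    enc_ids = {p.encounter_id for p in prescriptions}
    if len(enc_ids) > 1:
        raise UsageError(f"prescriptions from multiple encounters: {enc_ids}")
    rx_by_id = {p.prescription_id: p for p in prescriptions}
    results: list[ReconciliationResult] = []
    for mention in mentions:
        decision = match_medication(
            mention.name_span.text, prescriptions, lexicon, memory, config
        )
        if decision.label == MATCHED:
            attr_labels = match_attributes(mention, rx_by_id[decision.prescription_id])
            if config.route_must_match and any(
                lab == DISCREPANT
                for a, lab in attr_labels.items()
                if a.category == "route"
            ):
                decision = MatchDecision(DISCREPANT, STEP_NONE, None)
                attr_labels = {a: DISCREPANT for a in mention.attributes}
        else:
            # a medication missing from the list drags its attributes along
            attr_labels = {a: DISCREPANT for a in mention.attributes}
        results.append(ReconciliationResult(mention, decision, attr_labels))
    return results
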