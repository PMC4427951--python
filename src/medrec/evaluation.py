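"""Evaluation protocol: P/R/F metrics, cross-validation folds, matched/discrepant
scoring, recall propagation, inter-annotator agreement and corpus statistics.

Entity detection and attribute linkage are scored at the token level;
medication matching at the span level, so each medication and attribute is
counted once.  A matched medication is a true positive *iff* the system
returned ``matched`` and chose the same prescription as the annotators.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .attribute_linkage import MedicationMention
from .corpus_io import DISCREPANT, MATCHED, Encounter, EntitySpan, GoldLink
from .errors import UsageError
from .matching import ReconciliationResult

OVERALL = "overall"


# ---------------------------------------------------------------------------
# P / R / F


def fvalue(p: float, r: float) -> float:
    """Harmonic mean of precision and recall, on the [0, 1] scale."""
    for name, v in (("precision", p), ("recall", r)):
        if not (0.0 <= v <= 1.0):
            raise UsageError(f"{name} must lie in [0, 1]; got {v} (convert percentages first)")
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F with the underlying counts.

    Zero-denominator convention: a precision (or recall) whose denominator
    is zero is reported as 1 — nothing was predicted (or expected) and
    nothing was wrong.
    """

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return 1.0 if self.tp + self.fp == 0 else self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        return 1.0 if self.tp + self.fn == 0 else self.tp / (self.tp + self.fn)

    @property
    def f_value(self) -> float:
        return fvalue(self.precision, self.recall)

    def __add__(self, other: "PRF") -> "PRF":
        return PRF(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def _prf_table(counts: Mapping[str, Counter]) -> dict[str, PRF]:
    table = {
        cat: PRF(c["tp"], c["fp"], c["fn"]) for cat, c in counts.items() if cat != OVERALL
    }
    total = Counter()
    for c in counts.values():
        total.update(c)
    table[OVERALL] = PRF(total["tp"], total["fp"], total["fn"])
    return table


# ---------------------------------------------------------------------------
# token- and span-level scoring


def _label_category(label: str) -> Optional[str]:
    return None if label == "O" else label[2:]


def token_prf(
    gold_labels: Sequence[Sequence[str]], predicted_labels: Sequence[Sequence[str]]
) -> dict[str, PRF]:
    """Token-level P/R/F over non-O labels, per category and overall.

    B-/I- prefixes are collapsed: a token counts as correct when it carries
    the right entity category.
    """
    if len(gold_labels) != len(predicted_labels):
        raise UsageError("gold and predicted sequence counts differ")
    counts: dict[str, Counter] = defaultdict(Counter)
    for gold, pred in zip(gold_labels, predicted_labels):
        if len(gold) != len(pred):
            raise UsageError("gold and predicted label sequences differ in length")
        for g, p in zip(gold, pred):
            gc, pc = _label_category(g), _label_category(p)
            if gc is not None and gc == pc:
                counts[gc]["tp"] += 1
            else:
                if pc is not None:
                    counts[pc]["fp"] += 1
                if gc is not None:
                    counts[gc]["fn"] += 1
    return _prf_table(counts)


def span_prf(
    gold_spans: Iterable[EntitySpan], predicted_spans: Iterable[EntitySpan]
) -> dict[str, PRF]:
    """Exact-boundary, same-category span matching; each gold span credited once."""
    gold_keys = Counter((s.note_id, s.start, s.end, s.category) for s in gold_spans)
    pred_keys = Counter((s.note_id, s.start, s.end, s.category) for s in predicted_spans)
    counts: dict[str, Counter] = defaultdict(Counter)
    for key in gold_keys | pred_keys:
        cat = key[3]
        tp = min(gold_keys[key], pred_keys[key])
        counts[cat]["tp"] += tp
        counts[cat]["fp"] += pred_keys[key] - tp
        counts[cat]["fn"] += gold_keys[key] - tp
    return _prf_table(counts)


def iaa_f(annotations_a: Iterable[EntitySpan], annotations_b: Iterable[EntitySpan]) -> PRF:
    """Inter-annotator agreement as span-level F, with A as the reference."""
    return span_prf(annotations_a, annotations_b)[OVERALL]


# ---------------------------------------------------------------------------
# matched / discrepant scoring


def matching_prf(
    gold_links: Sequence[GoldLink], results: Sequence[ReconciliationResult]
) -> dict[str, dict[str, PRF]]:
    """Score the matching stage against gold links, per side and category.

    Returns ``{"matched": {...}, "discrepant": {...}}`` with a PRF per entity
    category plus overall.  On the matched side a medication is a true
    positive only when the system chose the annotators' prescription.
    Attribute categories are scored analogously from the per-attribute
    labels (a matched attribute additionally requires the medication to be
    matched to the gold prescription).
    """
    gold_by_key = {g.mention.key: g for g in gold_links}
    sys_by_key = {r.mention.key: r for r in results}
    matched: dict[str, Counter] = defaultdict(Counter)
    discrepant: dict[str, Counter] = defaultdict(Counter)

    def attr_key(span: EntitySpan) -> tuple:
        return (span.note_id, span.start, span.end, span.category)

    for key in gold_by_key.keys() | sys_by_key.keys():
        gold = gold_by_key.get(key)
        sys = sys_by_key.get(key)
        # medication level
        g_label = gold.label if gold else None
        g_rx = gold.prescription_id if gold else None
        s_label = sys.decision.label if sys else None
        s_rx = sys.decision.prescription_id if sys else None
        if g_label == MATCHED:
            if s_label == MATCHED and s_rx == g_rx:
                matched["medication_name"]["tp"] += 1
            else:
                matched["medication_name"]["fn"] += 1
                if s_label == MATCHED:
                    matched["medication_name"]["fp"] += 1
        elif s_label == MATCHED:
            matched["medication_name"]["fp"] += 1
        if g_label == DISCREPANT:
            if s_label == DISCREPANT:
                discrepant["medication_name"]["tp"] += 1
            else:
                discrepant["medication_name"]["fn"] += 1
        elif s_label == DISCREPANT:
            discrepant["medication_name"]["fp"] += 1

        # attribute level
        g_attrs = {attr_key(a): lab for a, lab in gold.attribute_labels.items()} if gold else {}
        s_attrs = {attr_key(a): lab for a, lab in sys.attribute_labels.items()} if sys else {}
        rx_agrees = s_label == MATCHED and s_rx == g_rx
        for akey in g_attrs.keys() | s_attrs.keys():
            cat = akey[3]
            ga, sa = g_attrs.get(akey), s_attrs.get(akey)
            if ga == MATCHED:
                if sa == MATCHED and rx_agrees:
                    matched[cat]["tp"] += 1
                else:
                    matched[cat]["fn"] += 1
                    if sa == MATCHED:
                        matched[cat]["fp"] += 1
            elif sa == MATCHED:
                matched[cat]["fp"] += 1
            if ga == DISCREPANT:
                if sa == DISCREPANT:
                    discrepant[cat]["tp"] += 1
                else:
                    discrepant[cat]["fn"] += 1
            elif sa == DISCREPANT:
                discrepant[cat]["fp"] += 1

    return {MATCHED: _prf_table(matched), DISCREPANT: _prf_table(discrepant)}


# ---------------------------------------------------------------------------
# cross-validation folds


@dataclass
class FoldAssignment:
    """Encounter-level fold partition (10-fold by default)."""

    folds: list[list[str]]
    seed: int

    def training_encounters(self, fold_index: int) -> list[str]:
        out: list[str] = []
        for i, fold in enumerate(self.folds):
            if i != fold_index:
                out.extend(fold)
        return out

    def validate_partition(self, encounter_ids: Iterable[str]) -> None:
        seen = [e for fold in self.folds for e in fold]
        if sorted(seen) != sorted(encounter_ids) or len(seen) != len(set(seen)):
            raise UsageError("folds do not partition the encounter set")


def stratified_tenfold(
    encounters: Sequence[Encounter], seed: int, n_folds: int = 10
) -> FoldAssignment:
    """Split encounters into folds, stratified by per-patient note volume.

    Encounters are binned by quartiles of their patient's total note count,
    shuffled within bins and dealt round-robin, so every fold sees a similar
    mix of note-heavy and note-light patients.  Deterministic for a fixed
    seed.
    """
    if len(encounters) < n_folds:
        raise UsageError(f"need at least {n_folds} encounters, got {len(encounters)}")
    notes_per_patient: Counter = Counter()
    for enc in encounters:
        notes_per_patient[enc.patient_id] += len(enc.notes)
    values = np.array([notes_per_patient[e.patient_id] for e in encounters], dtype=float)
    quartiles = np.quantile(values, [0.25, 0.5, 0.75])
    bins: dict[int, list[str]] = defaultdict(list)
    for enc, v in zip(encounters, values):
        bins[int(np.searchsorted(quartiles, v, side="right"))].append(enc.encounter_id)
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    i = 0
    for b in sorted(bins):
        ids = sorted(bins[b])
        rng.shuffle(ids)
        for enc_id in ids:
            folds[i % n_folds].append(enc_id)
            i += 1
    return FoldAssignment(folds, seed)


# ---------------------------------------------------------------------------
# recall propagation


def recall_propagation(
    gold_links: Sequence[GoldLink],
    note_types: Mapping[str, str],
    detected_spans: Mapping[str, Sequence[EntitySpan]],
    linked_mentions: Mapping[str, Sequence[MedicationMention]],
    results: Sequence[ReconciliationResult],
) -> dict[str, dict[str, float]]:
    """Stage-by-stage recall of gold-discrepant medications, per note type.

    Three stages: the medication name survives entity detection (its exact
    span was predicted); it survives attribute linkage (a mention with that
    name span exists — linkage passes names through, so this equals stage
    one); and the system finally places it in the discrepant bucket.
    """
    detected_keys = {
        (s.note_id, s.start, s.end)
        for spans in detected_spans.values()
        for s in spans
        if s.category == "medication_name"
    }
    linked_keys = {m.key for ms in linked_mentions.values() for m in ms}
    discrepant_keys = {r.mention.key for r in results if r.final_bucket == DISCREPANT}

    per_type: dict[str, Counter] = defaultdict(Counter)
    for link in gold_links:
        if link.bucket != DISCREPANT:
            continue
        key = link.mention.key
        ntype = note_types[key[0]]
        per_type[ntype]["gold"] += 1
        if key in detected_keys:
            per_type[ntype]["detected"] += 1
        if key in linked_keys and key in detected_keys:
            per_type[ntype]["linked"] += 1
        if key in discrepant_keys:
            per_type[ntype]["final"] += 1
    out: dict[str, dict[str, float]] = {}
    for ntype, c in per_type.items():
        n = c["gold"]
        out[ntype] = {
            "entity_detection": c["detected"] / n,
            "attribute_linkage": c["linked"] / n,
            "medication_matching": c["final"] / n,
        }
    return out


# ---------------------------------------------------------------------------
# descriptive corpus statistics


@dataclass
class CorpusCounts:
    """Raw descriptive counts of an annotated reconciliation corpus."""

    patients: int = 0
    encounters: int = 0
    overview_notes: int = 0
    discharge_summaries: int = 0
    discharge_summaries_available: Optional[int] = None
    entities_total: int = 0
    entities_discrepant: int = 0
    entities_overview: int = 0
    entities_discharge_summaries: int = 0
    patients_with_discrepancy: int = 0
    encounters_with_discrepancy: int = 0
    entities_by_category: dict[str, int] = field(default_factory=dict)

    def derived(self) -> dict[str, float]:
        """Derived fractions and densities, on the percentage scale where apt."""

        def pct(num: int, den: Optional[int]) -> float:
            return float("nan") if not den else 100.0 * num / den

        return {
            "discrepant_fraction_pct": pct(self.entities_discrepant, self.entities_total),
            "patient_coverage_pct": pct(self.patients_with_discrepancy, self.patients),
            "encounter_coverage_pct": pct(self.encounters_with_discrepancy, self.encounters),
            "discharge_summary_sampling_pct": pct(
                self.discharge_summaries, self.discharge_summaries_available
            ),
            "entities_per_discharge_summary": (
                self.entities_discharge_summaries / self.discharge_summaries
                if self.discharge_summaries
                else 0.0
            ),
            "entities_per_overview_note": (
                self.entities_overview / self.overview_notes if self.overview_notes else 0.0
            ),
        }

    @staticmethod
    def from_json(path_or_mapping) -> "CorpusCounts":
        if isinstance(path_or_mapping, Mapping):
            data = dict(path_or_mapping)
        else:
            with open(path_or_mapping, encoding="utf-8") as fh:
                data = json.load(fh)
        return CorpusCounts(**data)


def reference_corpus_counts() -> CorpusCounts:
    """Descriptive counts of the real reference corpus (shipped fixture)."""
    text = resources.files("medrec.data").joinpath("reference_corpus_counts.json").read_text(
        "utf-8"
    )
    return CorpusCounts.from_json(json.loads(text))


def corpus_stats(
    encounters: Sequence[Encounter],
    annotations: Mapping[str, Sequence[EntitySpan]],
    gold_links: Sequence[GoldLink] = (),
    discharge_summaries_available: Optional[int] = None,
) -> CorpusCounts:
    """Compute descriptive counts for an annotated corpus.

    Discrepant-entity counts come from the gold links: a medication name is
    discrepant when its link's bucket is discrepant; an attribute when its
    gold label is discrepant.
    """
    counts = CorpusCounts(discharge_summaries_available=discharge_summaries_available)
    counts.patients = len({e.patient_id for e in encounters})
    counts.encounters = len(encounters)
    note_type: dict[str, str] = {}
    for enc in encounters:
        for note in enc.notes:
            note_type[note.note_id] = note.note_type
            if note.note_type == "overview":
                counts.overview_notes += 1
            else:
                counts.discharge_summaries += 1
    for note_id, spans in annotations.items():
        for s in spans:
            counts.entities_total += 1
            counts.entities_by_category[s.category] = (
                counts.entities_by_category.get(s.category, 0) + 1
            )
            if note_type.get(note_id) == "overview":
                counts.entities_overview += 1
            else:
                counts.entities_discharge_summaries += 1

    note_to_encounter = {
        n.note_id: enc for enc in encounters for n in enc.notes
    }
    discrepant_patients: set[str] = set()
    discrepant_encounters: set[str] = set()
    for link in gold_links:
        # the medication name counts as discrepant only when the medication
        # itself lacks a counterpart; attribute disagreements count per span
        if link.label == DISCREPANT:
            counts.entities_discrepant += 1
        counts.entities_discrepant += sum(
            1 for lab in link.attribute_labels.values() if lab == DISCREPANT
        )
        if link.bucket == DISCREPANT:
            enc = note_to_encounter.get(link.mention.note_id)
            if enc is not None:
                discrepant_patients.add(enc.patient_id)
                discrepant_encounters.add(enc.encounter_id)
    counts.patients_with_discrepancy = len(discrepant_patients)
    counts.encounters_with_discrepancy = len(discrepant_encounters)
    return counts
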