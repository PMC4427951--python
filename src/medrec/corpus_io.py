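"""Data model and on-disk formats for encounters, notes, annotations and prescriptions.

An *encounter* (one inpatient visit) bundles the free-text clinical notes
written during the stay with the structured discharge prescription list.
Medication information in the notes is annotated as character-offset entity
spans over eight categories: the medication name itself plus seven attribute
categories (amount, dosage, duration, form, frequency, route, strength).

On-disk layout of a corpus directory::

    notes/<note_id>.txt        one UTF-8 text file per note
    notes.csv                  note metadata (note_id, encounter_id, patient_id, note_type)
    ann/<note_id>.tsv          standoff annotations, tab-separated
    prescriptions.csv          one row per prescription
    gold_links.json            gold matched/discrepant labels (optional)

Standoff lines are ``category<TAB>start<TAB>end<TAB>surface text`` with
0-based, half-open character offsets into the note text.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import IntegrityError, SchemaError, StandoffParseError, UsageError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .attribute_linkage import MedicationMention
    from .matching import ReconciliationResult

#: The eight entity categories, medication name first.
CATEGORIES: tuple[str, ...] = (
    "medication_name",
    "amount",
    "dosage",
    "duration",
    "form",
    "frequency",
    "route",
    "strength",
)

#: The seven attribute categories (everything but the name).
ATTRIBUTE_CATEGORIES: tuple[str, ...] = CATEGORIES[1:]

NOTE_TYPES: tuple[str, ...] = ("overview", "discharge_summary")

MATCHED = "matched"
DISCREPANT = "discrepant"


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A character-offset span in one note, carrying one entity category."""

    note_id: str
    start: int
    end: int
    category: str
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise IntegrityError(
                f"invalid span offsets [{self.start}, {self.end}) in note {self.note_id}"
            )
        if self.category not in CATEGORIES:
            raise IntegrityError(f"unknown entity category {self.category!r}")

    def validate_against(self, note: "ClinicalNote") -> None:
        """Check text/offset consistency against the note this span points into."""
        if self.note_id != note.note_id:
            raise UsageError(f"span belongs to note {self.note_id}, not {note.note_id}")
        if self.end > len(note.text):
            raise IntegrityError(
                f"span [{self.start}, {self.end}) exceeds note {note.note_id} "
                f"of length {len(note.text)}"
            )
        actual = note.text[self.start : self.end]
        if actual != self.text:
            raise IntegrityError(
                f"span text mismatch in note {note.note_id} at [{self.start}, {self.end}): "
                f"annotation says {self.text!r}, note has {actual!r}"
            )


@dataclass
class ClinicalNote:
    """One free-text note; either a problem overview note or a discharge summary."""

    note_id: str
    encounter_id: str
    patient_id: str
    note_type: str
    text: str

    def __post_init__(self) -> None:
        if self.note_type not in NOTE_TYPES:
            raise IntegrityError(f"unknown note type {self.note_type!r}")
        if self.text is None:
            raise IntegrityError("note text must not be null")


@dataclass
class Prescription:
    """One structured discharge-prescription record."""

    prescription_id: str
    patient_id: str
    encounter_id: str
    name: str
    generic_name: Optional[str] = None
    instruction: Optional[str] = None
    route: Optional[str] = None
    frequency: Optional[str] = None
    strength: Optional[str] = None
    form: Optional[str] = None
    ordering_date: Optional[_dt.date] = None
    start_date: Optional[_dt.date] = None
    end_date: Optional[_dt.date] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise IntegrityError("prescription name must be non-empty")
        if (
            self.start_date is not None
            and self.end_date is not None
            and self.start_date > self.end_date
        ):
            raise IntegrityError(
                f"prescription {self.prescription_id}: start_date "
                f"{self.start_date} after end_date {self.end_date}"
            )

    def attribute_field(self, category: str) -> Optional[str]:
        """The structured field corresponding to an attribute category, if any."""
        return {
            "route": self.route,
            "frequency": self.frequency,
            "strength": self.strength,
            "form": self.form,
        }.get(category)


@dataclass
class Encounter:
    """One patient visit: its notes plus its discharge prescription list."""

    encounter_id: str
    patient_id: str
    notes: list[ClinicalNote] = field(default_factory=list)
    prescriptions: list[Prescription] = field(default_factory=list)

    def __post_init__(self) -> None:
        for n in self.notes:
            if n.encounter_id != self.encounter_id:
                raise IntegrityError(
                    f"note {n.note_id} carries encounter {n.encounter_id}, "
                    f"expected {self.encounter_id}"
                )
        for p in self.prescriptions:
            if p.encounter_id != self.encounter_id:
                raise IntegrityError(
                    f"prescription {p.prescription_id} carries encounter "
                    f"{p.encounter_id}, expected {self.encounter_id}"
                )


@dataclass
class GoldLink:
    """Annotator verdict for one medication mention.

    ``label`` records whether the mention has a counterpart prescription;
    ``attribute_labels`` records per-attribute agreement with that
    prescription.  A mention lands in the discrepant bucket when either the
    medication itself is discrepant (no counterpart) or any linked attribute
    is discrepant.
    """

    mention: "MedicationMention"
    prescription_id: Optional[str]
    label: str
    attribute_labels: dict[EntitySpan, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (MATCHED, DISCREPANT):
            raise IntegrityError(f"unknown gold label {self.label!r}")
        if self.label == MATCHED and self.prescription_id is None:
            raise IntegrityError("a matched gold link requires a prescription_id")
        if self.prescription_id is None and self.label != DISCREPANT:
            raise IntegrityError("an absent prescription implies a discrepant label")

    @property
    def bucket(self) -> str:
        """Final matched/discrepant bucket, folding in attribute verdicts."""
        if self.label == DISCREPANT:
            return DISCREPANT
        if any(v == DISCREPANT for v in self.attribute_labels.values()):
            return DISCREPANT
        return MATCHED


# ---------------------------------------------------------------------------
# standoff annotations


def read_standoff_annotations(path: str | Path, note: ClinicalNote) -> list[EntitySpan]:
    """Read tab-separated standoff annotations for one note.

    Every span is validated against the note text; a mismatch between the
    recorded surface string and the note substring raises
    :class:`IntegrityError`.
    """
    spans: list[EntitySpan] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise StandoffParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            category, start_s, end_s, text = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise StandoffParseError(f"{path}:{lineno}: non-integer offsets") from exc
            span = EntitySpan(note.note_id, start, end, category, text)
            span.validate_against(note)
            spans.append(span)
    return spans


def write_standoff_annotations(spans: Iterable[EntitySpan], path: str | Path) -> None:
    """Write spans as one tab-separated record per line, sorted by offset."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sorted(spans, key=lambda s: (s.start, s.end, s.category)):
            if "\t" in s.text or "\n" in s.text:
                raise IntegrityError("span text may not contain tabs or newlines")
            fh.write(f"{s.category}\t{s.start}\t{s.end}\t{s.text}\n")


# ---------------------------------------------------------------------------
# prescriptions

_MANDATORY_RX_COLUMNS = ("prescription_id", "patient_id", "encounter_id", "name")
_OPTIONAL_RX_COLUMNS = (
    "generic_name",
    "instruction",
    "route",
    "frequency",
    "strength",
    "form",
    "ordering_date",
    "start_date",
    "end_date",
)
_DATE_COLUMNS = ("ordering_date", "start_date", "end_date")


def _parse_date(value: object) -> Optional[_dt.date]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def read_prescription_table(path: str | Path) -> list[Prescription]:
    """Read a CSV/TSV prescription table (delimiter chosen by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_RX_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    out: list[Prescription] = []
    for _, row in df.iterrows():
        kwargs: dict[str, object] = {c: row[c] for c in _MANDATORY_RX_COLUMNS}
        for c in _OPTIONAL_RX_COLUMNS:
            v = row[c] if c in df.columns else ""
            if c in _DATE_COLUMNS:
                kwargs[c] = _parse_date(v)
            else:
                kwargs[c] = v if v != "" else None
        out.append(Prescription(**kwargs))  # type: ignore[arg-type]
    return out


def write_prescription_table(prescriptions: Iterable[Prescription], path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    rows = []
    for p in prescriptions:
        d = dataclasses.asdict(p)
        for c in _DATE_COLUMNS:
            d[c] = d[c].isoformat() if d[c] is not None else ""
        rows.append(d)
    cols = list(_MANDATORY_RX_COLUMNS) + list(_OPTIONAL_RX_COLUMNS)
    pd.DataFrame(rows, columns=cols).fillna("").to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# reconciliation report


def _span_to_json(s: EntitySpan) -> dict:
    return {
        "note_id": s.note_id,
        "start": s.start,
        "end": s.end,
        "category": s.category,
        "text": s.text,
    }


def _span_from_json(d: Mapping) -> EntitySpan:
    return EntitySpan(d["note_id"], d["start"], d["end"], d["category"], d["text"])


def _result_to_json(r: "ReconciliationResult") -> dict:
    return {
        "mention": {
            "name_span": _span_to_json(r.mention.name_span),
            "attributes": [_span_to_json(a) for a in r.mention.attributes],
        },
        "label": r.decision.label,
        "step": r.decision.step,
        "prescription_id": r.decision.prescription_id,
        "attribute_labels": [
            {"span": _span_to_json(a), "label": lab} for a, lab in r.attribute_labels.items()
        ],
    }


def write_reconciliation_report(
    results: Mapping[str, Sequence["ReconciliationResult"]], path: str | Path
) -> None:
    """Write the per-encounter matched / discrepant medication lists as JSON.

    ``results`` maps encounter_id to that encounter's reconciliation results.
    """
    report = {}
    for encounter_id, res in results.items():
        report[encounter_id] = {
            "matched": [_result_to_json(r) for r in res if r.final_bucket == MATCHED],
            "discrepant": [_result_to_json(r) for r in res if r.final_bucket == DISCREPANT],
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_reconciliation_report(path: str | Path) -> dict[str, list["ReconciliationResult"]]:
    """Re-parse a reconciliation report into in-memory results."""
    from .attribute_linkage import MedicationMention
    from .matching import MatchDecision, ReconciliationResult

    with open(path, encoding="utf-8") as fh:
        report = json.load(fh)
    out: dict[str, list[ReconciliationResult]] = {}
    for encounter_id, buckets in report.items():
        res: list[ReconciliationResult] = []
        for bucket in ("matched", "discrepant"):
            for d in buckets[bucket]:
                name = _span_from_json(d["mention"]["name_span"])
                attrs = tuple(_span_from_json(a) for a in d["mention"]["attributes"])
                mention = MedicationMention(name, attrs)
                decision = MatchDecision(d["label"], d["step"], d["prescription_id"])
                attr_labels = {
                    _span_from_json(e["span"]): e["label"] for e in d["attribute_labels"]
                }
                res.append(ReconciliationResult(mention, decision, attr_labels))
        out[encounter_id] = res
    return out


# ---------------------------------------------------------------------------
# whole-corpus directory layout


def write_corpus_dir(
    encounters: Sequence[Encounter],
    annotations: Mapping[str, Sequence[EntitySpan]],
    out_dir: str | Path,
) -> None:
    """Write notes, note metadata, annotations and prescriptions under ``out_dir``."""
    out = Path(out_dir)
    (out / "notes").mkdir(parents=True, exist_ok=True)
    (out / "ann").mkdir(parents=True, exist_ok=True)
    meta_rows = []
    prescriptions: list[Prescription] = []
    for enc in encounters:
        for note in enc.notes:
            (out / "notes" / f"{note.note_id}.txt").write_text(note.text, encoding="utf-8")
            meta_rows.append(
                {
                    "note_id": note.note_id,
                    "encounter_id": note.encounter_id,
                    "patient_id": note.patient_id,
                    "note_type": note.note_type,
                }
            )
            write_standoff_annotations(
                annotations.get(note.note_id, []), out / "ann" / f"{note.note_id}.tsv"
            )
        prescriptions.extend(enc.prescriptions)
    pd.DataFrame(
        meta_rows, columns=["note_id", "encounter_id", "patient_id", "note_type"]
    ).to_csv(out / "notes.csv", index=False)
    write_prescription_table(prescriptions, out / "prescriptions.csv")


def read_corpus_dir(
    in_dir: str | Path,
) -> tuple[list[Encounter], dict[str, list[EntitySpan]]]:
    """Read a corpus directory back into encounters plus per-note annotations."""
    root = Path(in_dir)
    meta = pd.read_csv(root / "notes.csv", dtype=str)
    prescriptions = read_prescription_table(root / "prescriptions.csv")
    encounters: dict[str, Encounter] = {}
    annotations: dict[str, list[EntitySpan]] = {}
    for _, row in meta.iterrows():
        text = (root / "notes" / f"{row.note_id}.txt").read_text(encoding="utf-8")
        note = ClinicalNote(row.note_id, row.encounter_id, row.patient_id, row.note_type, text)
        enc = encounters.setdefault(
            note.encounter_id, Encounter(note.encounter_id, note.patient_id)
        )
        enc.notes.append(note)
        ann_path = root / "ann" / f"{note.note_id}.tsv"
        annotations[note.note_id] = (
            read_standoff_annotations(ann_path, note) if ann_path.exists() else []
        )
    for p in prescriptions:
        if p.encounter_id not in encounters:
            encounters[p.encounter_id] = Encounter(p.encounter_id, p.patient_id)
        encounters[p.encounter_id].prescriptions.append(p)
    return list(encounters.values()), annotations
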