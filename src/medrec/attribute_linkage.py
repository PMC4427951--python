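"""Attribute linkage: associate each detected attribute with a medication name.

Each attribute span (strength, route, frequency, ...) is linked to the
closest medication-name span in the same note by absolute character
distance, whether the name precedes or follows the attribute.  Distance is
the gap between the two character intervals (0 for overlapping spans).
When an attribute sits exactly equidistant between two names, the preceding
name wins — dosing attributes conventionally follow the drug they modify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .corpus_io import ClinicalNote, EntitySpan
from .errors import UsageError


@dataclass(frozen=True)
class MedicationMention:
    """A medication-name span plus the attribute spans linked to it."""

    name_span: EntitySpan
    attributes: tuple[EntitySpan, ...] = ()

    def __post_init__(self) -> None:
        for a in self.attributes:
            if a.note_id != self.name_span.note_id:
                raise UsageError(
                    f"attribute from note {a.note_id} linked to a name in note "
                    f"{self.name_span.note_id}"
                )

    @property
    def note_id(self) -> str:
        return self.name_span.note_id

    @property
    def key(self) -> tuple[str, int, int]:
        """Identity of the mention: its name span's location."""
        return (self.name_span.note_id, self.name_span.start, self.name_span.end)


@dataclass
class LinkageResult:
    """Mentions formed in one note, plus attributes left unlinked (no name present)."""

    mentions: list[MedicationMention] = field(default_factory=list)
    unlinked: list[EntitySpan] = field(default_factory=list)


def char_distance(span_a: EntitySpan, span_b: EntitySpan) -> int:
    """Gap between two character intervals; 0 when they touch or overlap."""
    if span_a.note_id != span_b.note_id:
        raise UsageError("char_distance requires spans from the same note")
    return max(0, max(span_a.start, span_b.start) - min(span_a.end, span_b.end))


def link_attributes(
    spans: Sequence[EntitySpan], note: Optional[ClinicalNote] = None
) -> LinkageResult:
    """Group one note's entity spans into medication mentions.

    Every attribute goes to exactly one medication name (minimum character
    gap; ties prefer the preceding name).  Names with no nearby attributes
    become mentions with empty attribute sets.  If the note has no
    medication name at all, every attribute is reported as unlinked.
    """
    note_ids = {s.note_id for s in spans}
    if len(note_ids) > 1:
        raise UsageError(f"spans from multiple notes passed to link_attributes: {note_ids}")
    names = sorted(
        (s for s in spans if s.category == "medication_name"), key=lambda s: s.start
    )
    attributes = sorted(
        (s for s in spans if s.category != "medication_name"), key=lambda s: s.start
    )
    if not names:
        return LinkageResult(mentions=[], unlinked=list(attributes))

    assigned: dict[EntitySpan, list[EntitySpan]] = {n: [] for n in names}
    for attr in attributes:
        best = None
        best_dist = None
        for name in names:
            d = char_distance(attr, name)
            if best is None or d < best_dist:
                best, best_dist = name, d
            elif d == best_dist:
                # tie: prefer the name that precedes the attribute; if both
                # candidates precede (or both follow), keep the earlier winner,
                # which is the preceding-most due to the start-order scan
                if name.end <= attr.start and not (best.end <= attr.start):
                    best, best_dist = name, d
        assigned[best].append(attr)

    mentions = [
        MedicationMention(name, tuple(sorted(assigned[name], key=lambda s: s.start)))
        for name in names
    ]
    return LinkageResult(mentions=mentions, unlinked=[])
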