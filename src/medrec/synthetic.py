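"""Synthetic reconciliation corpora: encounters, notes, gold annotations and links.

The generator emulates the data the discrepancy-detection pipeline assumes:
encounters carrying problem overview notes and a discharge summary, a
structured discharge prescription list, gold entity annotations over the
eight categories, gold attribute links and gold matched/discrepant labels,
plus a drug-lexicon fixture with trade-name relations.

Notes are built from templates ("Continue <MED> <STRENGTH> <FORM> <ROUTE>
<FREQUENCY>", bulleted discharge-medication lists, distractor sentences) so
character offsets are exact by construction.  Discharge summaries use a
fully controlled vocabulary; abbreviation and misspelling noise — the
documented failure modes of dictionary-free mentions — is injected into
overview notes only.

Defaults encode the study conditions: a ~7.5% per-medication discrepancy
rate split between missing-prescription and attribute-mismatch injections,
attribute inclusion probabilities proportional to the reference corpus's
category frequencies, and a few dozen patients with several encounters
each.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .attribute_linkage import MedicationMention
from .corpus_io import (
    ATTRIBUTE_CATEGORIES,
    DISCREPANT,
    MATCHED,
    ClinicalNote,
    Encounter,
    EntitySpan,
    GoldLink,
    Prescription,
    write_corpus_dir,
)
from .errors import ConfigError
from .lexicon import Lexicon, LexiconEntry

# hand-written real entries exercised by the matching cascade's documented
# behaviors (synonym co-occurrence, trade names, ingredient false positives)
SPECIAL_ENTRIES: tuple[tuple[str, str, str, str], ...] = (
    ("3322", "ingredient", "diazepam", ""),
    ("2052646", "brand", "diazepam rectal gel [diastat]", "3322"),
    ("151390", "clinical_drug", "ipratropium 500 mg/2.5 ml - albuterol 2.5 mg/0.5 ml nebulizer solution", ""),
    ("285163", "clinical_drug", "glycerin polyethylene glycol ophthalmic solution [artificial tears]", ""),
    ("6902", "ingredient", "methylprednisolone", ""),
    ("8638", "ingredient", "prednisolone", ""),
    ("723", "ingredient", "amoxicillin clavulanate", ""),
    ("151399", "brand", "amoxicillin clavulanate oral tablet [augmentin]", "723"),
)

_ING_HEADS = ("bal", "cort", "dal", "fenn", "lum", "mar", "nor", "pex", "quil", "rov",
              "sen", "tam", "vor", "zel", "gad", "hul", "jor", "kel", "mig", "ost")
_ING_TAILS = ("azole", "opril", "olol", "omycin", "astatin", "icillin", "umab", "avir",
              "ocaine", "ylline", "idone", "ettine")
_BRAND_HEADS = ("bri", "cla", "dur", "fle", "gla", "jus", "kev", "lyn", "plo", "ves",
                "wi", "ya", "zo", "tru", "rel")
_BRAND_TAILS = ("eza", "ivo", "ara", "eon", "ovi", "uly", "esse", "ute")

_STRENGTHS = ("2.5 mg", "5 mg", "10 mg", "20 mg", "25 mg", "50 mg", "100 mg")
_FORMS = ("tab", "capsule", "solution", "suspension", "syrup")
_ROUTES = ("po", "oral", "pr", "topical")
_FREQS = ("bid", "tid", "daily", "qid", "qhs", "prn")
_AMOUNTS = ("1 tab", "2 tab", "1 capsule", "5 ml", "2 ml")
_DOSAGES = ("2 ml", "5 ml", "10 ml")
_DURATION_DAYS = (7, 10, 14, 30)

_CONDITIONS = ("asthma", "reflux", "seizures", "constipation", "spasticity", "eczema")
_DISTRACTORS = (
    "Patient is doing well at home.",
    "Family has no new concerns today.",
    "Follow up with primary care in two weeks.",
    "Vital signs were stable throughout the stay.",
)
# separator long enough that an attribute is always strictly closer to its own
# medication name than to the next mention's name (worst-case in-mention gap
# between a name and its farthest attribute is under 70 characters)
_BULLET_FILLER = "  Medication list reviewed with the family and verified against the chart.\n"

MISSING_PRESCRIPTION = "missing_prescription"
ATTRIBUTE_MISMATCH = "attribute_mismatch"

#: attribute categories whose mismatch injection perturbs a structured field
_PERTURBABLE = ("route", "frequency", "strength", "form")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults are the study conditions."""

    n_patients: int = 30
    encounters_per_patient: tuple[int, int] = (1, 3)
    overview_notes_per_encounter: tuple[int, int] = (1, 2)
    meds_per_encounter: tuple[int, int] = (4, 8)
    meds_per_overview: tuple[int, int] = (1, 3)
    attribute_probs: dict[str, float] = field(
        default_factory=lambda: {
            "amount": 0.43,
            "dosage": 0.21,
            "duration": 0.09,
            "form": 0.47,
            "frequency": 0.73,
            "route": 0.42,
            "strength": 0.44,
        }
    )
    discrepancy_rate: float = 0.075
    discrepancy_mix: dict[str, float] = field(
        default_factory=lambda: {MISSING_PRESCRIPTION: 0.5, ATTRIBUTE_MISMATCH: 0.5}
    )
    brand_mention_prob: float = 0.15
    abbreviation_rate: float = 0.05
    misspelling_rate: float = 0.03
    noisy_note_types: tuple[str, ...] = ("overview",)
    lexicon_size: int = 40
    seed: int = 0

    def validate(self) -> None:
        for cat, p in self.attribute_probs.items():
            if cat not in ATTRIBUTE_CATEGORIES or not (0.0 <= p <= 1.0):
                raise ConfigError(f"bad attribute probability {cat}={p}")
        if not (0.0 <= self.discrepancy_rate <= 1.0):
            raise ConfigError("discrepancy_rate must lie in [0, 1]")
        if abs(sum(self.discrepancy_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("discrepancy_mix must sum to 1")
        if set(self.discrepancy_mix) - {MISSING_PRESCRIPTION, ATTRIBUTE_MISMATCH}:
            raise ConfigError("unknown discrepancy type in mix")
        for r in (self.brand_mention_prob, self.abbreviation_rate, self.misspelling_rate):
            if not (0.0 <= r <= 1.0):
                raise ConfigError("noise rates must lie in [0, 1]")
        if self.discrepancy_rate > 0 and self.meds_per_encounter[1] < 1:
            raise ConfigError("discrepancy_rate > 0 requires medications to exist")
        if self.lexicon_size < 10:
            raise ConfigError("lexicon_size must be at least 10")


# ---------------------------------------------------------------------------
# drug catalog and lexicon fixture


@dataclass(frozen=True)
class DrugEntry:
    """One generated drug: ingredient, optional brand, and lexicon codes."""

    ingredient: str
    brand: Optional[str]
    ingredient_code: str
    drug_code: str
    brand_code: Optional[str]
    abbreviation: Optional[str]


def _substring_free(name: str, existing: Sequence[str]) -> bool:
    return all(name not in e and e not in name for e in existing)


def _generate_names(
    rng: np.random.Generator, heads: Sequence[str], tails: Sequence[str], n: int,
    avoid: Sequence[str],
) -> list[str]:
    names: list[str] = []
    taken = list(avoid)
    attempts = 0
    while len(names) < n and attempts < 50 * n:
        attempts += 1
        name = rng.choice(heads) + rng.choice(tails)
        if _substring_free(name, taken):
            names.append(name)
            taken.append(name)
    if len(names) < n:
        raise ConfigError(f"could not generate {n} substring-free drug names")
    return names


def _special_terms() -> list[str]:
    return [t for _, _, desc, _ in SPECIAL_ENTRIES for t in desc.split()]


def generate_drug_catalog(size: int, seed: int) -> list[DrugEntry]:
    """Deterministic catalog of pseudo-drugs; ~40% carry a trade name."""
    rng = np.random.default_rng(seed)
    avoid = _special_terms()
    ingredients = _generate_names(rng, _ING_HEADS, _ING_TAILS, size, avoid)
    n_brands = int(round(0.4 * size))
    brands = _generate_names(rng, _BRAND_HEADS, _BRAND_TAILS, n_brands, avoid + ingredients)
    catalog: list[DrugEntry] = []
    taken_abbrevs: list[str] = []
    for i, ing in enumerate(ingredients):
        brand = brands[i] if i < n_brands else None
        abbrev = ing[:3] + "x"
        if not _substring_free(abbrev, ingredients + brands + taken_abbrevs):
            abbrev = None
        else:
            taken_abbrevs.append(abbrev)
        catalog.append(
            DrugEntry(
                ingredient=ing,
                brand=brand,
                ingredient_code=f"I{1000 + i}",
                drug_code=f"D{1000 + i}",
                brand_code=f"B{1000 + i}" if brand else None,
                abbreviation=abbrev,
            )
        )
    return catalog


def build_lexicon(catalog: Sequence[DrugEntry]) -> Lexicon:
    """Lexicon fixture over a catalog, plus the hand-written real entries."""
    entries = [
        LexiconEntry(code, desc, term_type)
        for code, term_type, desc, _ in SPECIAL_ENTRIES
    ]
    relations = [
        (code, rel) for code, _, _, rel in SPECIAL_ENTRIES if rel
    ]
    for d in catalog:
        entries.append(LexiconEntry(d.ingredient_code, d.ingredient, "ingredient"))
        entries.append(
            LexiconEntry(d.drug_code, f"{d.ingredient} oral tab", "clinical_drug")
        )
        if d.brand:
            entries.append(
                LexiconEntry(d.brand_code, f"{d.ingredient} oral tab [{d.brand}]", "brand")
            )
            relations.append((d.brand_code, d.ingredient_code))
    return Lexicon(entries, relations)


def generate_lexicon_fixture(size: int, seed: int) -> Lexicon:
    """Deterministic lexicon fixture (includes the diastat/diazepam entry)."""
    return build_lexicon(generate_drug_catalog(size, seed))


# ---------------------------------------------------------------------------
# note construction


class _NoteBuilder:
    def __init__(self, note_id: str) -> None:
        self.note_id = note_id
        self._parts: list[str] = []
        self._len = 0
        self.spans: list[EntitySpan] = []

    def add(self, text: str) -> None:
        self._parts.append(text)
        self._len += len(text)

    def add_span(self, text: str, category: str) -> EntitySpan:
        span = EntitySpan(self.note_id, self._len, self._len + len(text), category, text)
        self.spans.append(span)
        self.add(text)
        return span

    @property
    def text(self) -> str:
        return "".join(self._parts)


@dataclass
class _Medication:
    """One encounter medication with its canonical attribute values."""

    drug: DrugEntry
    strength: str
    form: str
    route: str
    frequency: str
    amount: str
    dosage: str
    duration_days: int
    prescription_id: str

    @property
    def duration(self) -> str:
        return f"for {self.duration_days} days"

    def attribute_value(self, category: str) -> str:
        return {
            "amount": self.amount,
            "dosage": self.dosage,
            "duration": self.duration,
            "form": self.form,
            "frequency": self.frequency,
            "route": self.route,
            "strength": self.strength,
        }[category]


@dataclass
class Corpus:
    """An in-memory synthetic corpus: the input of every pipeline stage."""

    encounters: list[Encounter]
    annotations: dict[str, list[EntitySpan]]
    gold_links: list[GoldLink]
    lexicon: Lexicon
    config: GeneratorConfig
    n_medications: int = 0  # distinct (encounter, drug) pairs generated
    n_discrepant_medications: int = 0  # of those, how many received an injection

    @property
    def notes_by_id(self) -> dict[str, ClinicalNote]:
        return {n.note_id: n for e in self.encounters for n in e.notes}

    @property
    def note_types(self) -> dict[str, str]:
        return {n.note_id: n.note_type for e in self.encounters for n in e.notes}

    def gold_mentions(self, note_id: str) -> list[MedicationMention]:
        return [g.mention for g in self.gold_links if g.mention.note_id == note_id]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        write_corpus_dir(self.encounters, self.annotations, out)
        self.lexicon.save(out / "lexicon.tsv")
        _write_gold_links(self.gold_links, out / "gold_links.json")


def _write_gold_links(links: Sequence[GoldLink], path: Path) -> None:
    import json

    def span_d(s: EntitySpan) -> dict:
        return {"note_id": s.note_id, "start": s.start, "end": s.end,
                "category": s.category, "text": s.text}

    payload = [
        {
            "name_span": span_d(g.mention.name_span),
            "attributes": [span_d(a) for a in g.mention.attributes],
            "prescription_id": g.prescription_id,
            "label": g.label,
            "attribute_labels": [
                {"span": span_d(a), "label": lab} for a, lab in g.attribute_labels.items()
            ],
        }
        for g in links
    ]
    path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_gold_links(path: str | Path) -> list[GoldLink]:
    import json

    def span(d: dict) -> EntitySpan:
        return EntitySpan(d["note_id"], d["start"], d["end"], d["category"], d["text"])

    out = []
    for g in json.loads(Path(path).read_text(encoding="utf-8")):
        mention = MedicationMention(
            span(g["name_span"]), tuple(span(a) for a in g["attributes"])
        )
        out.append(
            GoldLink(
                mention,
                g["prescription_id"],
                g["label"],
                {span(e["span"]): e["label"] for e in g["attribute_labels"]},
            )
        )
    return out


# ---------------------------------------------------------------------------
# generation


def _rand_range(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    lo, hi = lohi
    return int(rng.integers(lo, hi + 1))


def _misspell(word: str, rng: np.random.Generator) -> str:
    if len(word) < 4:
        return word
    i = int(rng.integers(1, len(word) - 2))
    return word[:i] + word[i + 1] + word[i] + word[i + 2 :]


def _mention_surface(
    med: _Medication, note_type: str, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[str, bool]:
    """Surface form of a mention and whether it was noise-corrupted."""
    if med.drug.brand and rng.random() < config.brand_mention_prob:
        return med.drug.brand, False
    name = med.drug.ingredient
    if note_type in config.noisy_note_types:
        r = rng.random()
        if med.drug.abbreviation and r < config.abbreviation_rate:
            return med.drug.abbreviation, True
        if r < config.abbreviation_rate + config.misspelling_rate:
            return _misspell(name, rng), True
    return name, False


def _emit_mention(
    builder: _NoteBuilder,
    med: _Medication,
    surface: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> MedicationMention:
    """Append one templated medication sentence, returning the gold mention."""
    verb = ("Continue", "Resume", "Give")[int(rng.integers(0, 3))]
    builder.add(f"{verb} ")
    name_span = builder.add_span(surface, "medication_name")
    attrs: list[EntitySpan] = []
    for cat in ("strength", "form", "route", "frequency"):
        if rng.random() < config.attribute_probs[cat]:
            builder.add(" ")
            attrs.append(builder.add_span(med.attribute_value(cat), cat))
    tail: list[tuple[str, str]] = []
    for cat in ("amount", "dosage", "duration"):
        if rng.random() < config.attribute_probs[cat]:
            tail.append((cat, med.attribute_value(cat)))
    if tail:
        builder.add(", take ")
        for k, (cat, value) in enumerate(tail):
            if k:
                builder.add(" ")
            attrs.append(builder.add_span(value, cat))
    builder.add(".")
    return MedicationMention(name_span, tuple(attrs))


def _make_medication(
    drug: DrugEntry, prescription_id: str, rng: np.random.Generator
) -> _Medication:
    return _Medication(
        drug=drug,
        strength=str(rng.choice(_STRENGTHS)),
        form=str(rng.choice(_FORMS)),
        route=str(rng.choice(_ROUTES)),
        frequency=str(rng.choice(_FREQS)),
        amount=str(rng.choice(_AMOUNTS)),
        dosage=str(rng.choice(_DOSAGES)),
        duration_days=int(rng.choice(_DURATION_DAYS)),
        prescription_id=prescription_id,
    )


def _make_prescription(
    med: _Medication, patient_id: str, encounter_id: str, discharge: _dt.date
) -> Prescription:
    return Prescription(
        prescription_id=med.prescription_id,
        patient_id=patient_id,
        encounter_id=encounter_id,
        name=f"{med.drug.ingredient} {med.strength} {med.form}",
        generic_name=med.drug.ingredient,
        instruction=f"take {med.amount} {med.dosage} {med.route} {med.frequency}",
        route=med.route,
        frequency=med.frequency,
        strength=med.strength,
        form=med.form,
        ordering_date=discharge,
        start_date=discharge,
        end_date=discharge + _dt.timedelta(days=med.duration_days),
    )


def inject_discrepancies(
    encounter: Encounter,
    links: list[GoldLink],
    meds: Sequence[_Medication],
    mix: dict[str, float],
    rate: float,
    rng: np.random.Generator,
) -> tuple[list[GoldLink], int]:
    """Flip ~``rate`` of the encounter's medications into gold discrepancies.

    ``missing_prescription`` deletes the prescription and relabels every
    mention of that medication discrepant; ``attribute_mismatch`` perturbs
    exactly one structured field of the prescription (route, frequency,
    strength or form) and relabels the touched attribute spans.
    """
    kinds = sorted(mix)
    probs = np.array([mix[k] for k in kinds])
    new_links = links
    n_injected = 0
    for med in meds:
        if rng.random() >= rate:
            continue
        n_injected += 1
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        med_links = [l for l in new_links if l.prescription_id == med.prescription_id]
        if kind == ATTRIBUTE_MISMATCH:
            present = [
                cat
                for cat in _PERTURBABLE
                if any(
                    a.category == cat for l in med_links for a in l.mention.attributes
                )
            ]
            if not present:
                kind = MISSING_PRESCRIPTION
        if kind == MISSING_PRESCRIPTION:
            encounter.prescriptions = [
                p for p in encounter.prescriptions if p.prescription_id != med.prescription_id
            ]
            replaced = {
                id(l): GoldLink(
                    l.mention,
                    None,
                    DISCREPANT,
                    {a: DISCREPANT for a in l.mention.attributes},
                )
                for l in med_links
            }
        else:
            cat = present[int(rng.choice(len(present)))]
            pool = {"route": _ROUTES, "frequency": _FREQS, "strength": _STRENGTHS,
                    "form": _FORMS}[cat]
            old = med.attribute_value(cat)
            alternatives = [v for v in pool if v != old]
            new_value = str(alternatives[int(rng.choice(len(alternatives)))])
            for p in encounter.prescriptions:
                if p.prescription_id == med.prescription_id:
                    setattr(p, cat, new_value)
            replaced = {}
            for l in med_links:
                attr_labels = {
                    a: (DISCREPANT if a.category == cat else lab)
                    for a, lab in l.attribute_labels.items()
                }
                replaced[id(l)] = GoldLink(l.mention, l.prescription_id, l.label, attr_labels)
        new_links = [replaced.get(id(l), l) for l in new_links]
    return new_links, n_injected


def generate_corpus(config: Optional[GeneratorConfig] = None) -> Corpus:
    """Generate a full synthetic corpus under the given configuration."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    catalog = generate_drug_catalog(config.lexicon_size, config.seed)
    lexicon = build_lexicon(catalog)

    encounters: list[Encounter] = []
    annotations: dict[str, list[EntitySpan]] = {}
    gold_links: list[GoldLink] = []
    rx_counter = 0
    note_counter = 0
    n_medications = 0
    n_discrepant = 0
    base_date = _dt.date(2012, 1, 1)

    for p in range(config.n_patients):
        patient_id = f"P{p:03d}"
        for e in range(_rand_range(rng, config.encounters_per_patient)):
            encounter_id = f"{patient_id}-E{e}"
            discharge = base_date + _dt.timedelta(days=int(rng.integers(0, 700)))
            n_meds = _rand_range(rng, config.meds_per_encounter)
            drug_idx = rng.choice(len(catalog), size=n_meds, replace=False)
            meds: list[_Medication] = []
            for di in drug_idx:
                rx_counter += 1
                meds.append(_make_medication(catalog[int(di)], f"RX{rx_counter:05d}", rng))
            encounter = Encounter(
                encounter_id,
                patient_id,
                prescriptions=[
                    _make_prescription(m, patient_id, encounter_id, discharge) for m in meds
                ],
            )
            links: list[GoldLink] = []

            def add_note(note_type: str, note_meds: Sequence[_Medication]) -> None:
                nonlocal note_counter
                note_counter += 1
                note_id = f"N{note_counter:05d}"
                b = _NoteBuilder(note_id)
                if note_type == "overview":
                    condition = str(rng.choice(_CONDITIONS))
                    b.add(f"Problem: {condition}. Plan of care reviewed.\n")
                    for m in note_meds:
                        surface, _ = _mention_surface(m, note_type, config, rng)
                        mention = _emit_mention(b, m, surface, config, rng)
                        b.add(
                            " "
                            + str(rng.choice(_DISTRACTORS))
                            + " "
                            + str(rng.choice(_DISTRACTORS))
                            + "\n"
                        )
                        links.append(_matched_link(mention, m))
                else:
                    b.add("Discharge summary.\nHospital course was uneventful.\n")
                    b.add("Discharge medications:\n")
                    for m in note_meds:
                        b.add("- ")
                        surface, _ = _mention_surface(m, note_type, config, rng)
                        mention = _emit_mention(b, m, surface, config, rng)
                        b.add("\n" + _BULLET_FILLER)
                        links.append(_matched_link(mention, m))
                    b.add(str(rng.choice(_DISTRACTORS)) + "\n")
                note = ClinicalNote(note_id, encounter_id, patient_id, note_type, b.text)
                for s in b.spans:
                    s.validate_against(note)
                encounter.notes.append(note)
                annotations[note_id] = b.spans

            for _ in range(_rand_range(rng, config.overview_notes_per_encounter)):
                k = min(_rand_range(rng, config.meds_per_overview), len(meds))
                idx = rng.choice(len(meds), size=k, replace=False)
                add_note("overview", [meds[int(i)] for i in idx])
            add_note("discharge_summary", meds)

            links, injected = inject_discrepancies(
                encounter, links, meds, config.discrepancy_mix, config.discrepancy_rate, rng
            )
            n_medications += len(meds)
            n_discrepant += injected
            encounters.append(encounter)
            gold_links.extend(links)

    return Corpus(
        encounters,
        annotations,
        gold_links,
        lexicon,
        config,
        n_medications=n_medications,
        n_discrepant_medications=n_discrepant,
    )


def _matched_link(mention: MedicationMention, med: _Medication) -> GoldLink:
    return GoldLink(
        mention,
        med.prescription_id,
        MATCHED,
        {a: MATCHED for a in mention.attributes},
    )
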