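"""End-to-end orchestration of the three pipeline processes.

Two evaluation configurations mirror the study protocol: *stage-isolated*
runs feed gold entities into linkage and matching, and *cumulative* runs
propagate predictions (entity detection → linkage → matching).  Both run
under encounter-level ten-fold cross-validation: the tagger and the pair
memory are always built from the nine training folds and applied to the
held-out fold, so no mention is ever scored by a model that saw it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import entity_detection as ner
from .attribute_linkage import MedicationMention, link_attributes
from .corpus_io import (
    Encounter,
    EntitySpan,
    GoldLink,
    read_corpus_dir,
    write_reconciliation_report,
)
from .crf import CRFParams
from .errors import ConfigError
from .evaluation import (
    FoldAssignment,
    PRF,
    matching_prf,
    recall_propagation,
    span_prf,
    stratified_tenfold,
    token_prf,
)
from .lexicon import Lexicon, load_lexicon
from .matching import MatchConfig, PairMemory, ReconciliationResult, build_pair_memory, reconcile_encounter
from .synthetic import Corpus, read_gold_links

GOLD_ENTITIES = "gold_entities"
PREDICTED_ENTITIES = "predicted_entities"


@dataclass
class RunConfig:
    """File-based pipeline run configuration."""

    corpus_dir: Path
    mode: str = GOLD_ENTITIES
    lexicon_path: Optional[Path] = None
    model_path: Optional[Path] = None
    output_path: Optional[Path] = None
    seed: int = 0
    match_config: MatchConfig = field(default_factory=MatchConfig)

    def validate(self) -> None:
        if self.mode not in (GOLD_ENTITIES, PREDICTED_ENTITIES):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not Path(self.corpus_dir).exists():
            raise ConfigError(f"missing input: corpus_dir {self.corpus_dir}")


@dataclass
class PipelineOutcome:
    """Aggregated cross-validated metrics plus the raw per-mention results."""

    results: list[ReconciliationResult]
    token: dict[str, PRF]
    span: dict[str, PRF]
    matching: dict[str, dict[str, PRF]]
    recall_propagation: dict[str, dict[str, float]]
    folds: FoldAssignment


def _encounter_spans(
    corpus: Corpus,
    encounter: Encounter,
    mode: str,
    model: Optional[ner.TaggerModel],
) -> dict[str, list[EntitySpan]]:
    spans: dict[str, list[EntitySpan]] = {}
    for note in encounter.notes:
        if mode == GOLD_ENTITIES:
            spans[note.note_id] = list(corpus.annotations.get(note.note_id, []))
        else:
            spans[note.note_id] = ner.predict_spans(model, note, corpus.lexicon)
    return spans


def cross_validate(
    corpus: Corpus,
    mode: str = PREDICTED_ENTITIES,
    seed: int = 0,
    n_folds: int = 10,
    match_config: Optional[MatchConfig] = None,
    crf_params: Optional[CRFParams] = None,
) -> PipelineOutcome:
    """Run the full pipeline under encounter-level cross-validation."""
    if mode not in (GOLD_ENTITIES, PREDICTED_ENTITIES):
        raise ConfigError(f"unknown mode {mode!r}")
    match_config = match_config or MatchConfig()
    folds = stratified_tenfold(corpus.encounters, seed, n_folds)
    folds.validate_partition([e.encounter_id for e in corpus.encounters])
    enc_by_id = {e.encounter_id: e for e in corpus.encounters}
    links_by_enc: dict[str, list[GoldLink]] = {}
    note_to_enc = {n.note_id: e.encounter_id for e in corpus.encounters for n in e.notes}
    for link in corpus.gold_links:
        links_by_enc.setdefault(note_to_enc[link.mention.note_id], []).append(link)

    all_results: list[ReconciliationResult] = []
    detected: dict[str, list[EntitySpan]] = {}
    linked: dict[str, list[MedicationMention]] = {}
    gold_bio: list[list[str]] = []
    pred_bio: list[list[str]] = []

    for i, test_ids in enumerate(folds.folds):
        train_ids = folds.training_encounters(i)
        model: Optional[ner.TaggerModel] = None
        if mode == PREDICTED_ENTITIES:
            train_notes = [n for eid in train_ids for n in enc_by_id[eid].notes]
            model = ner.train_tagger(
                train_notes, corpus.annotations, corpus.lexicon, crf_params, seed=seed
            )
        train_links = [l for eid in train_ids for l in links_by_enc.get(eid, [])]
        train_rx = {
            p.prescription_id: p
            for eid in train_ids
            for p in enc_by_id[eid].prescriptions
        }
        memory = build_pair_memory(train_links, train_rx)

        for eid in test_ids:
            enc = enc_by_id[eid]
            spans = _encounter_spans(corpus, enc, mode, model)
            detected.update(spans)
            mentions: list[MedicationMention] = []
            for note in enc.notes:
                tokens = ner.tokenize(note.text)
                gold_bio.append(
                    ner.spans_to_bio(corpus.annotations.get(note.note_id, []), tokens)
                )
                pred_bio.append(ner.spans_to_bio(spans[note.note_id], tokens))
                linkage = link_attributes(spans[note.note_id], note)
                linked[note.note_id] = linkage.mentions
                mentions.extend(linkage.mentions)
            all_results.extend(
                reconcile_encounter(
                    mentions, enc.prescriptions, corpus.lexicon, memory, match_config
                )
            )

    gold_spans = [s for spans in corpus.annotations.values() for s in spans]
    pred_spans = [s for spans in detected.values() for s in spans]
    return PipelineOutcome(
        results=all_results,
        token=token_prf(gold_bio, pred_bio),
        span=span_prf(gold_spans, pred_spans),
        matching=matching_prf(corpus.gold_links, all_results),
        recall_propagation=recall_propagation(
            corpus.gold_links, corpus.note_types, detected, linked, all_results
        ),
        folds=folds,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Single-pass file-based run: read a corpus directory, reconcile, report.

    Returns a summary dict (per-stage counts plus metrics when gold links
    are present in the corpus directory).
    """
    config.validate()
    root = Path(config.corpus_dir)
    encounters, annotations = read_corpus_dir(root)
    lexicon: Optional[Lexicon] = None
    lex_path = config.lexicon_path or (root / "lexicon.tsv")
    if Path(lex_path).exists():
        lexicon = load_lexicon(lex_path, "simple_tsv")
    gold_links: list[GoldLink] = []
    if (root / "gold_links.json").exists():
        gold_links = read_gold_links(root / "gold_links.json")

    model: Optional[ner.TaggerModel] = None
    if config.mode == PREDICTED_ENTITIES:
        if config.model_path is None:
            raise ConfigError("missing input: model_path (predicted_entities mode)")
        model = ner.TaggerModel.load(config.model_path)
    memory = PairMemory()

    per_encounter: dict[str, list[ReconciliationResult]] = {}
    n_spans = n_mentions = 0
    for enc in encounters:
        mentions: list[MedicationMention] = []
        for note in enc.notes:
            spans = (
                annotations.get(note.note_id, [])
                if config.mode == GOLD_ENTITIES
                else ner.predict_spans(model, note, lexicon)
            )
            n_spans += len(spans)
            mentions.extend(link_attributes(spans, note).mentions)
        n_mentions += len(mentions)
        per_encounter[enc.encounter_id] = reconcile_encounter(
            mentions, enc.prescriptions, lexicon, memory, config.match_config
        )
    if config.output_path is not None:
        write_reconciliation_report(per_encounter, config.output_path)

    all_results = [r for res in per_encounter.values() for r in res]
    summary: dict = {
        "encounters": len(encounters),
        "entity_spans": n_spans,
        "mentions": n_mentions,
        "matched": sum(r.final_bucket == "matched" for r in all_results),
        "discrepant": sum(r.final_bucket == "discrepant" for r in all_results),
    }
    if gold_links:
        m = matching_prf(gold_links, all_results)
        summary["matching_metrics"] = {
            side: {cat: (p.precision, p.recall, p.f_value) for cat, p in table.items()}
            for side, table in m.items()
        }
    return summary
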