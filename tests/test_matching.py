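import pytest

from medrec.attribute_linkage import MedicationMention, link_attributes
from medrec.corpus_io import DISCREPANT, MATCHED, EntitySpan, GoldLink, Prescription
from medrec.errors import UsageError
from medrec.lexicon import Lexicon, LexiconEntry, extract_mention_terms
from medrec.matching import (
    STEP_COOCCURRENCE,
    STEP_NONE,
    STEP_PAIR_MEMORY,
    STEP_SUBSTRING,
    MatchConfig,
    PairMemory,
    build_pair_memory,
    match_attributes,
    match_medication,
    normalize_attribute,
    reconcile_encounter,
)
from medrec.pipeline import cross_validate
from medrec.evaluation import stratified_tenfold


def rx(name, rx_id="r1", generic=None, **kw):
    return Prescription(rx_id, "p1", "e1", name, generic_name=generic, **kw)


def mention(text, start=0, note_id="n1", attrs=()):
    name = EntitySpan(note_id, start, start + len(text), "medication_name", text)
    return MedicationMention(name, tuple(attrs))


@pytest.fixture(scope="module")
def synonym_lexicon():
    return Lexicon(
        entries=[
            LexiconEntry("3322", "diazepam", "ingredient"),
            LexiconEntry("2052646", "diazepam rectal gel [diastat]", "brand"),
        ],
        trade_relations=[("2052646", "3322")],
    )


class TestCascade:
    def test_substring_step_fires_first(self):
        d = match_medication("albuterol", [rx("albuterol 2.5 mg/0.5 ml nebulizer solution")])
        assert (d.label, d.step, d.prescription_id) == (MATCHED, STEP_SUBSTRING, "r1")

    def test_substring_works_in_either_direction(self):
        d = match_medication("albuterol 2.5 mg solution", [rx("albuterol")])
        assert d.step == STEP_SUBSTRING

    def test_generic_name_also_compared(self):
        d = match_medication("salbutamol", [rx("brandair inhaler", generic="salbutamol")])
        assert d.step == STEP_SUBSTRING

    def test_pair_memory_step(self):
        memory = PairMemory()
        memory.add(frozenset({"abx"}), frozenset({"amoxicillin", "clavulanate"}))
        d = match_medication("abx", [rx("amoxicillin clavulanate oral tablet")], memory=memory)
        assert (d.label, d.step) == (MATCHED, STEP_PAIR_MEMORY)

    def test_description_cooccurrence_step(self, synonym_lexicon):
        d = match_medication("diastat", [rx("diazepam rectal gel")], lexicon=synonym_lexicon)
        assert (d.label, d.step) == (MATCHED, STEP_COOCCURRENCE)

    def test_no_match_is_discrepant_not_error(self, synonym_lexicon):
        d = match_medication("foobarol", [rx("albuterol")], lexicon=synonym_lexicon,
                             memory=PairMemory())
        assert (d.label, d.step, d.prescription_id) == (DISCREPANT, STEP_NONE, None)

    def test_empty_prescription_list_is_discrepant(self):
        assert match_medication("albuterol", []).label == DISCREPANT

    def test_similar_name_containment_misfire_is_reproduced(self):
        # bag-of-words substring matching cannot separate these two names
        d = match_medication("prednisolone", [rx("methylprednisolone 4 mg tab")])
        assert (d.label, d.step) == (MATCHED, STEP_SUBSTRING)

    def test_best_candidate_prefers_longest_common_substring(self):
        rxs = [rx("prednisolone", "r1"), rx("prednisolone acetate 1% suspension", "r2")]
        d = match_medication("prednisolone acetate", rxs)
        assert d.prescription_id == "r2"

    def test_equal_candidates_keep_prescription_list_order(self):
        rxs = [rx("methylprednisolone 4 mg tab", "r1"), rx("prednisolone 5 mg tab", "r2")]
        d = match_medication("prednisolone", rxs)
        assert d.prescription_id == "r1"


class TestPairMemory:
    def test_empty_training_set(self):
        assert len(build_pair_memory([], {})) == 0

    def test_gold_link_pair_is_remembered(self):
        m = mention("abx")
        link = GoldLink(m, "r9", MATCHED, {})
        rx9 = Prescription("r9", "p1", "e1", "amoxicillin clavulanate")
        memory = build_pair_memory([link], {"r9": rx9})
        assert memory.query(
            extract_mention_terms("abx"), extract_mention_terms("amoxicillin clavulanate")
        )

    def test_query_is_symmetric(self):
        memory = PairMemory()
        a, b = frozenset({"abx"}), frozenset({"amoxicillin", "clavulanate"})
        memory.add(a, b)
        assert memory.query(a, b) and memory.query(b, a)

    def test_fold_partition_leakage_audit(self, small_corpus):
        """A memory built on one fold never contains pairs unique to another."""
        folds = stratified_tenfold(small_corpus.encounters, seed=0, n_folds=2)
        note_to_enc = {
            n.note_id: e.encounter_id for e in small_corpus.encounters for n in e.notes
        }
        rx_all = {
            p.prescription_id: p for e in small_corpus.encounters for p in e.prescriptions
        }
        link_folds = []
        for fold in folds.folds:
            fold_set = set(fold)
            link_folds.append(
                [l for l in small_corpus.gold_links
                 if note_to_enc[l.mention.note_id] in fold_set]
            )
        mem0 = build_pair_memory(link_folds[0], rx_all)
        mem1 = build_pair_memory(link_folds[1], rx_all)
        unique_to_1 = mem1.pairs - mem0.pairs
        assert not (mem0.pairs & unique_to_1)


class TestAttributeComparison:
    def test_identical_route_matches(self):
        attr = EntitySpan("n1", 20, 24, "route", "oral")
        m = mention("albuterol", attrs=[attr])
        labels = match_attributes(m, rx("albuterol", route="oral"))
        assert labels[attr] == MATCHED

    def test_semantic_equivalence_is_not_resolved(self):
        attr = EntitySpan("n1", 20, 22, "frequency", "AM")
        m = mention("sucralfate", attrs=[attr])
        labels = match_attributes(m, rx("sucralfate", frequency="twice a day"))
        assert labels[attr] == DISCREPANT

    def test_unit_whitespace_normalization(self):
        attr = EntitySpan("n1", 20, 23, "strength", "5mg")
        m = mention("baclofen", attrs=[attr])
        labels = match_attributes(m, rx("baclofen", strength="5 mg"))
        assert labels[attr] == MATCHED

    def test_decimal_strengths_are_not_confused(self):
        attr = EntitySpan("n1", 20, 24, "strength", "5 mg")
        m = mention("baclofen", attrs=[attr])
        labels = match_attributes(m, rx("baclofen", strength="2.5 mg"))
        assert labels[attr] == DISCREPANT

    def test_amount_compared_against_instruction(self):
        attr = EntitySpan("n1", 20, 25, "amount", "1 tab")
        m = mention("baclofen", attrs=[attr])
        labels = match_attributes(m, rx("baclofen", instruction="take 1 tab po bid"))
        assert labels[attr] == MATCHED

    def test_blank_field_is_discrepant(self):
        attr = EntitySpan("n1", 20, 24, "route", "oral")
        m = mention("baclofen", attrs=[attr])
        labels = match_attributes(m, rx("baclofen"))
        assert labels[attr] == DISCREPANT

    def test_normalize_attribute_examples(self):
        assert normalize_attribute("5mg") == "5 mg"
        assert normalize_attribute("Milligrams") == "mg"
        assert normalize_attribute("2.5 ml") == "2.5 ml"


class TestReconcileEncounter:
    def test_missing_medication_lands_in_discrepant_bucket(self):
        results = reconcile_encounter([mention("orphanol")], [rx("albuterol")])
        assert results[0].final_bucket == DISCREPANT

    def test_fully_matched_medication(self):
        attr = EntitySpan("n1", 10, 14, "route", "oral")
        results = reconcile_encounter(
            [mention("albuterol", attrs=[attr])], [rx("albuterol 2 mg", route="oral")]
        )
        assert results[0].final_bucket == MATCHED

    def test_attribute_discrepancy_flips_the_bucket(self):
        attr = EntitySpan("n1", 10, 12, "route", "po")
        results = reconcile_encounter(
            [mention("albuterol", attrs=[attr])], [rx("albuterol 2 mg", route="pr")]
        )
        assert results[0].decision.label == MATCHED
        assert results[0].final_bucket == DISCREPANT

    def test_mixed_encounters_rejected(self):
        other = Prescription("r2", "p1", "e2", "albuterol")
        with pytest.raises(UsageError):
            reconcile_encounter([mention("albuterol")], [rx("albuterol"), other])

    def test_route_must_match_flag_voids_the_match(self):
        attr = EntitySpan("n1", 10, 12, "route", "po")
        results = reconcile_encounter(
            [mention("albuterol", attrs=[attr])],
            [rx("albuterol 2 mg", route="pr")],
            config=MatchConfig(route_must_match=True),
        )
        assert results[0].decision.label == DISCREPANT

    def test_directionality_no_list_to_note_results(self, clean_corpus):
        """Prescriptions without a note-side mention never produce a result."""
        enc = clean_corpus.encounters[0]
        mentions = []
        for note in enc.notes:
            mentions.extend(
                link_attributes(clean_corpus.annotations[note.note_id], note).mentions
            )
        results = reconcile_encounter(mentions, enc.prescriptions, clean_corpus.lexicon)
        assert len(results) == len(mentions)
        assert {r.mention.key for r in results} == {m.key for m in mentions}


def test_cascade_monotonicity_disabling_steps(small_corpus):
    """Turning off steps 2-4 can only shrink (or keep) the matched count."""
    full = cross_validate(small_corpus, mode="gold_entities", seed=0, n_folds=3)
    reduced = cross_validate(
        small_corpus,
        mode="gold_entities",
        seed=0,
        n_folds=3,
        match_config=MatchConfig(enabled_steps=frozenset({STEP_SUBSTRING})),
    )
    n_full = sum(r.decision.label == MATCHED for r in full.results)
    n_reduced = sum(r.decision.label == MATCHED for r in reduced.results)
    assert n_reduced <= n_full
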