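import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from medrec.attribute_linkage import MedicationMention
from medrec.corpus_io import DISCREPANT, MATCHED, EntitySpan, GoldLink
from medrec.errors import UsageError
from medrec.evaluation import (
    PRF,
    CorpusCounts,
    corpus_stats,
    fvalue,
    iaa_f,
    matching_prf,
    span_prf,
    stratified_tenfold,
    token_prf,
)
from medrec.matching import MatchDecision, ReconciliationResult
from medrec.synthetic import GeneratorConfig, generate_corpus


class TestFValue:
    def test_symmetric_input_is_identity(self):
        for x in (0.0, 0.25, 0.9, 1.0):
            assert fvalue(x, x) == pytest.approx(x)

    def test_zero_precision_gives_zero(self):
        assert fvalue(0.0, 0.9) == 0.0

    def test_percent_scale_rejected(self):
        with pytest.raises(UsageError):
            fvalue(95.0, 91.6)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_f_between_p_and_r(self, tp, fp, fn):
        prf = PRF(tp, fp, fn)
        assert min(prf.precision, prf.recall) - 1e-12 <= prf.f_value
        assert prf.f_value <= max(prf.precision, prf.recall) + 1e-12


class TestZeroDenominatorConvention:
    def test_nothing_predicted_nothing_expected(self):
        prf = PRF(0, 0, 0)
        assert prf.precision == 1.0 and prf.recall == 1.0


def seq(*labels):
    return list(labels)


class TestTokenPrf:
    def test_perfect_predictions(self):
        gold = [seq("B-route", "O", "B-strength", "I-strength")]
        table = token_prf(gold, gold)
        for cat in ("route", "strength", "overall"):
            assert table[cat].f_value == 1.0

    def test_all_outside_predictions_have_zero_recall(self):
        gold = [seq("B-route", "O")]
        table = token_prf(gold, [seq("O", "O")])
        assert table["overall"].recall == 0.0

    def test_hand_counted_case(self):
        # 10 tokens: 3 tp, 2 fp, 1 fn on a single category
        gold = [seq("B-route", "I-route", "I-route", "B-route", "O", "O", "O", "O", "O", "O")]
        pred = [seq("B-route", "I-route", "I-route", "O", "B-route", "I-route", "O", "O", "O", "O")]
        prf = token_prf(gold, pred)["route"]
        assert (prf.tp, prf.fp, prf.fn) == (3, 2, 1)
        assert prf.precision == pytest.approx(0.6)
        assert prf.recall == pytest.approx(0.75)

    def test_length_mismatch_rejected(self):
        with pytest.raises(UsageError):
            token_prf([seq("O")], [seq("O", "O")])


def span(start, end, category="medication_name", note_id="n1", text=None):
    return EntitySpan(note_id, start, end, category, text or "x" * (end - start))


class TestSpanPrf:
    def test_identical_sets(self):
        spans = [span(0, 5), span(10, 14, "route")]
        table = span_prf(spans, spans)
        assert table["overall"].f_value == 1.0

    def test_off_by_one_counts_fp_and_fn(self):
        table = span_prf([span(0, 5)], [span(0, 6)])
        prf = table["medication_name"]
        assert (prf.tp, prf.fp, prf.fn) == (0, 1, 1)

    def test_duplicate_predictions_credit_gold_once(self):
        table = span_prf([span(0, 5)], [span(0, 5), span(0, 5)])
        prf = table["medication_name"]
        assert (prf.tp, prf.fp, prf.fn) == (1, 1, 0)


class TestIaa:
    def test_self_agreement_is_one(self):
        spans = [span(0, 5), span(8, 12, "route")]
        assert iaa_f(spans, spans).f_value == 1.0

    def test_empty_second_annotator_is_zero(self):
        assert iaa_f([span(0, 5)], []).f_value == 0.0

    def test_symmetric_under_swap(self):
        a = [span(0, 5), span(8, 12, "route")]
        b = [span(0, 5), span(20, 24, "form")]
        assert iaa_f(a, b).f_value == pytest.approx(iaa_f(b, a).f_value)


def _gold(mention_, rx_id, label=MATCHED):
    return GoldLink(mention_, rx_id, label, {})


def _sys(mention_, rx_id, label=MATCHED):
    step = "1_substring" if label == MATCHED else "none"
    return ReconciliationResult(mention_, MatchDecision(label, step, rx_id), {})


def _m(i):
    return MedicationMention(span(i * 10, i * 10 + 5))


class TestMatchingPrf:
    def test_wrong_prescription_is_not_a_matched_tp(self):
        m = _m(0)
        table = matching_prf([_gold(m, "r1")], [_sys(m, "r2")])
        prf = table[MATCHED]["medication_name"]
        assert (prf.tp, prf.fp, prf.fn) == (0, 1, 1)

    def test_perfect_system(self):
        golds, syss = [], []
        for i in range(4):
            m = _m(i)
            label = MATCHED if i % 2 else DISCREPANT
            golds.append(_gold(m, "r%d" % i if label == MATCHED else None, label))
            syss.append(_sys(m, "r%d" % i if label == MATCHED else None, label))
        table = matching_prf(golds, syss)
        assert table[MATCHED]["overall"].f_value == 1.0
        assert table[DISCREPANT]["overall"].f_value == 1.0

    def test_all_discrepant_system_on_half_matched_gold(self):
        golds, syss = [], []
        for i in range(10):
            m = _m(i)
            label = MATCHED if i < 5 else DISCREPANT
            golds.append(_gold(m, f"r{i}" if label == MATCHED else None, label))
            syss.append(_sys(m, None, DISCREPANT))
        prf = matching_prf(golds, syss)[DISCREPANT]["medication_name"]
        assert prf.recall == 1.0
        assert prf.precision == pytest.approx(0.5)


class TestStratifiedTenfold:
    def test_uniform_encounters_one_per_fold(self):
        corpus = generate_corpus(
            GeneratorConfig(n_patients=10, encounters_per_patient=(1, 1), seed=0)
        )
        folds = stratified_tenfold(corpus.encounters, seed=1)
        assert sorted(len(f) for f in folds.folds) == [1] * 10

    def test_deterministic_for_fixed_seed(self, small_corpus):
        f1 = stratified_tenfold(small_corpus.encounters, seed=9)
        f2 = stratified_tenfold(small_corpus.encounters, seed=9)
        assert f1.folds == f2.folds

    def test_partition_and_stratification_audit(self):
        corpus = generate_corpus(
            GeneratorConfig(n_patients=40, encounters_per_patient=(1, 4), seed=2)
        )
        folds = stratified_tenfold(corpus.encounters, seed=3)
        folds.validate_partition([e.encounter_id for e in corpus.encounters])
        notes_per_patient = {}
        for e in corpus.encounters:
            notes_per_patient[e.patient_id] = notes_per_patient.get(e.patient_id, 0) + len(e.notes)
        per_enc = {e.encounter_id: notes_per_patient[e.patient_id] for e in corpus.encounters}
        global_mean = np.mean(list(per_enc.values()))
        for fold in folds.folds:
            fold_mean = np.mean([per_enc[eid] for eid in fold])
            assert global_mean / 2 <= fold_mean <= global_mean * 2

    def test_too_few_encounters_rejected(self, small_corpus):
        with pytest.raises(UsageError):
            stratified_tenfold(small_corpus.encounters[:5], seed=0)


class TestCorpusStats:
    def test_discrepant_fraction_direct_count(self):
        counts = CorpusCounts(entities_total=100, entities_discrepant=8)
        assert counts.derived()["discrepant_fraction_pct"] == pytest.approx(8.0)

    def test_empty_corpus_is_all_zero(self):
        counts = corpus_stats([], {})
        assert counts.entities_total == 0
        assert counts.patients == 0

    def test_generated_corpus_counts_are_consistent(self, small_corpus):
        counts = corpus_stats(
            small_corpus.encounters, small_corpus.annotations, small_corpus.gold_links
        )
        assert counts.entities_total == sum(
            len(v) for v in small_corpus.annotations.values()
        )
        assert counts.encounters == len(small_corpus.encounters)
        assert counts.entities_overview + counts.entities_discharge_summaries == (
            counts.entities_total
        )
        assert counts.patients_with_discrepancy <= counts.patients
        assert counts.encounters_with_discrepancy <= counts.encounters
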