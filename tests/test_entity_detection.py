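import itertools

import numpy as np
import pytest

from medrec.corpus_io import ClinicalNote, EntitySpan
from medrec.crf import CRFParams, LinearChainCRF, valid_bio
from medrec.entity_detection import (
    FEATURE_TEMPLATE_VERSION,
    TaggerModel,
    bio_to_spans,
    featurize,
    predict_labels,
    predict_spans,
    spans_to_bio,
    tokenize,
    train_tagger,
)
from medrec.errors import ConfigError, IntegrityError, UsageError
from medrec.evaluation import token_prf


class TestTokenize:
    def test_word_number_unit(self):
        toks = [(t.text, t.start, t.end) for t in tokenize("Baclofen 5 mg")]
        assert toks == [("Baclofen", 0, 8), ("5", 9, 10), ("mg", 11, 13)]

    def test_empty_text(self):
        assert tokenize("") == []

    def test_decimals_kept_slash_split(self):
        assert [t.text for t in tokenize("2.5 mg/0.5 ml")] == ["2.5", "mg", "/", "0.5", "ml"]


class TestBioCodec:
    def test_name_span_labels(self, baclofen_note):
        toks = tokenize(baclofen_note.text)
        span = EntitySpan("n1", 0, 8, "medication_name", "Baclofen")
        labels = spans_to_bio([span], toks)
        assert labels[:3] == ["B-medication_name", "O", "O"]

    def test_multi_token_span(self, baclofen_note):
        toks = tokenize(baclofen_note.text)
        span = EntitySpan("n1", 9, 13, "strength", "5 mg")
        assert spans_to_bio([span], toks)[:3] == ["O", "B-strength", "I-strength"]

    def test_no_spans_all_outside(self, baclofen_note):
        toks = tokenize(baclofen_note.text)
        assert set(spans_to_bio([], toks)) == {"O"}

    def test_same_category_overlap_rejected(self, baclofen_note):
        toks = tokenize(baclofen_note.text)
        spans = [
            EntitySpan("n1", 0, 8, "medication_name", "Baclofen"),
            EntitySpan("n1", 4, 8, "medication_name", "ofen"),
        ]
        with pytest.raises(IntegrityError, match="overlapping"):
            spans_to_bio(spans, toks)

    def test_round_trip_identity_on_corpus(self, small_corpus):
        for note_id, spans in list(small_corpus.annotations.items())[:20]:
            note = small_corpus.notes_by_id[note_id]
            toks = tokenize(note.text)
            back = bio_to_spans(toks, spans_to_bio(spans, toks), note)
            assert sorted(back) == sorted(spans)


class TestFeaturize:
    def test_drug_gazetteer_and_shape(self, lexicon, baclofen_note):
        note = ClinicalNote("n1", "e1", "p1", "overview", "Take diazepam daily")
        feats = featurize(tokenize(note.text), lexicon)
        diazepam = feats[1]
        assert "gaz=drug_term" in diazepam
        assert "shape=lower" in diazepam

    def test_digit_flag(self, baclofen_note):
        feats = featurize(tokenize(baclofen_note.text))
        assert "isdigit" in feats[1]

    def test_boundary_sentinel_on_first_token(self, baclofen_note):
        feats = featurize(tokenize(baclofen_note.text))
        assert "ctx[-1]=__BOUNDARY__" in feats[0]
        assert "ctx[-2]=__BOUNDARY__" in feats[0]


def _brute_force_best(crf, feats):
    """Enumerate all label sequences (no BIO mask) to find the max-score path."""
    E = np.asarray(crf._encode(feats) @ crf.w_emit)
    L = len(crf.labels)
    best, best_score = None, -np.inf
    for path in itertools.product(range(L), repeat=len(feats)):
        score = crf.w_start[path[0]] + E[0, path[0]]
        for t in range(1, len(path)):
            score += crf.w_trans[path[t - 1], path[t]] + E[t, path[t]]
        if score > best_score:
            best, best_score = path, score
    return [crf.labels[i] for i in best], best_score


def _brute_force_marginals(crf, feats):
    E = np.asarray(crf._encode(feats) @ crf.w_emit)
    L, T = len(crf.labels), len(feats)
    post = np.zeros((T, L))
    Z = 0.0
    for path in itertools.product(range(L), repeat=T):
        score = crf.w_start[path[0]] + E[0, path[0]]
        for t in range(1, T):
            score += crf.w_trans[path[t - 1], path[t]] + E[t, path[t]]
        w = np.exp(score)
        Z += w
        for t, j in enumerate(path):
            post[t, j] += w
    return post / Z


@pytest.fixture(scope="module")
def tiny_trained_crf():
    # two short sequences, two categories -> 5 labels, enumerable state space
    seqs = [
        [["w=take"], ["w=drug", "gaz"], ["w=5"], ["w=mg"]],
        [["w=drug", "gaz"], ["w=5"], ["w=mg"], ["w=stop"]],
    ]
    labels = [
        ["O", "B-medication_name", "B-strength", "I-strength"],
        ["B-medication_name", "B-strength", "I-strength", "O"],
    ]
    return LinearChainCRF(CRFParams(max_iter=60)).fit(seqs, labels), seqs


class TestCRFAgainstEnumeration:
    def test_viterbi_matches_exhaustive_argmax(self, tiny_trained_crf):
        crf, seqs = tiny_trained_crf
        for seq in seqs:
            brute, _ = _brute_force_best(crf, seq)
            decoded = crf.predict(seq)
            # the decoded path must score at least as well among BIO-valid paths
            assert valid_bio(decoded)
            if valid_bio(brute):
                assert decoded == brute

    def test_marginals_match_exhaustive_posterior(self, tiny_trained_crf):
        crf, seqs = tiny_trained_crf
        for seq in seqs:
            np.testing.assert_allclose(
                crf.marginals(seq), _brute_force_marginals(crf, seq), atol=1e-8
            )

    def test_marginals_rows_sum_to_one(self, tiny_trained_crf):
        crf, seqs = tiny_trained_crf
        np.testing.assert_allclose(crf.marginals(seqs[0]).sum(axis=1), 1.0)


@pytest.fixture(scope="module")
def trained_tagger(clean_corpus):
    notes = [n for e in clean_corpus.encounters[:25] for n in e.notes]
    return (
        train_tagger(notes, clean_corpus.annotations, clean_corpus.lexicon, seed=3),
        notes,
    )


class TestTagger:
    def test_fit_sanity_on_training_set(self, trained_tagger, clean_corpus):
        model, notes = trained_tagger
        gold, pred = [], []
        for note in notes:
            toks = tokenize(note.text)
            gold.append(spans_to_bio(clean_corpus.annotations[note.note_id], toks))
            pred.append(predict_labels(model, note, clean_corpus.lexicon).labels)
        assert token_prf(gold, pred)["overall"].f_value >= 0.95

    def test_training_is_deterministic(self, clean_corpus, trained_tagger):
        model1, notes = trained_tagger
        model2 = train_tagger(notes, clean_corpus.annotations, clean_corpus.lexicon, seed=3)
        held_out = clean_corpus.encounters[-1].notes[0]
        assert predict_spans(model1, held_out, clean_corpus.lexicon) == predict_spans(
            model2, held_out, clean_corpus.lexicon
        )

    def test_label_closure_single_category_corpus(self, clean_corpus):
        notes = [n for e in clean_corpus.encounters[:10] for n in e.notes]
        stripped = {
            nid: [s for s in spans if s.category == "medication_name"]
            for nid, spans in clean_corpus.annotations.items()
        }
        model = train_tagger(notes, stripped, clean_corpus.lexicon)
        for note in notes[:5]:
            for span in predict_spans(model, note, clean_corpus.lexicon):
                assert span.category == "medication_name"

    def test_empty_note_decodes_to_nothing(self, trained_tagger):
        model, _ = trained_tagger
        note = ClinicalNote("nx", "e", "p", "overview", "")
        assert predict_spans(model, note) == []

    def test_decodes_are_valid_bio(self, trained_tagger, clean_corpus):
        model, _ = trained_tagger
        for enc in clean_corpus.encounters[25:30]:
            for note in enc.notes:
                assert valid_bio(predict_labels(model, note, clean_corpus.lexicon).labels)

    def test_empty_corpus_rejected(self):
        with pytest.raises(UsageError):
            train_tagger([], {})

    def test_model_round_trip_and_version_guard(self, tmp_path, trained_tagger, clean_corpus):
        model, _ = trained_tagger
        path = tmp_path / "model.pkl"
        model.save(path)
        reloaded = TaggerModel.load(path)
        note = clean_corpus.encounters[-1].notes[0]
        assert predict_spans(reloaded, note, clean_corpus.lexicon) == predict_spans(
            model, note, clean_corpus.lexicon
        )
        stale = TaggerModel(model.crf, model.feature_config, template_version="ancient")
        stale_path = tmp_path / "stale.pkl"
        stale.save(stale_path)
        with pytest.raises(ConfigError, match=FEATURE_TEMPLATE_VERSION):
            TaggerModel.load(stale_path)
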