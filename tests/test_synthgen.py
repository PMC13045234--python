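import numpy as np
import pytest

from throatsense import synthgen
from throatsense.features import prosodic_descriptors
from throatsense.synthgen import (
    EMOTIONS,
    EmotionProfile,
    SubjectModel,
    generate_corpus,
    make_emotion_profile,
    make_sentence_template,
    make_subject_model,
    sentence_templates,
    synthesize_recording,
)
from throatsense.telemetry import ADC_MIDPOINT, adc_to_normalized


class TestProfiles:
    def test_angry_printed_values(self):
        p = make_emotion_profile("Angry")
        assert p.speech_rate == 180.0
        assert p.pause_rate == 2.8
        assert p.amp_norm == 0.25
        assert p.energy_mean == 0.25
        assert p.energy_sd == 0.12
        assert p.peak_to_peak == 1.55

    def test_sad_printed_values(self):
        p = make_emotion_profile("Sad")
        assert p.speech_rate == 100.0
        assert p.pause_rate == 6.5
        assert p.amp_norm == 0.08

    def test_neutral_double_of_sad(self):
        sad, neutral = make_emotion_profile("Sad"), make_emotion_profile("Neutral")
        assert neutral.amp_norm == pytest.approx(2 * sad.amp_norm)
        assert neutral.energy_mean == pytest.approx(2 * sad.energy_mean)
        assert sad.pause_rate > neutral.pause_rate  # sadness pauses more often

    def test_unknown_emotion_rejected(self):
        with pytest.raises(ValueError, match="Bored"):
            make_emotion_profile("Bored")

    @pytest.mark.parametrize("emotion", EMOTIONS)
    def test_profile_invariants(self, emotion):
        p = make_emotion_profile(emotion)
        assert p.speech_rate > 0
        assert p.pause_rate >= 0
        assert 0 < p.amp_norm <= 1
        w = np.asarray(p.band_weights)
        assert np.all(w >= 0) and np.isclose(w.sum(), 1.0)
        assert 80 <= p.f0_range[0] <= p.f0_range[1] <= 400

    def test_profiles_pairwise_distinct(self):
        vectors = [
            (p.speech_rate, p.pause_rate, p.amp_norm, *p.f0_range, *p.band_weights)
            for p in map(make_emotion_profile, EMOTIONS)
        ]
        assert len(set(vectors)) == len(EMOTIONS)

    def test_invalid_profile_fields(self):
        base = make_emotion_profile("Angry").__dict__.copy()
        for bad in (
            dict(speech_rate=0.0), dict(pause_rate=-1.0), dict(amp_norm=1.5),
            dict(f0_range=(50.0, 100.0)), dict(band_weights=(0.5, 0.5, 0.5)),
        ):
            with pytest.raises(ValueError):
                EmotionProfile(**{**base, **bad})


class TestSentencesAndSubjects:
    def test_exactly_five_templates(self):
        templates = sentence_templates()
        assert len(templates) == 5
        assert {t.sentence_id for t in templates} == set(range(5))

    def test_syllable_counts(self):
        for t in sentence_templates():
            assert t.syllable_count >= 2
            assert len(t.syllable_durations) == t.syllable_count

    def test_bad_sentence_id(self):
        with pytest.raises(ValueError):
            make_sentence_template(7)

    def test_subjects_distinguishable(self):
        models = [make_subject_model(i) for i in range(4)]
        vectors = {(m.f0_scale, m.amplitude_scale, m.timing_jitter, m.noise_floor)
                   for m in models}
        assert len(vectors) == 4

    def test_subject_validation(self):
        with pytest.raises(ValueError):
            SubjectModel(subject_id=0, f0_scale=0.0)


class TestSynthesize:
    def test_determinism_bit_identical(self):
        p = make_emotion_profile("Happy")
        s = make_sentence_template(0)
        sub = make_subject_model(1)
        a = synthesize_recording(p, s, sub, seed=99)
        b = synthesize_recording(p, s, sub, seed=99)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self):
        p = make_emotion_profile("Happy")
        s = make_sentence_template(0)
        sub = make_subject_model(1)
        a = synthesize_recording(p, s, sub, seed=1)
        b = synthesize_recording(p, s, sub, seed=2)
        assert not np.array_equal(a.samples, b.samples)

    def test_zero_amplitude_midpoint_plus_noise(self):
        p = make_emotion_profile("Neutral")
        p = EmotionProfile(**{**p.__dict__, "amp_norm": 0.0})
        sub = make_subject_model(0)
        rec = synthesize_recording(p, make_sentence_template(0), sub, seed=3)
        x = adc_to_normalized(rec.samples)
        assert np.abs(x).max() < 10 * sub.noise_floor
        assert abs(float(np.mean(rec.samples)) - ADC_MIDPOINT) < 10

    def test_samples_in_12bit_range_and_duration(self):
        rec = synthesize_recording(
            make_emotion_profile("Surprise"), make_sentence_template(4),
            make_subject_model(2), seed=8,
        )
        assert rec.samples.min() >= 0 and rec.samples.max() <= 4095
        assert 1.0 <= rec.duration <= 10.0

    def test_infeasible_profile_rejected(self):
        p = make_emotion_profile("Angry")
        p = EmotionProfile(**{**p.__dict__, "speech_rate": 2000.0})
        with pytest.raises(ValueError, match="infeasible"):
            synthesize_recording(p, make_sentence_template(0), make_subject_model(0), seed=1)

    def test_negative_seed_rejected(self):
        with pytest.raises(ValueError):
            synthesize_recording(
                make_emotion_profile("Sad"), make_sentence_template(0),
                make_subject_model(0), seed=-1,
            )


class TestCorpus:
    def test_minimal_corpus_counts(self):
        recs, manifest = generate_corpus(1, 1, master_seed=0)
        assert len(recs) == 30
        assert len(manifest) == 30

    def test_three_subject_corpus_900(self):
        # counting only; no waveforms needed beyond the generator itself
        _, manifest = generate_corpus(3, 10, master_seed=1)
        assert len(manifest) == 900

    def test_balance_every_cell(self, mini_corpus):
        _, manifest = mini_corpus
        counts = manifest.groupby(["subject_id", "emotion", "sentence_id"]).size()
        assert (counts == 2).all()
        assert len(counts) == 2 * 6 * 5

    def test_determinism_byte_identical(self):
        r1, m1 = generate_corpus(1, 2, master_seed=5)
        r2, m2 = generate_corpus(1, 2, master_seed=5)
        assert m1.equals(m2)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            generate_corpus(0, 1, 0)
        with pytest.raises(ValueError):
            generate_corpus(1, 0, 0)

    def test_energy_ordering_angry_neutral_sad(self, mini_corpus):
        recs, _ = mini_corpus
        means = {}
        for emotion in ("Angry", "Neutral", "Sad"):
            vals = [
                prosodic_descriptors(r, with_delta_mfcc=False).energy_mean
                for r in recs
                if r.emotion == emotion
            ]
            means[emotion] = np.mean(vals)
        assert means["Angry"] > means["Neutral"] > means["Sad"]


def test_speed_rate_recovery_with_corpus_stratification(mini_corpus):
    recs, _ = mini_corpus
    for emotion, target in (("Angry", 180.0), ("Sad", 100.0)):
        rates = [
            prosodic_descriptors(r, with_delta_mfcc=False).speech_rate
            for r in recs
            if r.emotion == emotion
        ]
        assert np.mean(rates) == pytest.approx(target, rel=0.10)
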