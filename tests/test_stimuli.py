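"""Stimulus synthesis: tone pools, grammar classification, tracks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.io import wavfile

from agdep import stimuli
from agdep.stimuli import (
    FAMILIARIZATION_COUNTS,
    REFAMILIARIZATION_COUNTS,
    ToneSpec,
    TokenString,
    assemble_sequence,
    classify_tokens,
    compose_familiarization_track,
    generate_test_session,
    sample_tone_inventory,
    synthesize_tone,
    transition_counts,
    write_track,
)


class TestToneInventory:
    def test_counts_and_bounds(self, inventory):
        assert len(inventory.tones_L) == 44 and len(inventory.tones_H) == 44
        for t in inventory.tones_L:
            assert 1800 <= t.frequency_hz <= 2200
            assert 210 <= t.duration_ms <= 240
        for t in inventory.tones_H:
            assert 9900 <= t.frequency_hz <= 12100

    def test_deterministic_given_seed(self):
        assert sample_tone_inventory(7) == sample_tone_inventory(7)
        assert sample_tone_inventory(7) != sample_tone_inventory(8)

    def test_tonespec_validation(self):
        with pytest.raises(ValueError):
            ToneSpec("L", 2500.0, 225.0)
        with pytest.raises(ValueError):
            ToneSpec("H", 11000.0, 300.0)

    def test_mean_pairwise_difference_matches_closed_form(self):
        # E|X - Y| = W/3 for i.i.d. uniforms on a width-W interval
        est = stimuli.mean_pairwise_frequency_difference("L", 200_000, seed=123)
        assert est == pytest.approx(400.0 / 3.0, abs=2.0)


class TestSynthesizeTone:
    def test_length_and_spectral_peak(self):
        tone = ToneSpec("L", 2000.0, 225.0)
        wave = synthesize_tone(tone, 44100.0)
        assert len(wave) == 9922  # round(0.225 * 44100)
        spectrum = np.abs(np.fft.rfft(wave))
        peak_hz = np.fft.rfftfreq(len(wave), 1 / 44100.0)[np.argmax(spectrum)]
        assert abs(peak_hz - 2000.0) <= 44100.0 / len(wave)  # within one bin

    def test_zero_amplitude_is_silent(self):
        wave = synthesize_tone(ToneSpec("L", 2000.0, 225.0), amplitude=0.0)
        assert not wave.any()

    def test_zero_ramp_is_pure_sine(self):
        tone = ToneSpec("L", 2100.0, 220.0)
        wave = synthesize_tone(tone, 44100.0, amplitude=0.8, ramp_ms=0.0)
        t = np.arange(len(wave)) / 44100.0
        np.testing.assert_allclose(wave, 0.8 * np.sin(2 * np.pi * 2100.0 * t))
        assert wave[0] == 0.0

    def test_rejects_sub_nyquist_rate(self):
        with pytest.raises(ValueError, match="sample rate"):
            synthesize_tone(ToneSpec("H", 11000.0, 225.0), sample_rate=22050.0)


class TestAssembleSequence:
    def test_onsets_every_250_ms(self, inventory):
        seq = assemble_sequence(TokenString.classify("LHL", "Test1"), inventory, 3)
        assert seq.onsets_ms == (0.0, 250.0, 500.0)
        seq6 = assemble_sequence(TokenString.classify("LHHHHL", "Test1"), inventory, 3)
        assert len(seq6.tones) == 6 and seq6.onsets_ms[-1] == 1250.0

    def test_tone_classes_follow_tokens_and_gaps_bounded(self, inventory):
        for seed in range(25):
            seq = assemble_sequence(
                TokenString.classify("LHHHL", "Test1"), inventory, seed
            )
            assert tuple(t.class_label for t in seq.tones) == tuple("LHHHL")
            for gap in seq.gaps_ms:
                assert 10.0 <= gap <= 40.0

    def test_deterministic_and_empty_rejected(self, inventory):
        ts = TokenString.classify("LHL", "Test1")
        assert assemble_sequence(ts, inventory, 5) == assemble_sequence(ts, inventory, 5)
        empty = TokenString((), "Test1", "inconsistent", "other", 0)
        with pytest.raises(ValueError):
            assemble_sequence(empty, inventory, 5)


@pytest.mark.parametrize(
    "tokens, grammar, expected",
    [
        ("LHL", "Test1", ("consistent", "repetition", 1)),
        ("LHHL", "Test1", ("consistent", "repetition", 2)),
        ("LHHHHL", "Test1", ("consistent", "repetition", 4)),
        ("LHHHL", "Test1", ("consistent", "variation", 3)),
        ("LHHHHHL", "Test1", ("consistent", "variation", 5)),
        ("HL", "Test1", ("inconsistent", "missing_first", 1)),
        ("HHHL", "Test1", ("inconsistent", "missing_first", 3)),
        ("LH", "Test1", ("inconsistent", "missing_last", 1)),
        ("LHHHH", "Test1", ("inconsistent", "missing_last", 4)),
        ("LLL", "Test1", ("inconsistent", "other", 0)),
        ("HLH", "Test2", ("consistent", "repetition", 1)),
        ("HLLLH", "Test2", ("consistent", "variation", 3)),
        ("LLH", "Test2", ("inconsistent", "missing_first", 2)),
        ("HLL", "Test2", ("inconsistent", "missing_last", 2)),
    ],
)
def test_classify_tokens_design_space(tokens, grammar, expected):
    assert classify_tokens(tuple(tokens), grammar) == expected


def test_classify_tokens_rejects_bad_input():
    with pytest.raises(ValueError):
        classify_tokens(("L", "X"), "Test1")
    with pytest.raises(ValueError):
        classify_tokens(("L",), "Test1")
    with pytest.raises(ValueError):
        classify_tokens(("L", "H"), "Test3")


@given(n=st.integers(min_value=1, max_value=12))
@settings(deadline=None, derandomize=True)
def test_grammatical_strings_always_classify_consistent(n):
    tokens = ("L",) + ("H",) * n + ("L",)
    consistency, subclass, n_rep = classify_tokens(tokens, "Test1")
    assert consistency == "consistent" and n_rep == n
    assert subclass == ("repetition" if n in {1, 2, 4} else "variation")


class TestFamiliarizationTrack:
    def test_canonical_composition(self, inventory):
        track = compose_familiarization_track(FAMILIARIZATION_COUNTS, inventory, 2)
        assert len(track.sequences) == 360
        assert track.duration_s == 1800.0  # 30 min at one onset per 5 s
        refam = compose_familiarization_track(
            REFAMILIARIZATION_COUNTS, inventory, 2, role="refamiliarization"
        )
        assert len(refam.sequences) == 120 and refam.duration_s == 600.0

    def test_closure_every_sequence_is_grammatical(self, inventory):
        track = compose_familiarization_track({1: 8, 2: 5, 4: 4}, inventory, 9)
        for seq in track.sequences:
            ts = seq.token_string
            assert classify_tokens(ts.tokens, ts.grammar_tag)[0] == "consistent"

    def test_negative_counts_rejected(self, inventory):
        with pytest.raises(ValueError):
            compose_familiarization_track({1: -1}, inventory, 0)

    def test_symbolic_transition_balance(self, inventory):
        # balance holds whenever sum(count[n]*(n-1)) == sum(count[n])
        track = compose_familiarization_track({2: 17}, inventory, 4)
        counts = transition_counts(track)
        assert counts[("H", "H")] == counts[("H", "L")] == counts[("L", "H")] == 17


def test_transition_counts_examples(inventory):
    seqs = [
        assemble_sequence(TokenString.classify(s, "Test1"), inventory, i)
        for i, s in enumerate(["LHL"])
    ]
    assert transition_counts(seqs) == {("L", "H"): 1, ("H", "L"): 1}
    seqs = [assemble_sequence(TokenString.classify("LHHHHL", "Test1"), inventory, 0)]
    assert transition_counts(seqs) == {("L", "H"): 1, ("H", "H"): 3, ("H", "L"): 1}


class TestTestSession:
    def test_design_counts(self, inventory):
        trials = generate_test_session("Test1", "S1", inventory, 5)
        assert len(trials) == 16
        by_cons = pd.Series(
            [t.sequence.token_string.consistency for t in trials]
        ).value_counts()
        assert by_cons["consistent"] == 8 and by_cons["inconsistent"] == 8
        by_sub = pd.Series(
            [t.sequence.token_string.subclass for t in trials]
        ).value_counts()
        assert set(by_sub.values) == {4}

    def test_inverse_grammar_session(self, inventory):
        trials = generate_test_session("Test2", "S1", inventory, 5)
        for t in trials:
            ts = t.sequence.token_string
            if ts.consistency == "consistent":
                assert ts.tokens[0] == "H" and ts.tokens[-1] == "H"
                assert all(tok == "L" for tok in ts.tokens[1:-1])

    def test_individual_stimulus_sets(self, inventory):
        a = generate_test_session("Test1", "S1", inventory, 5)
        b = generate_test_session("Test1", "S2", inventory, 5)
        freqs = lambda trials: [
            t.sequence.tones[0].frequency_hz for t in sorted(
                trials, key=lambda t: str(t.sequence.token_string)
            )
        ]
        assert freqs(a) != freqs(b)  # distinct tone draws
        subclasses = lambda trials: sorted(
            t.sequence.token_string.subclass for t in trials
        )
        assert subclasses(a) == subclasses(b)  # identical design counts

    def test_unknown_grammar_rejected(self, inventory):
        with pytest.raises(ValueError):
            generate_test_session("Test3", "S1", inventory, 5)


class TestWriteTrack:
    def test_round_trip_and_duration(self, inventory, tmp_path):
        track = compose_familiarization_track({1: 2, 2: 1}, inventory, 3)
        wav, csv = tmp_path / "t.wav", tmp_path / "t.csv"
        manifest = write_track(track, wav, csv)
        pd.testing.assert_frame_equal(stimuli.read_manifest(csv), manifest)
        sr, pcm = wavfile.read(wav)
        expected = 2 * 5 * sr + round(track.sequences[-1].span_ms / 1000 * sr)
        assert len(pcm) == expected and pcm.dtype == np.int16

    def test_identical_seed_identical_manifest_bytes(self, inventory, tmp_path):
        for name in ("a", "b"):
            track = compose_familiarization_track({1: 3}, inventory, 11)
            write_track(track, tmp_path / f"{name}.wav", tmp_path / f"{name}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_empty_track_rejected(self, tmp_path):
        empty = stimuli.PlaybackTrack((), 5.0, "test", 0)
        with pytest.raises(ValueError):
            write_track(empty, tmp_path / "e.wav", tmp_path / "e.csv")
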