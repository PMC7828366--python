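"""Properties of the synthetic scene generator: determinism, envelope shape,
spectral signatures, SNR calibration, and corpus structure."""

import numpy as np
import pytest

from coughwatch import (
    CorpusRecipe,
    EventSpec,
    SceneSpec,
    generate_cough_burst,
    generate_distractor,
    make_corpus,
    render_scene,
)
from coughwatch.synthetic import _COUGH_DEFAULTS, _DISTRACTOR_DEFAULTS

RATE = 16000


def _rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


class TestCoughBurst:
    def test_same_seed_is_bit_identical(self):
        ev = EventSpec(onset_s=0, kind="cough")
        a = generate_cough_burst(5, RATE, ev)
        b = generate_cough_burst(5, RATE, ev)
        np.testing.assert_array_equal(a, b)

    def test_length_matches_duration(self):
        ev = EventSpec(onset_s=0, kind="cough", duration_s=0.35)
        assert len(generate_cough_burst(0, RATE, ev)) == round(0.35 * RATE)

    def test_energy_front_loaded(self):
        """The explosive phase concentrates energy at the start: first 100 ms
        RMS at least 3x the last 100 ms RMS."""
        ev = EventSpec(onset_s=0, kind="cough")
        burst = generate_cough_burst(2, RATE, ev)
        n = int(0.1 * RATE)
        assert _rms(burst[:n]) >= 3 * _rms(burst[-n:])

    def test_band_limited_to_cough_band(self):
        ev = EventSpec(onset_s=0, kind="cough", duration_s=0.5)
        burst = generate_cough_burst(3, RATE, ev)
        spec = np.abs(np.fft.rfft(burst)) ** 2
        f = np.fft.rfftfreq(len(burst), 1 / RATE)
        # envelope modulation spreads the band edges slightly, so measure a
        # small guard band around the nominal 300-3000 Hz passband
        in_band = spec[(f >= 250) & (f <= 3200)].sum()
        assert in_band / spec.sum() > 0.95

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            EventSpec(onset_s=0, kind="cough", duration_s=0.0)


class TestDistractor:
    def test_same_seed_is_identical(self):
        ev = EventSpec(onset_s=0, kind="distractor")
        np.testing.assert_array_equal(
            generate_distractor(9, RATE, ev), generate_distractor(9, RATE, ev)
        )

    def test_tone_distractor_peaks_at_fundamental(self):
        ev = EventSpec(
            onset_s=0, kind="distractor", duration_s=0.5, shape_params={"tone_hz": 440.0}
        )
        wave = generate_distractor(4, RATE, ev)
        spec = np.abs(np.fft.rfft(wave))
        f = np.fft.rfftfreq(len(wave), 1 / RATE)
        peak_hz = f[np.argmax(spec)]
        assert abs(peak_hz - 440.0) <= f[1]  # within one bin

    def test_attack_much_slower_than_cough(self):
        assert _DISTRACTOR_DEFAULTS["attack_s"] >= 5 * _COUGH_DEFAULTS["attack_s"]


class TestRenderScene:
    def test_empty_event_list_gives_pure_noise_and_empty_truth(self):
        rec, truth = render_scene(SceneSpec(duration_s=2.0, events=(), seed=0))
        assert truth.intervals == ()
        assert len(rec.samples) == 2 * RATE
        assert np.std(rec.samples) > 0

    def test_each_event_has_a_truth_interval_containing_its_onset(self):
        events = tuple(EventSpec(onset_s=t, kind="cough") for t in (1.0, 2.0, 3.0))
        _, truth = render_scene(SceneSpec(duration_s=4.0, events=events, seed=1))
        assert len(truth.intervals) == 3
        for ev, iv in zip(events, truth.intervals):
            assert iv.start_s <= ev.onset_s < iv.end_s
            assert iv.label == "cough"

    def test_measured_snr_within_1db_of_request(self):
        events = tuple(EventSpec(onset_s=t, kind="cough") for t in (1.0, 3.0, 5.0, 7.0))
        rec, truth = render_scene(SceneSpec(duration_s=9.0, events=events, snr_db=20.0, seed=2))
        mask = np.zeros(len(rec.samples), dtype=bool)
        for iv in truth.intervals:
            mask[int(iv.start_s * RATE) : int(iv.end_s * RATE)] = True
        measured_db = 20 * np.log10(_rms(rec.samples[mask]) / _rms(rec.samples[~mask]))
        assert 19.0 <= measured_db <= 21.0

    def test_adding_an_event_never_reduces_scene_energy(self):
        base = SceneSpec(duration_s=4.0, events=(EventSpec(onset_s=1.0, kind="cough"),), seed=3)
        more = SceneSpec(
            duration_s=4.0,
            events=base.events + (EventSpec(onset_s=2.5, kind="cough"),),
            seed=3,
        )
        e1 = np.sum(render_scene(base)[0].samples ** 2)
        e2 = np.sum(render_scene(more)[0].samples ** 2)
        assert e2 >= e1

    def test_event_past_scene_end_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(duration_s=1.0, events=(EventSpec(onset_s=0.9, kind="cough"),), seed=0)

    def test_reverb_keeps_length_and_peak_bound(self):
        events = (EventSpec(onset_s=0.5, kind="cough", peak_amplitude=1.0),)
        rec, _ = render_scene(
            SceneSpec(duration_s=2.0, events=events, reverb_rt60_s=0.4, seed=4)
        )
        assert len(rec.samples) == 2 * RATE
        assert np.max(np.abs(rec.samples)) <= 0.99 + 1e-9


class TestCorpus:
    def test_recording_ids_distinct(self):
        corpus = make_corpus(8, CorpusRecipe(duration_s=5.0, n_coughs=1, n_distractors=1), seed=0)
        ids = [rec.recording_id for rec, _ in corpus]
        assert len(set(ids)) == 8

    def test_same_master_seed_reproduces_corpus_exactly(self):
        recipe = CorpusRecipe(duration_s=5.0, n_coughs=2, n_distractors=1)
        a = make_corpus(3, recipe, seed=77)
        b = make_corpus(3, recipe, seed=77)
        for (ra, ta), (rb, tb) in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)
            assert ta.intervals == tb.intervals

    def test_recipe_event_counts_respected(self):
        recipe = CorpusRecipe(duration_s=10.0, n_coughs=5, n_distractors=5)
        for _, truth in make_corpus(4, recipe, seed=5):
            labels = [iv.label for iv in truth.intervals]
            assert len(labels) == 10
            assert labels.count("cough") == 5
            assert labels.count("distractor") == 5

    def test_truth_intervals_disjoint(self):
        for _, truth in make_corpus(4, CorpusRecipe(duration_s=10.0), seed=6):
            ivs = sorted(truth.intervals, key=lambda v: v.start_s)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end_s <= b.start_s
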