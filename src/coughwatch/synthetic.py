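"""Synthetic acoustic scenes with ground-truth annotations.

Real nocturnal cough recordings are private clinical data, so every stage of
the detector is exercised on generated scenes that encode the acoustic
structure the detector assumes:

* **Coughs** — the explosive phase of a cough is a sudden release of air from
  the lungs, i.e. a band-limited noise burst with a very fast energy rise.
  The model is band-passed white noise (300–3000 Hz by default) shaped by an
  attack–decay envelope: a linear attack of a few milliseconds to peak, then
  an exponential decay.
* **Distractors** — transients that trigger an energy-onset gate but are not
  coughs: harmonic tone bursts (dropped object, beep) or slow-attack noise
  swells.  Their envelope attack is at least an order of magnitude slower
  than a cough's.
* **Background** — stationary white or pink noise at a controllable SNR, and
  optionally a synthetic exponentially-decaying room impulse response
  parameterised by RT60, standing in for varying rooms and devices.

Scene SNR convention: the noise floor is scaled so that the mean, over
events, of the event-signal RMS measured across the event's truth interval,
divided by the noise RMS, equals ``snr_db``.  Measured in-interval vs
out-of-interval RMS then matches the request to within about 1 dB at
moderate-to-high SNR.

Everything is a pure function of its seed: the same ``SceneSpec`` or corpus
recipe renders bit-identical audio and truth every time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal

from .audio import AudioRecording
from .evaluation import AnnotatedInterval

__all__ = [
    "EventSpec",
    "SceneSpec",
    "SceneTruth",
    "CorpusRecipe",
    "generate_cough_burst",
    "generate_distractor",
    "render_scene",
    "make_corpus",
    "easy_recipe",
]

#: pre-onset padding of truth intervals, seconds ("a little before" the onset)
TRUTH_PAD_BEFORE_S = 0.1

_COUGH_DEFAULTS = {
    "attack_s": 0.005,
    "decay_tau_s": 0.06,
    "band_lo_hz": 300.0,
    "band_hi_hz": 3000.0,
}
_DISTRACTOR_DEFAULTS = {
    "attack_s": 0.08,
    "decay_tau_s": 0.25,
    "tone_hz": 440.0,
    "n_harmonics": 3,
}


@dataclass(frozen=True)
class EventSpec:
    """One transient event placed in a scene."""

    onset_s: float
    kind: Literal["cough", "distractor"]
    peak_amplitude: float = 0.5
    duration_s: float = 0.35
    shape_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0 < self.peak_amplitude <= 1:
            raise ValueError("peak_amplitude must lie in (0, 1]")
        if self.kind not in ("cough", "distractor"):
            raise ValueError(f"unknown event kind {self.kind!r}")

    def resolved_shape(self) -> dict:
        base = _COUGH_DEFAULTS if self.kind == "cough" else _DISTRACTOR_DEFAULTS
        return {**base, **self.shape_params}


@dataclass(frozen=True)
class SceneSpec:
    """A full scene: events over a noise floor, optionally reverberant."""

    duration_s: float
    events: tuple[EventSpec, ...]
    noise_kind: Literal["white", "pink"] = "white"
    snr_db: float = 20.0
    reverb_rt60_s: float = 0.0
    seed: int = 0
    sample_rate_hz: int = 16000

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(sorted(self.events, key=lambda e: e.onset_s)))
        for ev in self.events:
            if ev.onset_s >= self.duration_s:
                raise ValueError(f"event onset {ev.onset_s} outside scene [0, {self.duration_s})")
            if ev.onset_s + ev.duration_s > self.duration_s:
                raise ValueError(f"event at {ev.onset_s} extends past scene end")
        if self.reverb_rt60_s < 0:
            raise ValueError("reverb_rt60_s must be >= 0")


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for a rendered scene: one labeled interval per event."""

    intervals: tuple[AnnotatedInterval, ...]


def _attack_decay_envelope(
    n: int, rate: int, attack_s: float, decay_tau_s: float
) -> np.ndarray:
    n_attack = max(1, int(round(attack_s * rate)))
    n_attack = min(n_attack, n)
    env = np.empty(n)
    env[:n_attack] = np.linspace(0.0, 1.0, n_attack, endpoint=False) if n_attack > 1 else 1.0
    t = np.arange(n - n_attack) / rate
    env[n_attack:] = np.exp(-t / decay_tau_s)
    return env


def generate_cough_burst(seed: int, sample_rate_hz: int, params: EventSpec) -> np.ndarray:
    """Render one cough-like burst: band-limited noise under an attack–decay envelope.

    Deterministic given ``seed``.  Length is ``round(duration_s * rate)`` and
    the peak absolute amplitude equals ``params.peak_amplitude``.
    """
    if params.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    shape = params.resolved_shape()
    if params.duration_s < shape["attack_s"]:
        raise ValueError("duration_s must cover at least the attack time")
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * sample_rate_hz))
    noise = rng.standard_normal(n)
    nyq = sample_rate_hz / 2
    sos = signal.butter(
        8, [shape["band_lo_hz"] / nyq, shape["band_hi_hz"] / nyq], btype="band", output="sos"
    )
    noise = signal.sosfilt(sos, noise)
    burst = noise * _attack_decay_envelope(n, sample_rate_hz, shape["attack_s"], shape["decay_tau_s"])
    peak = np.max(np.abs(burst))
    if peak > 0:
        burst *= params.peak_amplitude / peak
    return burst


def generate_distractor(seed: int, sample_rate_hz: int, params: EventSpec) -> np.ndarray:
    """Render one non-cough transient.

    If the resolved shape has a ``tone_hz``, the distractor is a harmonic tone
    burst; setting ``tone_hz`` to ``None`` gives a slow-attack broadband noise
    swell instead.  Either way the envelope attack is >= 50 ms, an order of
    magnitude slower than a cough's, so the two classes are separable in the
    log-mel domain while both still trip an energy-onset gate.
    """
    if params.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    shape = params.resolved_shape()
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    if shape.get("tone_hz") is not None:
        f0 = float(shape["tone_hz"])
        phases = rng.uniform(0, 2 * np.pi, size=int(shape["n_harmonics"]))
        wave = np.zeros(n)
        for h, ph in enumerate(phases, start=1):
            wave += np.sin(2 * np.pi * f0 * h * t + ph) / h
    else:
        wave = rng.standard_normal(n)
        sos = signal.butter(4, 2000.0 / (sample_rate_hz / 2), btype="low", output="sos")
        wave = signal.sosfilt(sos, wave)
    burst = wave * _attack_decay_envelope(n, sample_rate_hz, shape["attack_s"], shape["decay_tau_s"])
    peak = np.max(np.abs(burst))
    if peak > 0:
        burst *= params.peak_amplitude / peak
    return burst


def _noise_floor(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    if kind == "white":
        out = white
    elif kind == "pink":
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n)
        scale = np.ones_like(f)
        scale[1:] = 1.0 / np.sqrt(f[1:])
        out = np.fft.irfft(spec * scale, n=n)
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    return out / np.std(out)


def _reverb_ir(rt60_s: float, rate: int, rng: np.random.Generator) -> np.ndarray:
    # exponentially decaying noise tail; 60 dB decay over rt60 seconds
    n = max(1, int(round(rt60_s * rate)))
    t = np.arange(n) / rate
    ir = rng.standard_normal(n) * np.exp(-6.9078 * t / rt60_s)
    ir[0] = 1.0  # direct path
    return ir / np.max(np.abs(ir))


def truth_interval_for(event: EventSpec, recording_id: str) -> AnnotatedInterval:
    """The annotation bracket for one event: a little before the onset to its end."""
    return AnnotatedInterval(
        recording_id=recording_id,
        start_s=max(0.0, event.onset_s - TRUTH_PAD_BEFORE_S),
        end_s=event.onset_s + event.duration_s,
        label=event.kind,
    )


def render_scene(spec: SceneSpec, recording_id: str = "scene") -> tuple[AudioRecording, SceneTruth]:
    """Render a scene spec to audio plus its ground-truth intervals.

    The event mix is built dry, the noise floor is scaled to the requested
    SNR, reverberation (if any) is applied to the sum, and the final peak is
    normalised down to 0.99 if it exceeds full scale.
    """
    rate = spec.sample_rate_hz
    n = int(round(spec.duration_s * rate))
    rng = np.random.default_rng(spec.seed)

    event_mix = np.zeros(n)
    intervals = []
    interval_rms = []
    for k, ev in enumerate(spec.events):
        child = int(rng.integers(0, 2**31))
        wave = (
            generate_cough_burst(child, rate, ev)
            if ev.kind == "cough"
            else generate_distractor(child, rate, ev)
        )
        i0 = int(np.floor(ev.onset_s * rate + 1e-9))
        event_mix[i0 : i0 + len(wave)] += wave
        iv = truth_interval_for(ev, recording_id)
        intervals.append(iv)
        j0, j1 = int(np.floor(iv.start_s * rate + 1e-9)), int(np.ceil(iv.end_s * rate))
        seg = event_mix[j0:j1]  # event signal diluted over its annotation bracket
        interval_rms.append(np.sqrt(np.mean(wave**2) * len(wave) / max(len(seg), 1)))

    noise = _noise_floor(spec.noise_kind, n, rng)
    if interval_rms:
        target_noise_rms = float(np.mean(interval_rms)) / 10 ** (spec.snr_db / 20)
    else:
        target_noise_rms = 1e-3  # bare noise floor for event-free scenes
    scene = event_mix + noise * target_noise_rms

    if spec.reverb_rt60_s > 0:
        ir = _reverb_ir(spec.reverb_rt60_s, rate, rng)
        scene = signal.fftconvolve(scene, ir)[:n]

    peak = np.max(np.abs(scene)) if n else 0.0
    if peak > 0.99:
        scene *= 0.99 / peak

    rec = AudioRecording(recording_id=recording_id, samples=scene, sample_rate_hz=rate)
    return rec, SceneTruth(intervals=tuple(intervals))


@dataclass(frozen=True)
class CorpusRecipe:
    """Distribution over scenes for corpus generation.

    Defaults reflect the intended deployment: long quiet-room recordings in
    which sparse coughs and equally sparse non-cough transients sit on a
    stationary noise floor at comfortably positive SNR.
    """

    n_coughs: int = 5
    n_distractors: int = 5
    duration_s: float = 30.0
    snr_db_range: tuple[float, float] = (20.0, 30.0)
    reverb_rt60_range: tuple[float, float] = (0.0, 0.0)
    noise_kind: Literal["white", "pink"] = "white"
    sample_rate_hz: int = 16000
    event_duration_s: float = 0.35
    peak_amplitude_range: tuple[float, float] = (0.3, 0.8)


def easy_recipe() -> CorpusRecipe:
    """The benign study condition: dry scenes, SNR >= 20 dB, 5 coughs + 5 distractors per 30 s."""
    return CorpusRecipe()


def _place_events(recipe: CorpusRecipe, rng: np.random.Generator) -> tuple[EventSpec, ...]:
    n_events = recipe.n_coughs + recipe.n_distractors
    kinds = ["cough"] * recipe.n_coughs + ["distractor"] * recipe.n_distractors
    rng.shuffle(kinds)
    # one event per equal slot, jittered, so truth intervals never overlap
    slot = recipe.duration_s / n_events
    margin = TRUTH_PAD_BEFORE_S + recipe.event_duration_s
    if slot <= margin + 0.05:
        raise ValueError("scene too short for the requested event count")
    events = []
    for k, kind in enumerate(kinds):
        lo = k * slot + TRUTH_PAD_BEFORE_S + 0.025
        hi = (k + 1) * slot - recipe.event_duration_s - 0.025
        onset = float(rng.uniform(lo, hi))
        events.append(
            EventSpec(
                onset_s=onset,
                kind=kind,  # type: ignore[arg-type]
                peak_amplitude=float(rng.uniform(*recipe.peak_amplitude_range)),
                duration_s=recipe.event_duration_s,
            )
        )
    return tuple(events)


def make_corpus(
    n_recordings: int, recipe: CorpusRecipe, seed: int
) -> list[tuple[AudioRecording, SceneTruth]]:
    """Generate ``n_recordings`` annotated scenes, reproducibly from ``seed``.

    Each recording draws a distinct child seed from the master seed and a
    distinct ``recording_id`` (``rec0000``, ``rec0001``, ...).
    """
    if n_recordings < 1:
        raise ValueError("n_recordings must be >= 1")
    master = np.random.default_rng(seed)
    corpus = []
    for i in range(n_recordings):
        child_seed = int(master.integers(0, 2**31))
        rng = np.random.default_rng(child_seed)
        events = _place_events(recipe, rng)
        spec = SceneSpec(
            duration_s=recipe.duration_s,
            events=events,
            noise_kind=recipe.noise_kind,
            snr_db=float(rng.uniform(*recipe.snr_db_range)),
            reverb_rt60_s=float(rng.uniform(*recipe.reverb_rt60_range)),
            seed=int(rng.integers(0, 2**31)),
            sample_rate_hz=recipe.sample_rate_hz,
        )
        corpus.append(render_scene(spec, recording_id=f"rec{i:04d}"))
    return corpus
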