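"""Fixed analysis windows and their log-mel spectrograms.

Every candidate onset is represented to the classifier by the same geometry:
a window from 0.125 s before the onset to 0.5 s after it (0.625 s total,
zero-padded at recording edges), mapped to a log-mel spectrogram — STFT
power through an area-normalised triangular mel filterbank, then a natural
log with a small additive floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .audio import AudioRecording, extract_snippet
from .onsets import OnsetEvent

__all__ = [
    "Segment",
    "MelParams",
    "LogMelSpectrogram",
    "extract_segment",
    "log_mel",
    "featurize_onsets",
    "resample",
    "SEGMENT_PRE_S",
    "SEGMENT_POST_S",
]

SEGMENT_PRE_S = 0.125  # window starts this long before the onset
SEGMENT_POST_S = 0.5  # and ends this long after it
SEGMENT_LEN_S = SEGMENT_PRE_S + SEGMENT_POST_S


@dataclass(frozen=True)
class Segment:
    """The fixed 0.625 s analysis window anchored at one onset."""

    recording_id: str
    onset_time_s: float
    samples: np.ndarray
    sample_rate_hz: int

    @property
    def start_s(self) -> float:
        return self.onset_time_s - SEGMENT_PRE_S

    @property
    def end_s(self) -> float:
        return self.onset_time_s + SEGMENT_POST_S


@dataclass(frozen=True)
class MelParams:
    """Log-mel geometry.  Defaults: 64 bands, 25 ms Hann window, 10 ms hop,
    50 Hz–8 kHz, natural log with a 1e-10 floor, at a 16 kHz processing rate."""

    n_mels: int = 64
    win_s: float = 0.025
    hop_s: float = 0.010
    fmin_hz: float = 50.0
    fmax_hz: float = 8000.0
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")
        if not 0 < self.fmin_hz < self.fmax_hz:
            raise ValueError("need 0 < fmin_hz < fmax_hz")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")

    def to_dict(self) -> dict:
        return {
            "n_mels": self.n_mels,
            "win_s": self.win_s,
            "hop_s": self.hop_s,
            "fmin_hz": self.fmin_hz,
            "fmax_hz": self.fmax_hz,
            "log_floor": self.log_floor,
        }


@dataclass(frozen=True)
class LogMelSpectrogram:
    """frames x n_mels log-power matrix with per-frame start times."""

    values: np.ndarray
    frame_times_s: np.ndarray
    params: MelParams


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, rate: int, fmin: float, fmax: float) -> np.ndarray:
    """Triangular, area-normalised mel filterbank (n_mels x n_fft//2+1)."""
    edges_hz = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2))
    bin_hz = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, len(bin_hz)))
    for m in range(n_mels):
        lo, ctr, hi = edges_hz[m : m + 3]
        rise = (bin_hz - lo) / max(ctr - lo, 1e-12)
        fall = (hi - bin_hz) / max(hi - ctr, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(rise, fall))
        fb[m] *= 2.0 / max(hi - lo, 1e-12)  # area normalisation
    return fb


def extract_segment(recording: AudioRecording, onset: OnsetEvent | float) -> Segment:
    """Cut the fixed window around one onset, zero-padding past recording edges.

    Raises
    ------
    ValueError
        If the onset time lies outside the recording.
    """
    t = onset.time_s if isinstance(onset, OnsetEvent) else float(onset)
    if not 0 <= t <= recording.duration_s:
        raise ValueError(f"onset {t} s outside recording of {recording.duration_s} s")
    snip = extract_snippet(recording, t - SEGMENT_PRE_S, t + SEGMENT_POST_S)
    return Segment(
        recording_id=recording.recording_id,
        onset_time_s=t,
        samples=snip.samples,
        sample_rate_hz=recording.sample_rate_hz,
    )


def log_mel(segment: Segment, params: MelParams | None = None) -> LogMelSpectrogram:
    """Log-mel spectrogram of one segment.

    Frames are taken without padding (count ``1 + (N - win) // hop``), so a
    0.625 s segment at 16 kHz with the default geometry always yields a
    61 x 64 matrix.
    """
    params = params or MelParams()
    rate = segment.sample_rate_hz
    if params.fmax_hz > rate / 2:
        raise ValueError(f"fmax {params.fmax_hz} Hz above Nyquist {rate / 2} Hz")
    n_win = int(round(params.win_s * rate))
    n_hop = int(round(params.hop_s * rate))
    n_fft = 1 << (n_win - 1).bit_length()
    x = segment.samples
    n_frames = 1 + (len(x) - n_win) // n_hop
    if n_frames < 1:
        raise ValueError("segment shorter than one analysis window")
    idx = np.arange(n_win)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hanning(n_win)
    power = np.abs(np.fft.rfft(frames, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(params.n_mels, n_fft, rate, params.fmin_hz, params.fmax_hz)
    melpow = power @ fb.T
    values = np.log(melpow + params.log_floor)
    frame_times = n_hop * np.arange(n_frames) / rate
    return LogMelSpectrogram(values=values, frame_times_s=frame_times, params=params)


def featurize_onsets(
    recording: AudioRecording,
    onsets: list[OnsetEvent],
    params: MelParams | None = None,
) -> list[tuple[Segment, LogMelSpectrogram]]:
    """Segment + log-mel for each onset, order preserved."""
    params = params or MelParams()
    out = []
    for onset in onsets:
        seg = extract_segment(recording, onset)
        out.append((seg, log_mel(seg, params)))
    return out


def resample(recording: AudioRecording, target_rate_hz: int) -> AudioRecording:
    """Polyphase resample to the processing rate (identity if already there)."""
    if recording.sample_rate_hz == target_rate_hz:
        return recording
    from math import gcd

    g = gcd(target_rate_hz, recording.sample_rate_hz)
    up, down = target_rate_hz // g, recording.sample_rate_hz // g
    samples = _sig.resample_poly(recording.samples, up, down)
    return AudioRecording(
        recording_id=recording.recording_id,
        samples=samples,
        sample_rate_hz=target_rate_hz,
        source_label=recording.source_label,
    )
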