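"""Acoustic onset detection: spectral-flux novelty and adaptive peak picking.

This is the gate in front of the classifier.  A cough's explosive phase
produces a rapid rise in acoustic energy, so candidate instants are found as
peaks of a half-wave-rectified spectral-flux novelty function; only the
fixed window around each pick is ever featurised and classified, which cuts
the audio volume the classifier must see by orders of magnitude on sparse
recordings.

The threshold is adaptive — a multiple of the local 1-second median of the
novelty — so a single setting works across noise floors from different rooms
and devices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import AudioRecording

__all__ = ["OnsetEvent", "OnsetParams", "novelty_curve", "pick_onsets", "detect_onsets"]

_EPS = 1e-8  # absolute part of the threshold floor; keeps silence pick-free
_REL_FLOOR = 0.1  # floor fraction of the global median novelty


@dataclass(frozen=True)
class OnsetEvent:
    """A picked onset: time from recording start and novelty strength."""

    time_s: float
    strength: float


@dataclass(frozen=True)
class OnsetParams:
    """Analysis geometry and picking thresholds.

    frame_s : STFT frame length (s); 32 ms default resolves cough transients.
    hop_s : analysis hop (s).
    threshold_k : multiplier on the adaptive median threshold.
    min_separation_s : minimum gap between picks; 0.2 s default is shorter
        than the 0.625 s classification window so bursts inside one coughing
        fit still each gate a segment.
    """

    frame_s: float = 0.032
    hop_s: float = 0.010
    threshold_k: float = 1.5
    min_separation_s: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.hop_s <= self.frame_s:
            raise ValueError("need 0 < hop_s <= frame_s")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")
        if self.min_separation_s < 0:
            raise ValueError("min_separation_s must be >= 0")


def _frame(samples: np.ndarray, n_frame: int, n_hop: int) -> np.ndarray:
    n = len(samples)
    if n < n_frame:
        return np.empty((0, n_frame))
    n_frames = 1 + (n - n_frame) // n_hop
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    return samples[idx]


def novelty_curve(recording: AudioRecording, params: OnsetParams) -> np.ndarray:
    """Per-frame half-wave-rectified spectral flux.

    Frame ``t``'s value is the sum over frequency bins of the positive part
    of the STFT-magnitude increment from frame ``t-1``; the first frame is 0.
    Returns an empty array if the recording is shorter than one frame.
    """
    rate = recording.sample_rate_hz
    n_frame = int(round(params.frame_s * rate))
    n_hop = int(round(params.hop_s * rate))
    frames = _frame(recording.samples, n_frame, n_hop)
    if len(frames) == 0:
        return np.zeros(0)
    window = np.hanning(n_frame)
    mags = np.abs(np.fft.rfft(frames * window, axis=1))
    flux = np.sum(np.maximum(np.diff(mags, axis=0), 0.0), axis=1)
    return np.concatenate([[0.0], flux])


def _adaptive_threshold(novelty: np.ndarray, params: OnsetParams) -> np.ndarray:
    # The floor added to the local median is scale-aware: a fixed absolute
    # constant cannot be "small" across unknown input levels, and without a
    # level-proportional part, dips of the local median on stationary noise
    # let ordinary fluctuations through as picks.
    eps = _EPS + _REL_FLOOR * float(np.median(novelty))
    half = max(1, int(round(0.5 / params.hop_s)))  # 1 s sliding window
    n = len(novelty)
    thr = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        thr[i] = np.median(novelty[lo:hi])
    return params.threshold_k * (thr + eps)


def pick_onsets(novelty: np.ndarray, params: OnsetParams) -> list[OnsetEvent]:
    """Pick onset frames from a novelty curve.

    A frame is a candidate iff it is a strict local maximum and exceeds
    ``threshold_k * (local 1 s median + eps)``, where ``eps`` is a tenth of
    the global median novelty plus a tiny absolute constant — so stationary
    noise whose local median happens to dip cannot generate spurious picks,
    and digital silence yields none at all.  Candidates closer than
    ``min_separation_s`` are thinned by keeping the strongest (earliest on
    ties).  Output is sorted by time.
    """
    n = len(novelty)
    if n == 0:
        return []
    thr = _adaptive_threshold(novelty, params)
    prev = np.concatenate([[np.inf], novelty[:-1]])
    nxt = np.concatenate([novelty[1:], [np.inf]])
    cand = np.flatnonzero((novelty > prev) & (novelty > nxt) & (novelty > thr))
    # greedy strongest-first suppression, earliest wins ties
    order = sorted(cand, key=lambda i: (-novelty[i], i))
    min_gap = params.min_separation_s / params.hop_s
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_gap for j in kept):
            kept.append(i)
    kept.sort()
    return [OnsetEvent(time_s=i * params.hop_s, strength=float(novelty[i])) for i in kept]


def detect_onsets(recording: AudioRecording, params: OnsetParams | None = None) -> list[OnsetEvent]:
    """Novelty computation and peak picking in one call."""
    params = params or OnsetParams()
    return pick_onsets(novelty_curve(recording, params), params)
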