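"""WAV reading/writing and time-windowed snippet extraction.

Everything downstream works on a mono floating-point representation with
amplitudes in [-1, 1].  Time intervals are half-open ``[start, end)`` in
seconds and the sample index of a time ``t`` is ``floor(t * rate)``, which
makes snippet concatenation lossless: the snippets ``[a, b)`` and ``[b, c)``
concatenate exactly to ``[a, c)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioRecording", "read_wav", "write_wav", "extract_snippet"]

_INT_SCALES = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
    np.dtype(np.uint8): 2.0**7,  # uint8 WAV is offset-binary around 128
}


@dataclass
class AudioRecording:
    """A sampled mono waveform with its rate and an identity.

    Parameters
    ----------
    recording_id
        Opaque identifier; evaluation folds group on it.
    samples
        1-D float array, nominal range [-1, 1].
    sample_rate_hz
        Sampling rate in Hz, > 0.
    source_label
        Optional free-text device/condition tag.
    """

    recording_id: str
    samples: np.ndarray
    sample_rate_hz: int
    source_label: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")

    @property
    def duration_s(self) -> float:
        """Duration in seconds, derived from the sample count."""
        return len(self.samples) / self.sample_rate_hz


def read_wav(path: str | Path, recording_id: str | None = None) -> AudioRecording:
    """Read a PCM WAV file into a mono float recording.

    Stereo (or any multi-channel) input is mixed down by averaging channels;
    integer sample formats are rescaled to [-1, 1].

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file is not an uncompressed WAV payload.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises ValueError/Parse errors for non-WAV
        raise ValueError(f"{path} is not a readable PCM WAV file: {exc}") from exc

    dtype = data.dtype
    if dtype in _INT_SCALES:
        if dtype == np.dtype(np.uint8):
            samples = (data.astype(np.float64) - 128.0) / _INT_SCALES[dtype]
        else:
            samples = data.astype(np.float64) / _INT_SCALES[dtype]
    elif np.issubdtype(dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {dtype} in {path}")

    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioRecording(
        recording_id=recording_id if recording_id is not None else path.stem,
        samples=samples,
        sample_rate_hz=int(rate),
    )


def write_wav(recording: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM mono WAV at its sample rate.

    Samples outside [-1, 1] are clipped to full scale with a warning.
    """
    samples = recording.samples
    peak = float(np.max(np.abs(samples))) if len(samples) else 0.0
    if peak > 1.0:
        warnings.warn(
            f"clipping {recording.recording_id}: peak amplitude {peak:.3f} exceeds full scale",
            stacklevel=2,
        )
        samples = np.clip(samples, -1.0, 1.0)
    pcm = np.round(samples * (2.0**15 - 1)).astype(np.int16)
    wavfile.write(str(Path(path)), int(recording.sample_rate_hz), pcm)


def extract_snippet(recording: AudioRecording, start_s: float, end_s: float) -> AudioRecording:
    """Return the samples in the half-open window ``[start_s, end_s)``.

    Spans outside the recording are zero-padded, so the output length is
    always ``round((end_s - start_s) * sample_rate_hz)`` — onset-anchored
    windows near recording edges still yield fixed-length segments.

    Raises
    ------
    ValueError
        If ``start_s >= end_s``.
    """
    if start_s >= end_s:
        raise ValueError(f"need start_s < end_s, got [{start_s}, {end_s})")
    rate = recording.sample_rate_hz
    n_out = int(round((end_s - start_s) * rate))
    # tiny bias guards against 159.999... artifacts when start_s is not binary-exact
    i0 = int(np.floor(start_s * rate + 1e-9))
    out = np.zeros(n_out, dtype=np.float64)
    src_lo = max(i0, 0)
    src_hi = min(i0 + n_out, len(recording.samples))
    if src_hi > src_lo:
        out[src_lo - i0 : src_hi - i0] = recording.samples[src_lo:src_hi]
    return AudioRecording(
        recording_id=recording.recording_id,
        samples=out,
        sample_rate_hz=rate,
        source_label=recording.source_label,
    )
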