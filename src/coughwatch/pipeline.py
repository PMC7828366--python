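"""Offline end-to-end processing: detect -> featurize -> classify -> report.

A recording is resampled to the processing rate, gated by the onset
detector, and each candidate window is classified; candidates labelled
cough become :class:`CoughEventRecord` entries (count + temporal location),
optionally with the 0.625 s window exported as a WAV snippet for later
playback by a professional reviewer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .audio import AudioRecording, extract_snippet, write_wav
from .classifier import CoughClassifier, LabeledExample
from .features import MelParams, featurize_onsets, resample
from .onsets import OnsetParams, detect_onsets
from .evaluation import AnnotatedInterval

__all__ = ["CoughEventRecord", "RunConfig", "process_recording", "build_labeled_examples"]


@dataclass(frozen=True)
class CoughEventRecord:
    """One detected cough: where it is, how confident, and its snippet file."""

    recording_id: str
    onset_time_s: float
    p_cough: float
    snippet_path: str | None = None


@dataclass(frozen=True)
class RunConfig:
    """Everything a processing run needs, serialisable to one YAML/JSON map."""

    sample_rate_hz: int = 16000
    onset: OnsetParams = field(default_factory=OnsetParams)
    mel: MelParams = field(default_factory=MelParams)
    threshold: float = 0.5
    window_start_s: float | None = None  # optional monitoring window
    window_end_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "sample_rate_hz": self.sample_rate_hz,
            "onset": {
                "frame_s": self.onset.frame_s,
                "hop_s": self.onset.hop_s,
                "threshold_k": self.onset.threshold_k,
                "min_separation_s": self.onset.min_separation_s,
            },
            "mel": self.mel.to_dict(),
            "threshold": self.threshold,
            "window_start_s": self.window_start_s,
            "window_end_s": self.window_end_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            sample_rate_hz=d.get("sample_rate_hz", 16000),
            onset=OnsetParams(**d.get("onset", {})),
            mel=MelParams(**d.get("mel", {})),
            threshold=d.get("threshold", 0.5),
            window_start_s=d.get("window_start_s"),
            window_end_s=d.get("window_end_s"),
        )


def process_recording(
    recording: AudioRecording,
    model: CoughClassifier,
    config: RunConfig | None = None,
    snippet_dir: str | Path | None = None,
) -> tuple[list[CoughEventRecord], dict]:
    """Run the full detection pipeline over one recording.

    Returns cough events sorted by time plus a summary dict with
    ``n_onsets``, ``n_cough_events`` and ``duration_s``.  When
    ``snippet_dir`` is given, each cough's 0.625 s window is written there
    as 16-bit WAV.

    Raises
    ------
    ValueError
        If the model's feature contract disagrees with the run config.
    """
    config = config or RunConfig()
    if model.mel_params != config.mel:
        raise ValueError(
            "model/config feature mismatch:\n"
            f"  model  : {model.mel_params.to_dict()}\n"
            f"  config : {config.mel.to_dict()}"
        )
    rec = resample(recording, config.sample_rate_hz)
    if config.window_start_s is not None or config.window_end_s is not None:
        lo = config.window_start_s or 0.0
        hi = config.window_end_s if config.window_end_s is not None else rec.duration_s
        rec = extract_snippet(rec, lo, hi)
    onsets = detect_onsets(rec, config.onset)
    events: list[CoughEventRecord] = []
    if onsets:
        feats = featurize_onsets(rec, onsets, config.mel)
        p = model.predict_proba([sp for _, sp in feats])
        for (seg, _), prob, onset in zip(feats, p, onsets):
            if prob >= config.threshold:
                snippet_path = None
                if snippet_dir is not None:
                    snippet_dir = Path(snippet_dir)
                    snippet_dir.mkdir(parents=True, exist_ok=True)
                    name = f"{rec.recording_id}_{onset.time_s:08.3f}s.wav"
                    snippet_path = str(snippet_dir / name)
                    write_wav(
                        AudioRecording(rec.recording_id, seg.samples, rec.sample_rate_hz),
                        snippet_path,
                    )
                events.append(
                    CoughEventRecord(
                        recording_id=rec.recording_id,
                        onset_time_s=onset.time_s,
                        p_cough=float(prob),
                        snippet_path=snippet_path,
                    )
                )
    summary = {
        "n_onsets": len(onsets),
        "n_cough_events": len(events),
        "duration_s": rec.duration_s,
    }
    return events, summary


def build_labeled_examples(
    recording: AudioRecording,
    truth: list[AnnotatedInterval],
    onset_params: OnsetParams | None = None,
    mel_params: MelParams | None = None,
) -> list[LabeledExample]:
    """Gate a recording and label each candidate window from the annotations.

    A candidate is labelled ``cough`` iff its onset lies inside a cough truth
    interval; everything else (distractor intervals and stray picks) is
    ``non_cough`` — exactly the population the classifier sees in deployment.
    """
    onset_params = onset_params or OnsetParams()
    mel_params = mel_params or MelParams()
    onsets = detect_onsets(recording, onset_params)
    cough_ivs = [iv for iv in truth if iv.label == "cough"]
    out = []
    for seg, spec in featurize_onsets(recording, onsets, mel_params):
        is_cough = any(iv.contains(seg.onset_time_s) for iv in cough_ivs)
        out.append(
            LabeledExample(
                spectrogram=spec,
                label="cough" if is_cough else "non_cough",
                recording_id=recording.recording_id,
            )
        )
    return out


def events_to_json(events: list[CoughEventRecord], summary: dict) -> str:
    """Stable JSON payload for a processed recording (no timestamps)."""
    payload = {
        "recording_id": events[0].recording_id if events else summary.get("recording_id", ""),
        "events": [
            {
                "onset_time_s": round(e.onset_time_s, 6),
                "p_cough": round(e.p_cough, 6),
                "snippet": e.snippet_path,
            }
            for e in events
        ],
        "summary": summary,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
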