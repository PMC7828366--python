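# Methods

## Problem and pipeline

`coughwatch` detects cough events in long offline audio recordings, the
processing back-end of a remote respiratory-monitoring setting: a phone
records during a user-defined period (typically overnight), and the
recording is analysed afterwards to report how many coughs occurred, when,
and with which audio snippets for clinical review.

The pipeline has three stages:

1. **Onset gate.** The explosive phase of a cough — the sudden release of
   air from the lungs — produces a rapid rise in acoustic energy. A
   half-wave-rectified spectral-flux novelty function is computed over
   STFT frames, and peaks above an adaptive threshold are picked as
   candidate instants. Only the neighbourhood of each candidate is ever
   classified, which reduces the audio volume reaching the classifier by
   orders of magnitude on sparse recordings, at the cost of missing events
   the gate skips.
2. **Fixed-window features.** Around each candidate onset a window from
   0.125 s before to 0.5 s after the onset (0.625 s total, zero-padded at
   recording edges) is cut and converted to a log-mel spectrogram.
3. **Recurrent classifier.** The spectrogram's frame sequence feeds two
   stacked LSTM layers of 256 units; the final hidden state feeds a dense
   layer of 64 units (ReLU), a dropout layer with probability 0.3, and a
   2-way softmax giving p(cough).

## Onset detection

Novelty: per frame, the sum over frequency bins of the positive part of the
STFT-magnitude increment from the previous frame (first frame 0). Spectral
flux responds to spectral change rather than absolute level, which makes it
robust to gain differences between devices. Analysis geometry: 32 ms Hann
frames, 10 ms hop.

Picking: a frame is picked iff it is a strict local maximum of the novelty
and exceeds `threshold_k × (local median + ε)`, where the local median is
taken over a sliding 1 s window, `threshold_k = 1.5`, and
`ε = 1e-8 + 0.1 × median(novelty)` over the whole recording. The
level-proportional part of ε matters: a purely absolute floor cannot be
"small" across unknown input scales, and without it, dips of the local
median on stationary noise let ordinary ±40 % flux fluctuations through as
spurious picks. With it, event-free noise scenes produce essentially no
picks while cough onsets (tens to hundreds of times the median flux at
SNR ≥ 20 dB) are unaffected. Picks closer than `min_separation_s = 0.2 s`
are thinned keeping the strongest (earliest on ties); 0.2 s is deliberately
shorter than the 0.625 s window so consecutive coughs within one fit each
gate their own segment.

A note on a tempting invariant: "raising `threshold_k` never increases the
pick count" is not a theorem under strongest-first suppression with a
*local* threshold — removing a strong pick can in principle un-suppress two
weaker neighbours. It holds in practice on realistic novelty curves, and the
suite checks it on rendered scenes, not on adversarial constructions.

## Features

STFT with 25 ms Hann windows and 10 ms hop, frames taken without padding
(`1 + (N − win)//hop` frames, i.e. 61 frames for a 0.625 s segment at
16 kHz); magnitude-squared spectra pass through a 64-band triangular mel
filterbank (area-normalised, 50 Hz–8 kHz) and a natural log with a `1e-10`
additive floor. Recordings at other rates are polyphase-resampled to the
16 kHz processing rate first, so the classifier input shape is universal.
These geometry values are package defaults chosen as field-standard
settings; nothing downstream depends on their particular values, only on
their being fixed in the model bundle.

## Classifier and training

The network is implemented directly on numpy (float32) with hand-written
backpropagation through time and Adam. Design points:

* **Sequence pooling.** The dense layer reads the last LSTM hidden state.
  Mean-pooling is a plausible alternative; last-state is the simplest
  reading of a recurrent encoder followed by a dense layer, and the segment
  is short enough (61 frames) that the choice is not critical.
* **Dropout placement** follows the layer order of the architecture: after
  the dense layer, before the softmax, active only in training (inverted
  dropout).
* **Loss.** Cross-entropy weighted by inverse class frequency. The onset
  gate passes roughly twice as many non-cough candidates as coughs on the
  synthetic corpus (and far more in real deployments), so unweighted
  training would bias toward the majority class.
* **Input standardisation.** Per-mel-band mean/variance computed on the
  training set and stored in the model bundle; log-mel values live around
  −23 … 0 and unstandardised inputs slow convergence badly.
* **Optimisation.** Adam, lr 1e-3, batch 32, gradient-norm clipping at 5,
  forget-gate bias initialised to 1, Glorot-uniform weights. Early stopping
  monitors the loss on a stratified 15 % holdout of the training examples;
  the best-epoch weights are restored. Defaults are max 50 epochs with
  patience 5; the cross-validation entry points use 25 epochs / patience 4,
  which is past convergence on the synthetic corpus (training typically
  converges within 10 epochs). After convergence individual epochs can blip
  upward (Adam on a saturated softmax); the restored-best contract is what
  callers rely on.
* **Determinism.** Initialisation, batch shuffling and dropout masks all
  derive from the config seed via separate `SeedSequence` streams; repeated
  training runs on identical data produce bit-identical predictions on the
  same platform.

The model bundle (`.npz`) serialises architecture, weights, normalisation
statistics and the mel geometry together; a loaded model refuses features
whose mel parameters disagree with its own.

## Evaluation protocol

Event-level semantics: a truth interval counts as *detected* if at least one
onset lies within it (`[start, end)`, multiple onsets collapse to one hit);
onsets inside no interval are stray picks. For the classifier, candidates
whose onset lies inside a cough truth interval are positives; everything
else the gate passed is a negative candidate. Sensitivity = 100·tp/(tp+fn),
specificity = 100·tn/(tn+fp), detection rate = 100·detected/total, all
rounded half-up to one decimal, matching the precision such results are
printed at. A metric with a zero denominator is reported as missing
(`None`), never as 0 or 100, so averages are not silently distorted.
Overlapping same-label truth intervals are merged before matching; the
corpus generator produces disjoint intervals by construction.

Cross-validation assigns *recordings*, not segments, to folds (seeded
shuffle, round-robin; fold sizes differ by at most one). This guarantees
that segments from one recording never appear on both sides of a
train/validation split, so the estimate reflects unseen recording
conditions rather than memorised room acoustics. Fold metrics are averaged
arithmetically. Each fold trains a fresh model with a fold-specific child
seed.

One arithmetic caveat is worth recording: published event counts for this
kind of protocol are sometimes internally inconsistent (e.g. a stated total
of 284 annotated onsets alongside a "275 out of 285" detection claim; 275
of 284 matches the printed 96.8 % rate, 275 of 285 would give 96.5 %). The
worked-example tests here use the count pair consistent with the printed
rate and make no claim about which figure is the typo.

## Synthetic scenes

The generator encodes the acoustic assumptions the detector relies on, not
physiological realism:

* **Cough** = white noise band-passed to 300–3000 Hz (8th-order
  Butterworth), shaped by a linear attack of 5 ms to peak and an
  exponential decay (τ = 60 ms), 0.35 s duration, peak amplitude drawn from
  [0.3, 0.8]. This realises exactly the property the gate exploits (a very
  fast energy rise) plus a spectral signature that makes classification
  learnable.
* **Distractor** = harmonic tone burst (440 Hz + 2 harmonics by default) or
  slow lowpassed-noise swell, with an 80 ms attack — at least an order of
  magnitude slower than a cough's, but still fast enough to trip the gate.
  Distractors exist so that the gate's false alarms are populated and the
  classifier has a non-trivial rejection task.
* **Background** = stationary white or pink noise. The noise floor is
  scaled so that the mean, over events, of the event-signal RMS across the
  event's truth interval over the noise RMS equals the requested SNR; this
  definition is well-behaved at all SNRs and keeps the measured
  in-interval/out-of-interval RMS ratio within about 1 dB of the request at
  moderate-to-high SNR (pooling across events of different peak amplitude
  biases the quadratic-mean measurement slightly above the arithmetic-mean
  target).
* **Reverberation** = convolution with an exponentially decaying noise
  impulse response parameterised by RT60 — a cheap stand-in for varying
  rooms and devices, not a room simulation.
* **Truth intervals** bracket each event from 0.1 s before its onset to its
  end; the 0.1 s pre-pad is this package's quantification of an annotator
  marking "a little before" the audible onset.

Scenes and corpora are pure functions of their seeds. The default corpus
recipe (the "easy" or benign condition) is 30 s scenes with 5 coughs and 5
distractors each, SNR drawn from [20, 30] dB, no reverberation.

**What passing on this corpus does and does not show.** Synthetic coughs
are homogeneous, truly band-limited, and sit on stationary noise; real
coughs vary across people and pathologies, overlap speech and music, and
arrive through unknown microphone chains. Results on the synthetic corpus
(gate recall ≈ 100 %, cross-validated sensitivity/specificity in the
mid-90s to 100) therefore validate the *machinery* — gating, windowing,
features, training, leakage-free evaluation — and say nothing quantitative
about clinical performance. The published real-data figures this design
descends from (96.8 % gate detection rate, 87.8 %/98.9 % cross-validated
sensitivity/specificity) came from a private recording set and are not
reproducible here; the worked-example tests reproduce only their
arithmetic.

## Problem sizes

The default verification workloads are sized for a single CPU: the standard
corpus is 20 recordings × 30 s (≈ 420 gated segments), on which grouped
4-fold cross-validation of the full 2×256 LSTM takes about a minute; unit
tests use an 8-recording × 10 s corpus. The acceptance script runs the full
chain (corpus synthesis → gate scoring → noise false-pick measurement →
4-fold CV) in under a minute.

## Known limitations

* No streaming/real-time mode; recordings are processed offline in memory.
* Cough *bouts* are reported per gated onset; a fit of n coughs closer than
  0.2 s apart may merge into fewer events, and no bout-aggregation logic is
  provided.
* The LSTM implementation is CPU-only and unbatched across recordings;
  training beyond a few thousand segments would be slow.
* Pink-noise and reverberation conditions are generated but the default
  acceptance conditions are dry; robustness under heavy reverberation is
  not claimed.
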