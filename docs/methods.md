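# Methods

This note documents the models, the parameter choices and the numerical
conventions behind `cryextract`, and what the synthetic validation does and
does not establish.

## Problem setting

Recordings are mono WAV at a canonical 24 kHz (other rates are polyphase
resampled on read; multi-channel audio is averaged). The target events are
spontaneous cries of preterm newborns, whose fundamental frequency typically
lies in 250–600 Hz, embedded in hours of incubator audio containing device
alarms, adult speech and broadband handling noise. The pipeline is strictly
sequential: segmentation → per-segment features → projection →
classification → (optionally) re-segmentation and F0 characterisation.

## Sound segmentation

The energy track uses 10 ms frames with a 5 ms hop, `10·log10(mean(x²))`
per frame, floored at −120 dB so silent frames stay finite. Frame length and
hop are design choices (fine enough to honour the 250 ms minimum event
duration); both are configurable.

Otsu's threshold is computed exactly: candidate thresholds are the inner
edges of a 256-bin histogram, and the between-class variance at each edge is
evaluated from the actual sample moments (prefix sums over the sorted
values), not from bin-centre approximations. When several edges tie — they
fall in an empty gap between modes — the plateau midpoint is returned. A
constant input raises a degeneracy error, which the segmenter maps to "no
events".

Two Otsu passes are applied in a seed-and-extend scheme: the first threshold
over all frame energies separates silence from sound; the second, estimated
only on above-silence frames, separates weak from strong activity. Runs of
above-low frames containing at least one above-high frame become segments.
This reading of "two successive thresholds" is isolated behind
`double_otsu_segment` so it can be swapped if a different interaction is
preferred. Segments closer than 50 ms are merged (glottal pulses of a single
cry otherwise fragment), and only segments with duration in the closed
interval [0.25 s, 5 s] are kept.

Because energies are log-scaled and the histogram adapts to the data range,
the segmentation is exactly invariant to global gain changes (as long as no
frame hits the −120 dB floor).

## F0 tracking

F0 is estimated per 5 ms frame as the frequency in the analysis band whose
continuous-wavelet-transform magnitude is maximal at the frame centre. The
wavelet is the analytic Morlet with centre frequency ω₀ = 6, evaluated in
the FFT domain (one Gaussian spectral window and one inverse FFT per scale,
keeping only frame-centre columns); scales are mapped to a 1 Hz frequency
grid over the band. The default band is 150–750 Hz. Segments are decimated
to 4 kHz before the transform — the band of interest lies far below the
2 kHz Nyquist of the decimated signal — which makes long segments cheap to
analyse at identical accuracy.

A frame is voiced when the peak magnitude is at least 3× the median
magnitude across the band (amplitude-invariant by construction) *and* the
peak is not at a band edge — an edge peak means the true F0 lies outside the
band. The ratio statistic is not comparable across bands of different
widths (a narrow band sits largely inside the Morlet response skirt of its
own peak, raising the median); therefore the automatic cry characterisation
takes voicing decisions from the standard-band pass and uses the refined
band only to re-estimate the voiced frames' F0 values.

Smoothing is a running median over each contiguous voiced run with a
9-frame (45 ms) default window; frames within half a window of a run
boundary are demoted to unvoiced, so the smoothed track starts after and
ends before unreliable leading/trailing frames, and voiced runs shorter than
the window disappear. Smoothing never voices a previously unvoiced frame.
Octave-jump handling is delegated entirely to this smoothing step.

Measured performance (recomputed by `scripts/acceptance.py`): mean |F0
error| ≈ 5.8 Hz over 50 synthetic cries with ±30 Hz vibrato at 20 dB SNR.

## Harmonic-plus-noise model

Analysis frames are 5 ms without overlap; a 1.000 s segment yields exactly
200 frames. For voiced frames the number of harmonics is
K = ⌊MVF / F0⌋ with the maximum voiced frequency fixed at MVF = 750 Hz, the
top of the analysis band (no per-frame MVF estimation; with F0 ≥ 150 Hz this
bounds K ≤ 5). Amplitudes and phases come from a least-squares fit of the
cosine/sine bank over a Hann-weighted window of 4 F0 periods centred on the
frame (≥ 2 periods are needed for conditioning); the phase argument is
2π·F0·t within the frame with the offset absorbed into Φₖ
(quasi-stationarity over 5 ms), with no cross-frame phase continuity
constraint. The fit is exact to machine precision on noiseless in-model
frames.

The residual (frame minus harmonic reconstruction) is modelled by
autocorrelation-method linear prediction of order 20, monic convention, with
gain equal to the prediction-error standard deviation; a constant or zero
residual maps to zero gain and an identity filter. Resynthesis drives each
frame's all-pole filter with fresh seeded white Gaussian noise scaled by the
gain (the autocorrelation identity then reproduces the residual variance)
and shapes it with a triangular envelope normalised to unit RMS so energy is
conserved; analysis is fully deterministic, synthesis is stochastic only
through that seeded noise. On synthetic material the in-band resynthesis SNR
is ≈ 26 dB and total energy is conserved within a few percent.

MFCCs are computed from the harmonic part: the line spectrum (k·F0, Aₖ) is
linearly interpolated onto a dense grid up to Nyquist with constant
extrapolation beyond the first/last harmonic, squared, passed through a
26-filter area-normalised triangular mel filterbank spanning 0 Hz–Nyquist,
log-compressed (floor 1e−10) and DCT-II (orthonormal) transformed; 16
coefficients are kept. Constant extrapolation makes a uniform amplitude
rescaling shift only coefficient 0. Unvoiced frames use the Hann-windowed
frame spectrum instead, and K = 0 is defined as the MFCC of a floor
spectrum. Computing MFCCs from the envelope rather than from resynthesised
h(t) is a committed design choice (the two agree up to interpolation error
and the envelope route is deterministic).

## Feature schema

Each segment is summarised by per-frame medians of the HNM quantities, by
default over *all* frames with unvoiced harmonic fields as zeros (weakly
voiced segments are thereby penalised, which serves the classification
intent; `median_voiced_only` flips this), plus ZCR and duration computed on
the raw samples. The fixed 73-column order is: F0 (1), number of harmonics
(1), harmonic amplitudes padded to 18 slots, harmonic phases padded to 14
slots, gain (1), 20 filter coefficients, 16 MFCCs, ZCR (1), duration (1).
The amplitude/phase slot widths exceed the K ≤ 5 reachable under the fixed
MVF; the surplus columns are identically zero and are removed by null-column
pruning (exact-zero test), whose surviving schema is stored in the model
artifact and re-applied verbatim at prediction time. The duration feature is
the raw segment duration, not the voiced duration. In the zero-crossing
indicator a zero sample is treated as positive (a product of zero is not a
crossing).

## Reduction

Standard scaling uses the population (divide-by-n) standard deviation —
stated explicitly because the sample/population choice changes downstream
numbers. PCA is fitted on the scaled training rows and the smallest k with
cumulative explained-variance ratio ≥ 0.95 is kept. Residual constant
columns are dropped with a warning. Component signs are fixed by making each
component's largest-magnitude loading positive, so serialised models are
reproducible. The scaler+PCA is always persisted inside the classifier
artifact; it is never refitted at prediction time.

## Classification

The labelled corpus is collapsed to binary (cry vs. everything else) and
split 60/40 with stratification and a mandatory seed. Hyper-parameters are
tuned by exhaustive grid search under 3-fold stratified CV **on the
projected features**: the null-column pruning and the scaler+PCA are fitted
once on the training split, then the CV folds select parameters — matching
the protocol in which the PCA is fitted on the training database before
classification. Two selection strategies are supported: highest mean CV
accuracy, or highest mean CV precision. Default grids: KNN neighbours
{1,3,5,11,15} × {Manhattan, Euclidean}; LDA solver {svd, lsqr, eigen};
logistic-regression probability cut-off {0.1, 0.2, 0.5, 0.7} (implemented as
a threshold wrapper, so cut-off 0 labels everything cry and cut-off 1
labels nothing); random-forest trees {5,…,300} × {gini, entropy}; MLP
layers {1,2,5} × width {1,…,30} × four activations; SVM polynomial degree
{1..4}; SVM RBF C {0.01..10⁴} × γ {10⁻⁴..100}. Unlisted hyper-parameters
stay at scikit-learn defaults and are recorded in the artifact. When
TP+FP = 0, precision is reported as 0 with a degeneracy flag. A `final`
training mode refits the tuned configuration on 100% of the labelled data
for deployment.

One measured caveat: on synthetic well-separated Gaussian clusters the full
scaler+PCA+classifier path reaches ≥ 95% test accuracy for seven of the
eight methods; the random forest plateaus a few points lower because
standardisation equalises the separating direction's variance with the
noise directions and the PCA rotation then spreads it across axes, which
axis-aligned splits handle poorly. This mirrors the generally weaker
generalisation of tree ensembles observed for this task.

## Deployment pipeline

`extract_cries` chains segmentation, per-segment features, schema
projection and prediction; a failing segment is logged and skipped rather
than aborting (a monitoring tool must survive 8 h recordings). Optional
post-passes:

- `resegment_long` re-runs segmentation+classification inside segments
  longer than 3 s (back-to-back events merge into one interval at the first
  pass) and maps results back to the recording timeline. It is opt-in,
  because re-segmentation destroys the duration information of genuinely
  long single cries.
- `characterise_cry` refines the analysis band to one octave either side of
  the coarse voiced median (clipped to 150–750 Hz), re-estimates F0 there,
  median-smooths, and reports median, IQR and voiced fraction. The manual
  band remains overridable.

## Synthetic data and what the tests show

`synthsound` generates: cry bursts (1/k-decaying harmonic stack, sinusoidal
vibrato, 50 ms attack / 100 ms release envelope, additive noise at a set
SNR, F0 250–600 Hz, durations inside the duration filter); softer
vocalisations; pulsed pure-tone alarms at {400, 800, 1500, 2000, 3000} Hz;
adult-voice surrogates (F0 85–255 Hz with formant-like resonances near 500
and 1500 Hz, so the first formant intrudes into the cry band); broadband
noise bursts; and full scenes on a −50 dB RMS stationary noise floor with
exact manifests (cries co-occurring with other events are labelled
`cry_overlap`). Foreground events are normalised by RMS (defaults 0.06–0.10,
i.e. 30–34 dB above the floor) so no class is systematically louder —
loudness is deliberately not a discriminative cue.

The training corpus is built the way an annotated database would be: events
are laid out in scenes, the energy segmenter is run, and the resulting
segments are labelled by majority overlap with the truth. Training examples
therefore have exactly the boundary statistics seen at deployment (one
segment per alarm pulse, attack/release ramps included). Default corpus:
40 cry events and 20 events of each non-cry class, giving ≈ 115 segments
with cry as a ~35% minority; alarm frequencies are cycled so every
frequency is represented. The closed-loop benchmark uses 60 s scenes with
5 cries, 3 alarms and 2 background bursts, ≥ 0.5 s event gaps, and scores
event-level precision/recall at 50% overlap.

Passing these tests shows the chain is self-consistent and that each stage
meets its stated accuracy on in-model signals. It does **not** establish
clinical performance: the surrogates have no reverberation, no overlapping
foreground events in the benchmark scenes, no recording-chain artefacts, no
infant-to-infant variability beyond F0/duration ranges, and the
cry/vocalisation boundary — subjective even for human annotators — is not
probed. Numbers on real NICU recordings will be lower.

## Problem sizes

The shipped tests and the acceptance script use deliberately small problem
sizes chosen to exercise every code path at statistical resolution adequate
for the stated tolerances: a ~115-segment training corpus, 50 F0 fixtures,
100-trial oracle comparisons, and ten 60 s benchmark scenes. All sizes are
parameters and scale up trivially.

## Known limitations

- The F0 grid is 1 Hz; sub-hertz vibrato detail is quantised away.
- MVF is fixed at 750 Hz, so harmonics of high-pitched cries above 750 Hz
  are deliberately relegated to the noise part (their energy is preserved,
  their harmonic structure is not).
- The LPC order (20) exceeds what a 120-sample frame can estimate crisply;
  coefficients are regularised by a tiny ridge on the autocorrelation.
- The double-Otsu seed-and-extend reading is one of several defensible
  interpretations of "two successive thresholds"; it is isolated in a
  single function.
- Overlap-resolving source separation, video-assisted segmentation,
  MFCC deltas, higher-frequency analysis bands and deep classifiers are out
  of scope.
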