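"""Synthetic NICU-like audio: labelled fixtures and full scenes.

No public corpus of incubator audio exists, so every stage of the package is
exercised on generated material that mimics the sound classes found around a
neonatal intensive care bed: harmonic cry bursts with vibrating F0 in the
250-600 Hz range, pulsed tonal device alarms, lower-pitched voiced
interference standing in for adult speech (F0 85-255 Hz), broadband
background noise bursts, and a stationary noise floor.  Generators are pure
functions of their parameters and seed, and every scene carries an exact
ground-truth manifest (cries co-occurring with another event are labelled
``cry_overlap``).

These surrogates reproduce the spectral layout and timing statistics that
drive segmentation and classification; they do not attempt perceptual
realism, room acoustics or recording-chain artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioInputError, AudioRecording, SegmentManifestRow

SAMPLE_RATE_HZ = 24_000

#: device-alarm tone frequencies covered by the generators (low to high)
ALARM_FREQS_HZ = (400.0, 800.0, 1500.0, 2000.0, 3000.0)


@dataclass
class SceneEvent:
    onset_s: float
    kind: str  # cry | vocalisation | alarm | adult | background
    params: dict = field(default_factory=dict)


@dataclass
class SceneSpec:
    duration_s: float
    events: list[SceneEvent]
    noise_floor_db: float = -50.0
    seed: int = 0


def _envelope(n: int, fs: int, attack_s: float = 0.050, release_s: float = 0.100) -> np.ndarray:
    """Linear attack / release amplitude envelope."""
    env = np.ones(n)
    a = min(int(attack_s * fs), n // 2)
    r = min(int(release_s * fs), n // 2)
    if a:
        env[:a] = np.linspace(0.0, 1.0, a, endpoint=False)
    if r:
        env[-r:] = np.linspace(1.0, 0.0, r)
    return env


def _add_noise(x: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    if not np.isfinite(snr_db):
        return x
    p_sig = np.mean(x**2)
    if p_sig == 0:
        return x
    sigma = np.sqrt(p_sig / 10 ** (snr_db / 10.0))
    return x + sigma * rng.standard_normal(x.size)


def gen_cry(
    duration_s: float = 1.5,
    f0_base_hz: float = 400.0,
    vibrato_hz: float = 30.0,
    vibrato_rate_hz: float = 5.0,
    n_harmonics: int = 5,
    snr_db: float = 30.0,
    seed: int = 0,
    sample_rate_hz: int = SAMPLE_RATE_HZ,
    amplitude: float = 0.10,
) -> tuple[np.ndarray, dict]:
    """A cry burst: decaying harmonic stack with sinusoidal F0 vibrato.

    Harmonic amplitudes fall off as 1/k; the F0 contour (the ground truth)
    vibrates by ``vibrato_hz`` around ``f0_base_hz`` at ``vibrato_rate_hz``.
    """
    if not 0.25 <= duration_s <= 5.0:
        raise AudioInputError("cry duration must be in [0.25, 5] s")
    if not 200.0 <= f0_base_hz <= 650.0:
        raise AudioInputError("cry F0 must be in [200, 650] Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    f0 = f0_base_hz + vibrato_hz * np.sin(2.0 * np.pi * vibrato_rate_hz * t)
    phase = 2.0 * np.pi * np.cumsum(f0) / sample_rate_hz
    x = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        x += (1.0 / k) * np.cos(k * phase + rng.uniform(0, 2 * np.pi))
    x *= _envelope(n, sample_rate_hz)
    scale = amplitude / max(np.sqrt(np.mean(x**2)), 1e-12)
    x *= scale
    x = _add_noise(x, snr_db, rng)
    truth = {
        "f0_times_s": t,
        "f0_hz": f0,
        "kind": "cry",
        # per-harmonic amplitudes at the envelope plateau (envelope = 1)
        "harmonic_amplitudes": scale / np.arange(1, n_harmonics + 1),
    }
    return x, truth


def gen_vocalisation(
    duration_s: float = 0.5,
    f0_base_hz: float = 350.0,
    seed: int = 0,
    sample_rate_hz: int = SAMPLE_RATE_HZ,
    amplitude: float = 0.06,
) -> tuple[np.ndarray, dict]:
    """A short, softer cooing-like voiced burst (fewer harmonics, no vibrato)."""
    x, truth = gen_cry(
        max(duration_s, 0.25),
        f0_base_hz,
        vibrato_hz=10.0,
        n_harmonics=3,
        snr_db=25.0,
        seed=seed,
        sample_rate_hz=sample_rate_hz,
        amplitude=amplitude,
    )
    truth["kind"] = "vocalisation"
    return x, truth


def gen_alarm(
    duration_s: float = 1.5,
    freq_hz: float = 2000.0,
    period_s: float = 1.0,
    duty: float = 0.4,
    seed: int = 0,
    sample_rate_hz: int = SAMPLE_RATE_HZ,
    amplitude: float = 0.10,
) -> tuple[np.ndarray, dict]:
    """A pulsed pure-tone device alarm with an on/off duty cycle."""
    if not 0 < freq_hz < sample_rate_hz / 2:
        raise AudioInputError("alarm frequency must be below Nyquist")
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    gate = (np.mod(t, period_s) < duty * period_s).astype(np.float64)
    # short ramps at gate edges to avoid clicks
    edge = max(int(0.005 * sample_rate_hz), 1)
    kernel = np.ones(edge) / edge
    gate_smooth = np.convolve(gate, kernel, mode="same")
    x = np.sin(2.0 * np.pi * freq_hz * t) * gate_smooth
    x *= amplitude / max(np.sqrt(np.mean(x**2)), 1e-12)
    onsets = []
    rising = np.flatnonzero(np.diff(np.concatenate(([0.0], gate))) > 0)
    falling = np.flatnonzero(np.diff(np.concatenate((gate, [0.0]))) < 0)
    for r, f in zip(rising, falling):
        onsets.append((r / sample_rate_hz, (f + 1) / sample_rate_hz))
    truth = {"kind": "alarm", "freq_hz": freq_hz, "pulses_s": onsets}
    return x, truth


def gen_voice_like(
    duration_s: float = 1.5,
    f0_hz: float = 120.0,
    seed: int = 0,
    sample_rate_hz: int = SAMPLE_RATE_HZ,
    amplitude: float = 0.08,
) -> tuple[np.ndarray, dict]:
    """Adult-voice surrogate: low-F0 harmonic stack with formant-like peaks.

    F0 must lie in the adult range 85-255 Hz; the spectral envelope has broad
    resonances near 500 and 1500 Hz, so the first formant can intrude into
    the cry analysis band.
    """
    if not 85.0 <= f0_hz <= 255.0:
        raise AudioInputError("adult F0 must be in [85, 255] Hz")
    n = int(round(duration_s * sample_rate_hz))
    if n == 0:
        return np.zeros(0), {"kind": "adult", "f0_hz": f0_hz}
    rng = np.random.default_rng(seed)
    t = np.arange(n) / sample_rate_hz
    x = np.zeros(n)
    formants = ((500.0, 150.0), (1500.0, 250.0))
    k_max = int(3000.0 // f0_hz)
    for k in range(1, k_max + 1):
        fk = k * f0_hz
        env = sum(np.exp(-0.5 * ((fk - fc) / bw) ** 2) for fc, bw in formants)
        x += (0.2 + env) / k**0.5 * np.cos(2.0 * np.pi * fk * t + rng.uniform(0, 2 * np.pi))
    x *= _envelope(n, sample_rate_hz)
    x *= amplitude / max(np.sqrt(np.mean(x**2)), 1e-12)
    return x, {"kind": "adult", "f0_hz": f0_hz}


def gen_background(
    duration_s: float = 1.0,
    seed: int = 0,
    sample_rate_hz: int = SAMPLE_RATE_HZ,
    amplitude: float = 0.08,
) -> tuple[np.ndarray, dict]:
    """A broadband background-noise burst (door, packaging, airflow ...)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    x = rng.standard_normal(n)
    x *= _envelope(n, sample_rate_hz)
    x *= amplitude / max(np.sqrt(np.mean(x**2)), 1e-12)
    return x, {"kind": "background"}


_GENERATORS = {
    "cry": gen_cry,
    "vocalisation": gen_vocalisation,
    "alarm": gen_alarm,
    "adult": gen_voice_like,
    "background": gen_background,
}


def gen_event(kind: str, seed: int, **params) -> tuple[np.ndarray, dict]:
    if kind not in _GENERATORS:
        raise AudioInputError(f"unknown event kind {kind!r}")
    return _GENERATORS[kind](seed=seed, **params)


def gen_scene(
    spec: SceneSpec, sample_rate_hz: int = SAMPLE_RATE_HZ
) -> tuple[AudioRecording, list[SegmentManifestRow]]:
    """Mix events onto a stationary noise floor; return audio + exact truth.

    Overlapping events are summed.  A cry that co-occurs in time with any
    other event is labelled ``cry_overlap`` in the manifest.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * sample_rate_hz))
    floor_sigma = 10 ** (spec.noise_floor_db / 20.0)
    x = floor_sigma * rng.standard_normal(n)
    intervals = []
    for i, ev in enumerate(spec.events):
        samples, _ = gen_event(ev.kind, seed=spec.seed * 1009 + i, **ev.params)
        i0 = int(round(ev.onset_s * sample_rate_hz))
        i1 = i0 + samples.size
        if i0 < 0 or i1 > n:
            raise AudioInputError(f"event {i} ({ev.kind}) outside the scene")
        x[i0:i1] += samples
        intervals.append((ev.onset_s, ev.onset_s + samples.size / sample_rate_hz, ev.kind))
    manifest = []
    rec_id = f"scene_seed{spec.seed}"
    for j, (s0, s1, kind) in enumerate(intervals):
        label = kind
        if kind == "cry":
            overlapped = any(
                j != k and s0 < o1 and o0 < s1 for k, (o0, o1, _) in enumerate(intervals)
            )
            label = "cry_overlap" if overlapped else "cry"
        manifest.append(SegmentManifestRow(rec_id, s0, s1, label=label))
    return AudioRecording(rec_id, x, sample_rate_hz), manifest


def _event_durations(kind: str, rng: np.random.Generator) -> float:
    if kind == "cry":
        return float(rng.uniform(0.4, 3.0))
    if kind == "vocalisation":
        return float(rng.uniform(0.3, 0.8))
    if kind == "alarm":
        return float(rng.uniform(0.4, 2.0))
    if kind == "adult":
        return float(rng.uniform(0.4, 3.0))
    return float(rng.uniform(0.3, 1.5))  # background


def _event_params(kind: str, rng: np.random.Generator, snr_db: float) -> dict:
    params: dict = {"duration_s": _event_durations(kind, rng)}
    if kind == "cry":
        params.update(
            f0_base_hz=float(rng.uniform(250, 600)),
            vibrato_hz=float(rng.uniform(10, 30)),
            n_harmonics=int(rng.integers(3, 6)),
            snr_db=snr_db,
        )
    elif kind == "vocalisation":
        params.update(f0_base_hz=float(rng.uniform(250, 500)))
    elif kind == "alarm":
        params.update(
            freq_hz=float(rng.choice(ALARM_FREQS_HZ)),
            period_s=float(rng.uniform(0.6, 1.2)),
            duty=float(rng.uniform(0.4, 0.9)),
        )
    elif kind == "adult":
        params.update(f0_hz=float(rng.uniform(85, 255)))
    return params


def sequential_scene_spec(
    kinds: list[str], seed: int, gap_s: float = 0.8, snr_db: float = 30.0
) -> SceneSpec:
    """A scene with the given events laid out sequentially with fixed gaps."""
    rng = np.random.default_rng(seed)
    events, t = [], gap_s
    for kind in kinds:
        params = _event_params(kind, rng, snr_db)
        events.append(SceneEvent(onset_s=t, kind=kind, params=params))
        t += params["duration_s"] + gap_s
    return SceneSpec(duration_s=t + gap_s, events=events, seed=seed)


def gen_training_segments(
    n_cry: int = 40,
    n_per_other: int = 20,
    seed: int = 0,
    snr_db: float = 30.0,
    sample_rate_hz: int = SAMPLE_RATE_HZ,
) -> list[tuple[AudioRecording, str]]:
    """An annotated segment collection built the way the study database was.

    Events of every class are laid out in synthetic scenes, the energy
    segmenter is run on each scene, and the resulting segments are labelled
    by their overlap with the ground truth.  Training examples therefore
    have exactly the boundary statistics the classifier will see at
    deployment time (an alarm pulse train, for instance, yields one segment
    per pulse).  Cries span F0 250-600 Hz and the in-filter duration range.
    """
    from .segmentation import segment_recording  # local import avoids cycle at module load

    rng = np.random.default_rng(seed)
    kinds = (
        ["cry"] * n_cry
        + ["alarm"] * n_per_other
        + ["adult"] * n_per_other
        + ["background"] * n_per_other
    )
    order = rng.permutation(len(kinds))
    out: list[tuple[AudioRecording, str]] = []
    batch = 10  # events per scene keeps each scene short
    alarm_count = 0
    for b in range(0, len(kinds), batch):
        scene_kinds = [kinds[j] for j in order[b : b + batch]]
        spec = sequential_scene_spec(scene_kinds, seed=seed * 7919 + b, snr_db=snr_db)
        for ev in spec.events:  # guarantee coverage of every alarm frequency
            if ev.kind == "alarm":
                ev.params["freq_hz"] = ALARM_FREQS_HZ[alarm_count % len(ALARM_FREQS_HZ)]
                alarm_count += 1
        rec, truth = gen_scene(spec, sample_rate_hz)
        seg_result = segment_recording(rec)
        for i, seg in enumerate(seg_result.segments):
            label = _majority_label(seg, truth)
            if label is None:
                continue
            clip = rec.slice_time(seg.start_s, seg.end_s, segment_id=f"{rec.recording_id}_{i}")
            out.append((clip, label))
    return out


def _majority_label(seg, truth) -> str | None:
    """Label of the truth event covering most of a detected segment."""
    best, best_cov = None, 0.0
    for t in truth:
        cov = max(0.0, min(t.end_s, seg.end_s) - max(t.start_s, seg.start_s))
        if cov > best_cov:
            best, best_cov = t.label, cov
    if best is None or best_cov < 0.5 * seg.duration_s:
        return None
    return "cry" if best == "cry_overlap" else best


def benchmark_scene_spec(seed: int, duration_s: float = 60.0) -> SceneSpec:
    """A standard 60 s benchmark scene: 5 cries, 3 alarms, 2 noise bursts.

    Event onsets are drawn so that events do not overlap (segmentation then
    has an unambiguous ground truth) and are separated by at least 0.5 s.
    """
    rng = np.random.default_rng(seed)
    events = []
    kinds = ["cry"] * 5 + ["alarm"] * 3 + ["background"] * 2
    durations = []
    for kind in kinds:
        if kind == "cry":
            durations.append(float(rng.uniform(0.5, 3.0)))
        elif kind == "alarm":
            durations.append(float(rng.uniform(0.4, 1.5)))
        else:
            durations.append(float(rng.uniform(0.3, 1.5)))
    # lay events on a jittered grid with >= 0.5 s gaps
    total = sum(durations) + 0.5 * (len(kinds) + 1)
    slack = duration_s - total
    gaps = rng.dirichlet(np.ones(len(kinds) + 1)) * max(slack, 0.0)
    t = 0.0
    order = rng.permutation(len(kinds))
    for pos, j in enumerate(order):
        t += 0.5 + gaps[pos]
        kind = kinds[j]
        params: dict = {"duration_s": durations[j]}
        if kind == "cry":
            params.update(
                f0_base_hz=float(rng.uniform(250, 600)),
                vibrato_hz=float(rng.uniform(10, 30)),
                snr_db=30.0,
            )
        elif kind == "alarm":
            params.update(
                freq_hz=float(rng.choice(ALARM_FREQS_HZ)),
                duty=float(rng.uniform(0.5, 0.9)),
            )
        events.append(SceneEvent(onset_s=t, kind=kind, params=params))
        t += durations[j]
    return SceneSpec(duration_s=duration_s, events=events, seed=seed)
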