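"""Synthetic annotated ECG records and labelled beat datasets.

Every downstream stage (WFDB I/O, preprocessing, balancing, training,
evaluation) is testable without downloading real data.  Beats are modelled as
sums of Gaussian bumps for the P, Q, R, S and T deflections — the simplest
parametric model that produces the morphological contrasts that distinguish
the five AAMI classes:

* **N** — full P-QRS-T complex with a dominant R deflection.
* **S** — P amplitude reduced to 40 % of normal and a shortened RR interval
  (supraventricular beats differ from normal ones mainly in atrial activation
  and timing).
* **V** — QRS deflections three times wider, no P wave (ventricular beats have
  broad, bizarre QRS complexes without preceding atrial activity).
* **F** — the elementwise average of the N and V wave parameters (fusion of a
  normal and a ventricular depolarisation).
* **Q** — a systematically distorted template (widened low-amplitude QRS,
  inverted T, paced-beat-like) plus heavy-tailed Student-t noise
  (unclassifiable, distorted beats).

Records add sinusoidal baseline wander and Gaussian high-frequency noise so
the denoiser has realistic contaminants to remove.  This is deliberately *not*
a physiological simulator: see the methods note for what the generator does
and does not emulate.

All randomness flows through explicit integer seeds; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .preprocess import (SAMPLES_BEFORE_R, SEGMENT_LENGTH, BeatDataset,
                         zscore)
from .wfdb_io import CLASS_SYMBOLS, CLASSES, EcgRecord

#: Wave order inside ``wave_params``.
WAVES = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class BeatMorphology:
    """Parametric beat template: five (amplitude, center, width) Gaussians.

    Amplitudes in mV, centers in seconds relative to the R peak, widths
    (Gaussian SDs) in seconds.  ``distortion_sd`` adds heavy-tailed Student-t
    noise (used by the Q class).
    """

    class_label: str
    wave_params: tuple[tuple[float, float, float], ...]
    rr_interval_mean: float = 0.8
    rr_interval_jitter: float = 0.05
    distortion_sd: float = 0.0

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise ValueError(f"invalid beat class label {self.class_label!r}")
        if len(self.wave_params) != len(WAVES):
            raise ValueError(f"expected {len(WAVES)} wave triples (P,Q,R,S,T)")
        for amp, _center, width in self.wave_params:
            if width <= 0:
                raise ValueError("wave widths must be positive")
        if self.rr_interval_mean <= 0:
            raise ValueError("rr_interval_mean must be positive")
        r_amp = abs(self.wave_params[WAVES.index("R")][0])
        others = [abs(a) for i, (a, _c, _w) in enumerate(self.wave_params)
                  if WAVES[i] != "R"]
        if any(a >= r_amp for a in others):
            raise ValueError("R must be the single dominant deflection")


@dataclass(frozen=True)
class NoiseModel:
    """Record-level contaminants: baseline wander and high-frequency noise."""

    baseline_wander_amplitude: float = 0.1   # mV
    baseline_wander_freq: float = 0.25       # Hz, must stay below 1 Hz
    hf_noise_sd: float = 0.02                # mV
    seed: int = 0

    def __post_init__(self):
        if self.baseline_wander_amplitude < 0 or self.hf_noise_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if not 0 <= self.baseline_wander_freq < 1.0:
            raise ValueError("baseline wander frequency must be below 1 Hz")


def default_morphologies() -> dict[str, BeatMorphology]:
    """The five class templates used throughout the package."""
    n_waves = (
        (0.15, -0.20, 0.025),   # P
        (-0.10, -0.030, 0.010),  # Q
        (1.00, 0.0, 0.012),      # R
        (-0.25, 0.030, 0.010),   # S
        (0.35, 0.25, 0.060),     # T
    )
    n = BeatMorphology("N", n_waves, rr_interval_mean=0.80)
    # S: P amplitude x0.4, shortened preceding RR
    s_waves = ((0.15 * 0.4, -0.20, 0.025),) + n_waves[1:]
    s = BeatMorphology("S", s_waves, rr_interval_mean=0.55,
                       rr_interval_jitter=0.04)
    # V: QRS widths x3, centers spread accordingly, no P wave
    v_waves = (
        (0.0, -0.20, 0.025),
        (-0.10, -0.090, 0.030),
        (1.00, 0.0, 0.036),
        (-0.25, 0.090, 0.030),
        (0.35, 0.28, 0.060),
    )
    v = BeatMorphology("V", v_waves, rr_interval_mean=0.80)
    # F: midpoint of the N and V templates
    f_waves = tuple(
        tuple(0.5 * (a + b) for a, b in zip(wn, wv))
        for wn, wv in zip(n_waves, v_waves))
    f = BeatMorphology("F", f_waves, rr_interval_mean=0.80)
    # Q: systematically distorted beat (paced-like widened low QRS, inverted
    # T) plus heavy-tailed noise.  Independent noise alone cannot make a
    # class nearest-neighbour-separable from the clean template it wraps, so
    # the distortion must live in the template itself.
    q_waves = (
        (0.05, -0.20, 0.025),
        (-0.10, -0.060, 0.020),
        (0.85, 0.0, 0.024),
        (-0.25, 0.060, 0.020),
        (-0.30, 0.25, 0.060),
    )
    q = BeatMorphology("Q", q_waves, rr_interval_mean=0.80,
                       rr_interval_jitter=0.08, distortion_sd=0.15)
    return {"N": n, "S": s, "V": v, "F": f, "Q": q}


def _bumps(t: np.ndarray, wave_params) -> np.ndarray:
    """Sum of Gaussian deflections evaluated at times ``t`` (s, R at 0)."""
    out = np.zeros_like(t)
    for amp, center, width in wave_params:
        if amp == 0.0:
            continue
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def _heavy_tail_noise(rng: np.random.Generator, n: int,
                      rms: float) -> np.ndarray:
    """Student-t (df=2) noise rescaled to a fixed realised RMS.

    Raw heavy-tail draws vary wildly in power; pinning the RMS guarantees
    every distorted (Q-class) window actually looks distorted rather than
    occasionally indistinguishable from a clean beat.
    """
    draw = rng.standard_t(df=2, size=n)
    return draw * (rms / max(np.sqrt(np.mean(draw ** 2)), 1e-12))


def _jitter_morphology(morph: BeatMorphology,
                       rng: np.random.Generator,
                       amp_sd: float = 0.08,
                       center_sd: float = 0.004,
                       width_sd: float = 0.08) -> BeatMorphology:
    """Small per-beat variation of the template parameters."""
    waves = []
    for amp, center, width in morph.wave_params:
        waves.append((
            amp * (1.0 + amp_sd * rng.standard_normal()),
            center + center_sd * rng.standard_normal(),
            max(width * (1.0 + width_sd * rng.standard_normal()), 1e-3),
        ))
    try:
        return replace(morph, wave_params=tuple(waves))
    except ValueError:
        return morph  # jitter broke an invariant; keep the clean template


def generate_beat(morph: BeatMorphology, fs: float, rng_seed: int) -> np.ndarray:
    """One isolated beat: ``round(1.5 * fs)`` samples centered on the R peak.

    Deterministic given the seed (the seed matters only for classes with
    ``distortion_sd > 0``, e.g. Q).
    """
    if fs not in (360, 125):
        raise ValueError(f"fs must be 360 or 125 Hz, got {fs!r}")
    length = round(1.5 * fs)
    t = (np.arange(length) - length // 2) / fs
    out = _bumps(t, morph.wave_params)
    if morph.distortion_sd > 0:
        rng = np.random.default_rng(rng_seed)
        out = out + _heavy_tail_noise(rng, length, morph.distortion_sd)
    return out


def generate_record(n_beats: int,
                    class_probs,
                    fs: float = 360,
                    noise: NoiseModel = NoiseModel(),
                    rng_seed: int = 0,
                    record_id: str = "synth",
                    morphologies: dict[str, BeatMorphology] | None = None,
                    ) -> EcgRecord:
    """A synthetic annotated single-lead record emulating an MIT-BIH trace.

    Beat classes are drawn i.i.d. from ``class_probs`` (ordered N, S, V, F, Q);
    annotation symbols are drawn from the MIT-BIH symbols of the drawn class.
    RR intervals follow each class's mean/jitter.  Baseline wander and
    high-frequency noise come from ``noise`` (seeded separately so the same
    beat sequence can be rendered at different noise levels).
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    class_probs = np.asarray(class_probs, dtype=float)
    if class_probs.shape != (5,) or np.any(class_probs < 0) or \
            abs(class_probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_probs must be 5 non-negative values summing to 1")
    morphologies = morphologies or default_morphologies()
    rng = np.random.default_rng(rng_seed)
    noise_rng = np.random.default_rng(noise.seed)

    classes = rng.choice(len(CLASSES), size=n_beats, p=class_probs)
    labels = [CLASSES[k] for k in classes]
    # R-peak times: generous margins so interior beats survive segmentation
    r_times = []
    t_cursor = 0.8
    for lbl in labels:
        m = morphologies[lbl]
        r_times.append(t_cursor)
        rr = max(0.3, m.rr_interval_mean + m.rr_interval_jitter
                 * rng.standard_normal())
        t_cursor += rr
    duration = r_times[-1] + 0.8
    n_samples = int(math.ceil(duration * fs))
    t = np.arange(n_samples) / fs

    signal = np.zeros(n_samples)
    annotations: list[tuple[int, str]] = []
    for r_time, lbl in zip(r_times, labels):
        m = _jitter_morphology(morphologies[lbl], rng)
        lo = max(0, int((r_time - 0.75) * fs))
        hi = min(n_samples, int((r_time + 0.75) * fs) + 1)
        signal[lo:hi] += _bumps(t[lo:hi] - r_time, m.wave_params)
        if m.distortion_sd > 0:
            signal[lo:hi] += _heavy_tail_noise(rng, hi - lo, m.distortion_sd)
        annotations.append((int(round(r_time * fs)),
                            str(rng.choice(CLASS_SYMBOLS[lbl]))))
    if noise.baseline_wander_amplitude > 0 and noise.baseline_wander_freq > 0:
        phase = noise_rng.uniform(0, 2 * np.pi)
        signal += noise.baseline_wander_amplitude * np.sin(
            2 * np.pi * noise.baseline_wander_freq * t + phase)
    if noise.hf_noise_sd > 0:
        signal += noise.hf_noise_sd * noise_rng.standard_normal(n_samples)
    return EcgRecord(samples=signal, fs=fs, lead_name="MLII",
                     annotations=annotations, record_id=record_id)


def generate_dataset(n_per_class: int, rng_seed: int = 0,
                     hf_noise_sd: float = 0.02,
                     morphologies: dict[str, BeatMorphology] | None = None,
                     ) -> BeatDataset:
    """A labelled, z-scored beat dataset: ``5 * n_per_class`` windows of 188.

    Each window is rendered directly on the 125 Hz grid with the R peak at
    offset 90 and includes the tails of the previous and next beat at the
    class's RR interval, so timing cues (e.g. the shortened RR of S beats)
    are visible inside the window.  Per-beat template jitter plus Gaussian
    noise keeps classes internally variable yet separable by construction.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    fs = 125.0
    morphologies = morphologies or default_morphologies()
    rng = np.random.default_rng(rng_seed)
    t = (np.arange(SEGMENT_LENGTH) - SAMPLES_BEFORE_R) / fs

    beats, labels = [], []
    for lbl in CLASSES:
        template = morphologies[lbl]
        for _ in range(n_per_class):
            m = _jitter_morphology(template, rng)
            window = _bumps(t, m.wave_params)
            # neighbouring beats at +-RR make interval cues visible
            rr_prev = max(0.3, template.rr_interval_mean
                          + template.rr_interval_jitter * rng.standard_normal())
            rr_next = max(0.3, template.rr_interval_mean
                          + template.rr_interval_jitter * rng.standard_normal())
            window += _bumps(t + rr_prev, m.wave_params)
            window += _bumps(t - rr_next, m.wave_params)
            if m.distortion_sd > 0:
                window += _heavy_tail_noise(rng, SEGMENT_LENGTH,
                                            m.distortion_sd)
            if hf_noise_sd > 0:
                window += hf_noise_sd * rng.standard_normal(SEGMENT_LENGTH)
            beats.append(zscore(window))
            labels.append(lbl)
    beats = np.asarray(beats, dtype=np.float32)
    labels = np.asarray(labels, dtype="U1")
    order = rng.permutation(len(labels))
    return BeatDataset(beats[order], labels[order],
                       [{"step": "synth_dataset", "n_per_class": n_per_class,
                         "seed": rng_seed, "hf_noise_sd": hf_noise_sd,
                         "fs": fs}])
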