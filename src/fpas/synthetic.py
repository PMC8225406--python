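"""Synthetic EEG, audio, and behavioural data with recorded ground truth.

Every stage of the analysis can be exercised against data whose true
structure is known: steady-state EEG epochs containing periodic responses at
a base rate and an oddball (target) rate with chosen harmonic amplitudes and
scalp topographies, embedded in 1/f-shaped plus alpha-band Gaussian noise;
vocal-like versus non-vocal sound corpora (with a matched variant whose
fundamental-frequency and harmonics-to-noise-ratio distributions coincide by
construction); and yes/no observers following the equal-variance Gaussian
signal-detection model.

All generators are deterministic per seed and return their ground truth
alongside the data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .behavior import TrialSet
from .layout import biosemi128_layout
from .preprocess import Epoch
from .stimgen import AudioClip

_RAYLEIGH_MEAN = np.sqrt(np.pi) / 2  # E|CN(0,1)| per unit-variance complex normal


def _target_harmonic_freqs(
    base: float, target: float, n: int, tol: float = 1e-9
) -> list[float]:
    """First ``n`` harmonics of the target rate that do not coincide with a
    base-rate multiple (those belong to the base response)."""
    out: list[float] = []
    k = 0
    while len(out) < n:
        k += 1
        f = k * target
        m = round(f / base)
        if m >= 1 and abs(f - m * base) <= tol * max(1.0, f):
            continue
        out.append(f)
    return out


@dataclass
class SSEPGroundTruth:
    """True structure of one condition's steady-state response.

    Harmonic amplitudes are in microvolts at the topography maximum; the
    target amplitudes apply to successive target-rate harmonics that do not
    overlap base-rate multiples (for 4 Hz / 1.333 Hz these are 1.333, 2.667,
    5.333, 6.667 Hz).  Noise: per-channel Gaussian noise whose single-epoch
    amplitude-spectrum floor is ``noise_scale * f^-noise_exponent``
    microvolts (clamped below 0.5 Hz), plus flat extra noise of amplitude
    ``alpha_amp`` inside ``alpha_band``.
    """

    base_freq: float = 4.0
    target_freq: float | None = None  # default: base_freq / 3
    base_harmonic_amps: tuple[float, ...] = (1.0, 0.5)
    target_harmonic_amps: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    base_topography: np.ndarray | None = None
    target_topography: np.ndarray | None = None
    noise_exponent: float = 0.7
    noise_scale: float = 0.025
    alpha_amp: float = 0.05
    alpha_band: tuple[float, float] = (8.0, 13.0)
    ch_names: list[str] = field(default_factory=lambda: list(biosemi128_layout()))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_freq is None:
            self.target_freq = self.base_freq / 3.0
        if any(a < 0 for a in self.base_harmonic_amps + self.target_harmonic_amps):
            raise ValueError("harmonic amplitudes must be >= 0")
        n_ch = len(self.ch_names)
        if self.base_topography is None:
            self.base_topography = default_base_topography(self.ch_names)
        if self.target_topography is None:
            self.target_topography = default_target_topography(self.ch_names)
        self.base_topography = np.asarray(self.base_topography, dtype=float)
        self.target_topography = np.asarray(self.target_topography, dtype=float)
        if self.base_topography.shape != (n_ch,) or self.target_topography.shape != (n_ch,):
            raise ValueError("topography must have one weight per channel")
        if not (np.isfinite(self.base_topography).all()
                and np.isfinite(self.target_topography).all()):
            raise ValueError("topography weights must be finite")

    @property
    def base_harmonic_freqs(self) -> list[float]:
        return [(k + 1) * self.base_freq for k in range(len(self.base_harmonic_amps))]

    @property
    def target_harmonic_freqs(self) -> list[float]:
        return _target_harmonic_freqs(
            self.base_freq, self.target_freq, len(self.target_harmonic_amps)
        )

    def replace(self, **kw) -> "SSEPGroundTruth":
        return dataclasses.replace(self, **kw)


def default_target_topography(ch_names: list[str]) -> np.ndarray:
    """Focal right superior-temporal topography: weight 1 on the four
    voice-ROI electrodes, 0 elsewhere."""
    roi = {"TP8h", "CP6", "C6", "T8"}
    return np.array([1.0 if c in roi else 0.0 for c in ch_names])


def default_base_topography(ch_names: list[str]) -> np.ndarray:
    """Broad centro-occipital topography (Gaussian falloff on the sphere
    from the midpoint of Cz and Oz)."""
    layout = biosemi128_layout()
    centre = layout["Cz"] + layout["Oz"]
    centre = centre / np.linalg.norm(centre)
    w = np.empty(len(ch_names))
    for i, c in enumerate(ch_names):
        p = layout.get(c)
        if p is None:
            w[i] = 0.0
            continue
        w[i] = np.exp(-(np.linalg.norm(p - centre) ** 2) / (2 * 0.55**2))
    return w


def _component_phases(gt: SSEPGroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-harmonic phases shared by all epochs of a condition
    (the phase-locked part of the response)."""
    rng = np.random.default_rng(gt.seed)
    return (
        rng.uniform(0, 2 * np.pi, len(gt.base_harmonic_amps)),
        rng.uniform(0, 2 * np.pi, len(gt.target_harmonic_amps)),
    )


def noise_amplitude_profile(gt: SSEPGroundTruth, freqs: np.ndarray) -> np.ndarray:
    """Expected single-epoch amplitude-spectrum noise floor per frequency."""
    f = np.maximum(freqs, 0.5)  # clamp the 1/f divergence
    prof = gt.noise_scale * f ** (-gt.noise_exponent)
    prof = prof + gt.alpha_amp * (
        (freqs >= gt.alpha_band[0]) & (freqs <= gt.alpha_band[1])
    )
    prof[freqs == 0] = 0.0
    return prof


def simulate_epoch(
    gt: SSEPGroundTruth,
    duration: float = 60.0,
    rate: float = 256.0,
    epoch_seed: int = 0,
    amplitude_scale: float = 1.0,
    n_average: int = 1,
) -> Epoch:
    """One epoch: phase-locked harmonic responses (identical across epochs
    of a condition) plus independent spectrally shaped Gaussian noise.

    ``duration`` must hold an integer number of target cycles so the
    responses fall exactly on FFT bins.  With ``n_average`` > 1 the epoch is
    the time-domain (coherent) average of that many independent epochs —
    because the noise is complex Gaussian in the frequency domain, drawing
    one epoch at noise amplitude / sqrt(n_average) is exactly equivalent in
    distribution, and much cheaper.
    """
    n = int(round(duration * rate))
    n_cycles = duration * gt.target_freq
    if abs(n_cycles - round(n_cycles)) > 1e-6:
        raise ValueError("duration must be an integer number of target cycles")
    t = np.arange(n) / rate
    base_ph, targ_ph = _component_phases(gt)

    signal = np.zeros(n)
    sig_t = np.zeros(n)
    for amp, f, ph in zip(gt.base_harmonic_amps, gt.base_harmonic_freqs, base_ph):
        signal += amp * np.sin(2 * np.pi * f * t + ph)
    for amp, f, ph in zip(gt.target_harmonic_amps, gt.target_harmonic_freqs, targ_ph):
        sig_t += amp * np.sin(2 * np.pi * f * t + ph)
    data = amplitude_scale * (
        np.outer(gt.base_topography, signal) + np.outer(gt.target_topography, sig_t)
    )

    if gt.noise_scale > 0 or gt.alpha_amp > 0:
        rng = np.random.default_rng(epoch_seed)
        freqs = np.fft.rfftfreq(n, 1.0 / rate)
        prof = noise_amplitude_profile(gt, freqs)
        n_ch = len(gt.ch_names)
        g = rng.standard_normal((n_ch, len(freqs))) + 1j * rng.standard_normal(
            (n_ch, len(freqs))
        )
        # scaled so the expected single-sided amplitude per bin equals prof
        spec = g / np.sqrt(2) / _RAYLEIGH_MEAN * (prof / np.sqrt(n_average)) * (n / 2)
        spec[:, 0] = 0.0
        if n % 2 == 0:
            spec[:, -1] = spec[:, -1].real
        data = data + np.fft.irfft(spec, n=n, axis=1)

    return Epoch(data=data, rate=rate, ch_names=list(gt.ch_names), t0=0.0)


@dataclass
class SyntheticCohortSpec:
    """A cohort of subjects measured in one or more conditions.

    Per-subject response amplitudes are jittered multiplicatively
    (Gaussian, SD ``amp_jitter_sd``, floored at 0); per-subject response
    phases are redrawn when ``phase_jitter`` is true.  ``subject_scale``
    optionally fixes each subject's amplitude scale (overriding the jitter),
    e.g. to give some subjects no response at all.
    """

    conditions: dict[str, SSEPGroundTruth] = field(default_factory=dict)
    n_subjects: int = 16
    n_epochs: int = 4
    amp_jitter_sd: float = 0.2
    phase_jitter: bool = True
    subject_scale: dict[str, np.ndarray] | None = None
    duration: float = 60.0
    rate: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need >= 2 subjects")
        if not self.conditions:
            self.conditions = {"standard": SSEPGroundTruth(seed=self.seed)}


@dataclass
class CohortLedger:
    """Ground truth for recovery scoring: per-condition harmonic frequencies
    and per-subject amplitude scales."""

    conditions: dict[str, SSEPGroundTruth]
    subject_scale: dict[str, np.ndarray]  # condition -> (n_subjects,)

    def true_target_sum(self, condition: str, topo_weight: float = 1.0) -> float:
        """Cohort-mean total target amplitude at a site of the given
        topography weight (the quantity harmonic summation recovers)."""
        gt = self.conditions[condition]
        return float(
            sum(gt.target_harmonic_amps)
            * topo_weight
            * self.subject_scale[condition].mean()
        )


def cohort_subject_epochs(
    spec: SyntheticCohortSpec, condition: str, subject: int,
    scale: float,
) -> list[Epoch]:
    """The epochs of one subject in one condition (deterministic)."""
    gt = spec.conditions[condition]
    cond_idx = sorted(spec.conditions).index(condition)
    if spec.phase_jitter:
        ss = np.random.SeedSequence([spec.seed, cond_idx, subject, 7])
        gt = gt.replace(seed=int(ss.generate_state(1)[0] >> 1))
    epochs = []
    for e in range(spec.n_epochs):
        es = np.random.SeedSequence([spec.seed, cond_idx, subject, e])
        epochs.append(
            simulate_epoch(
                gt, spec.duration, spec.rate,
                epoch_seed=int(es.generate_state(1)[0] >> 1),
                amplitude_scale=scale,
            )
        )
    return epochs


def simulate_subject_average(
    spec: SyntheticCohortSpec, condition: str, subject: int, scale: float
) -> Epoch:
    """The subject's time-domain average over ``n_epochs`` epochs, drawn
    directly (noise amplitude / sqrt(n_epochs)); distributionally identical
    to averaging :func:`cohort_subject_epochs` output but much cheaper."""
    gt = spec.conditions[condition]
    cond_idx = sorted(spec.conditions).index(condition)
    if spec.phase_jitter:
        ss = np.random.SeedSequence([spec.seed, cond_idx, subject, 7])
        gt = gt.replace(seed=int(ss.generate_state(1)[0] >> 1))
    es = np.random.SeedSequence([spec.seed, cond_idx, subject, 0])
    return simulate_epoch(
        gt, spec.duration, spec.rate,
        epoch_seed=int(es.generate_state(1)[0] >> 1),
        amplitude_scale=scale, n_average=spec.n_epochs,
    )


def simulate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[dict[str, list[list[Epoch]]], CohortLedger]:
    """All epochs of all subjects: ``data[condition][subject]`` is a list of
    epochs.  Prefer :func:`iter_cohort` for large cohorts."""
    ledger = cohort_ledger(spec)
    data = {
        cond: [
            cohort_subject_epochs(spec, cond, s, float(ledger.subject_scale[cond][s]))
            for s in range(spec.n_subjects)
        ]
        for cond in spec.conditions
    }
    return data, ledger


def cohort_ledger(spec: SyntheticCohortSpec) -> CohortLedger:
    """Draw (or copy) the per-subject amplitude scales; the ground truth of
    the cohort."""
    scales: dict[str, np.ndarray] = {}
    for ci, cond in enumerate(sorted(spec.conditions)):
        if spec.subject_scale is not None and cond in spec.subject_scale:
            s = np.asarray(spec.subject_scale[cond], dtype=float)
            if s.shape != (spec.n_subjects,):
                raise ValueError("subject_scale must have one entry per subject")
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, ci, 13]).generate_state(1)[0] >> 1
            )
            s = np.maximum(rng.normal(1.0, spec.amp_jitter_sd, spec.n_subjects), 0.0)
        scales[cond] = s
    return CohortLedger(conditions=dict(spec.conditions), subject_scale=scales)


def iter_cohort(spec: SyntheticCohortSpec):
    """Yield ``(condition, subject, scale, epochs)`` lazily (memory-friendly
    for full-size cohorts)."""
    ledger = cohort_ledger(spec)
    for cond in sorted(spec.conditions):
        for s in range(spec.n_subjects):
            scale = float(ledger.subject_scale[cond][s])
            yield cond, s, scale, cohort_subject_epochs(spec, cond, s, scale)


# --------------------------------------------------------------------------
# audio corpora
# --------------------------------------------------------------------------

def _formant_gain(freqs: np.ndarray, formants, bws, tilt_db_oct: float) -> np.ndarray:
    gain = np.zeros_like(freqs, dtype=float)
    for fc, bw in zip(formants, bws):
        gain += 1.0 / (1.0 + ((freqs - fc) / (bw / 2)) ** 2)
    tilt = 10 ** (tilt_db_oct * np.log2(np.maximum(freqs, 100.0) / 100.0) / 20)
    return gain * tilt


def _harmonic_tone(
    rng: np.random.Generator,
    f0: float,
    duration: float,
    rate: float,
    envelope: str,
    hnr_db: float,
    jitter: float = 0.0,
) -> np.ndarray:
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    freqs = np.arange(1, int(5000 / f0) + 1) * f0
    if envelope == "formant":
        gains = _formant_gain(freqs, (500, 1500, 2500), (100, 180, 300), -6.0)
    else:  # smooth low-pass instrument-like envelope
        gains = 1.0 / (1 + (freqs / 1200.0) ** 2)
    for f, g in zip(freqs, gains):
        f_j = f * (1 + jitter * rng.standard_normal())
        x += g * np.sin(2 * np.pi * f_j * t + rng.uniform(0, 2 * np.pi))
    p_harm = np.mean(x**2)
    rho = 10 ** (hnr_db / 10)
    noise = rng.standard_normal(n)
    noise *= np.sqrt(p_harm / rho / np.mean(noise**2))
    return x + noise


def _inharmonic_cluster(
    rng: np.random.Generator, duration: float, rate: float
) -> np.ndarray:
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    for _ in range(rng.integers(6, 12)):
        f = rng.uniform(300, 6000)
        x += rng.uniform(0.2, 1.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    # band-passed noise component
    noise = rng.standard_normal(n)
    x += 0.8 * noise / np.std(noise) * np.std(x)
    return x


def simulate_audio_corpus(
    n_vocal: int,
    n_nonvocal: int,
    matched: bool = False,
    duration: float = 0.25,
    rate: float = 48000.0,
    seed: int = 0,
) -> list[AudioClip]:
    """A labelled corpus of short clips.

    Vocal clips are harmonic complexes (f0 ~ N(220, 7^2) Hz) with
    formant-shaped spectra, slight frequency jitter, and noise set so the
    harmonics-to-noise ratio is ~N(21, 2.5^2) dB.  Non-vocal clips are
    inharmonic tone clusters over noise (unmatched) or instrument-like
    harmonic tones drawn from the same f0 and HNR distributions (matched),
    so that matched corpora differ in timbre but not in pitch or
    harmonicity.  All clips are RMS-equalised to 0.1.
    """
    rng = np.random.default_rng(seed)
    clips: list[AudioClip] = []
    for i in range(n_vocal):
        f0 = rng.normal(220.0, 7.0)
        hnr = rng.normal(21.0, 2.5)
        x = _harmonic_tone(rng, f0, duration, rate, "formant", hnr, jitter=0.0008)
        clips.append(AudioClip(x, rate, "vocal", f"voc{i:03d}"))
    for i in range(n_nonvocal):
        if matched:
            f0 = rng.normal(220.0, 7.0)
            hnr = rng.normal(21.0, 2.5)
            x = _harmonic_tone(rng, f0, duration, rate, "instrument", hnr)
        else:
            x = _inharmonic_cluster(rng, duration, rate)
        clips.append(AudioClip(x, rate, "nonvocal", f"non{i:03d}"))
    out = []
    for c in clips:
        out.append(c.replace(c.samples * (0.1 / c.rms())))
    return out


# --------------------------------------------------------------------------
# observers
# --------------------------------------------------------------------------

def simulate_observer(
    true_dprime: float,
    criterion: float,
    trials: TrialSet,
    seed: int = 0,
) -> list[bool]:
    """Equal-variance Gaussian observer: evidence ~ N(d', 1) on voice trials
    and N(0, 1) otherwise; respond yes above d'/2 + criterion."""
    rng = np.random.default_rng(seed)
    lam = true_dprime / 2 + criterion
    out = []
    for t in trials.trials:
        ev = rng.standard_normal() + (true_dprime if t.voice_present else 0.0)
        out.append(bool(ev > lam))
    return out
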