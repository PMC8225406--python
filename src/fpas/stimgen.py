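"""Auditory stimulus engineering for fast periodic (oddball) stimulation.

Builds the three ingredients of an FPAS experiment: RMS-equalised, ramped
short sound clips; frequency-bin scrambled controls that keep the long-term
spectrum of a sound while destroying its harmonic structure; and periodic
stimulation sequences in which every ``oddball_period``-th sound belongs to
the tagged category (voices), so that category-selective brain responses are
forced onto a known frequency (base rate / oddball period).

Also provides the acoustic descriptors (pitch, harmonics-to-noise ratio,
spectral centre of gravity) used to build matched vocal / non-vocal corpora.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class AudioClip:
    """A mono sound clip in arbitrary (linear) amplitude units."""

    samples: np.ndarray
    rate: float
    category: str | None = None  # "vocal" | "nonvocal"
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip is mono: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioClip samples must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def replace(self, samples: np.ndarray, **kw) -> "AudioClip":
        return dataclasses.replace(self, samples=samples, **kw)


@dataclass
class ScrambleConfig:
    """Parameters of frequency-bin scrambling.

    bin_width
        Width in Hz of the spectral windows within which Fourier component
        magnitudes and phases are shuffled (default 200 Hz).
    envelope_cutoff
        Low-pass cutoff (Hz) of the temporal-envelope extractor used when
        re-imposing the original envelope on the scrambled waveform.
    """

    bin_width: float = 200.0
    seed: int = 0
    envelope_cutoff: float = 50.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@dataclass
class SequenceSpec:
    """Layout of one stimulation sequence.

    The stimulus-onset asynchrony equals the clip duration, so the base
    stimulation rate is 1/soa and the oddball (target) rate is
    1/(soa * oddball_period).
    """

    soa: float = 0.250
    oddball_period: int = 3
    total_duration: float = 64.0
    fade_duration: float = 2.0
    n_attentional_targets: int = 6
    attenuation_factor: float = 12.5
    target_min_spacing: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.oddball_period < 2:
            raise ValueError("oddball_period must be >= 2")
        if self.fade_duration < 0:
            raise ValueError("fade_duration must be >= 0")
        if self.total_duration <= 2 * self.fade_duration:
            raise ValueError("total_duration must exceed both fades")

    @property
    def base_freq(self) -> float:
        return 1.0 / self.soa

    @property
    def target_freq(self) -> float:
        return self.base_freq / self.oddball_period

    @property
    def n_slots(self) -> int:
        n = self.total_duration / self.soa
        if abs(n - round(n)) > 1e-9:
            raise ValueError("total_duration must be a multiple of soa")
        return int(round(n))


@dataclass
class SequenceEvent:
    onset: float
    stimulus_id: str
    category: str
    is_target: bool


@dataclass
class StimulusSequence:
    waveform: np.ndarray
    rate: float
    events: list[SequenceEvent]
    base_freq: float
    target_freq: float


@dataclass
class PitchResult:
    f0: float  # Hz; nan when unvoiced
    strength: float  # normalised autocorrelation at the pitch lag
    voiced: bool


@dataclass
class AcousticProfile:
    pitch: float
    hnr: float
    spectral_cog: float


# --------------------------------------------------------------------------
# clip-level operations
# --------------------------------------------------------------------------

def rms_equalize(clip: AudioClip, target_rms: float) -> AudioClip:
    """Scale a clip so its root-mean-square amplitude equals ``target_rms``."""
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    r = clip.rms()
    if r == 0:
        raise ValueError("cannot equalise an all-zero clip")
    return clip.replace(clip.samples * (target_rms / r))


def attenuate_target(clip: AudioClip, factor: float) -> AudioClip:
    """Divide the clip's RMS by ``factor`` (volume drop for attentional targets)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return clip.replace(clip.samples / factor)


def apply_ramps(clip: AudioClip, ramp: float) -> AudioClip:
    """Fade a clip in and out with linear amplitude ramps of ``ramp`` seconds."""
    if ramp < 0:
        raise ValueError("ramp must be >= 0")
    n_ramp = int(round(ramp * clip.rate))
    if 2 * n_ramp > clip.n_samples:
        raise ValueError("ramps longer than the clip")
    if n_ramp == 0:
        return clip.replace(clip.samples.copy())
    env = np.ones(clip.n_samples)
    up = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
    env[:n_ramp] = up
    env[-n_ramp:] = up[::-1]
    return clip.replace(clip.samples * env)


def extract_envelope(clip: AudioClip, cutoff: float = 50.0) -> np.ndarray:
    """Smooth amplitude envelope: |analytic signal| low-passed at ``cutoff`` Hz."""
    if cutoff >= clip.rate / 2:
        raise ValueError("cutoff must be below Nyquist")
    mag = np.abs(sps.hilbert(clip.samples))
    sos = sps.butter(4, cutoff, btype="low", fs=clip.rate, output="sos")
    env = sps.sosfiltfilt(sos, mag)
    return np.maximum(env, 0.0)


def _bin_slices(freqs: np.ndarray, bin_width: float, n: int) -> list[np.ndarray]:
    """Index groups of positive-frequency rFFT components per spectral bin.

    DC (index 0) and the Nyquist component (last index for even n) are left
    out: they carry no phase freedom for a real signal.
    """
    idx = np.arange(1, len(freqs) - 1 if n % 2 == 0 else len(freqs))
    labels = np.floor(freqs[idx] / bin_width).astype(int)
    return [idx[labels == b] for b in np.unique(labels)]


def scramble_frequency_bins(
    clip: AudioClip,
    config: ScrambleConfig,
    apply_envelope: bool = True,
) -> AudioClip:
    """Shuffle Fourier magnitudes and phases within fixed-width frequency bins.

    Magnitudes and phases are permuted independently within each bin
    (positive frequencies only; conjugate symmetry is restored by the inverse
    real FFT), which preserves the per-bin power of the sound exactly while
    destroying harmonic structure. With ``apply_envelope`` the original
    temporal envelope is re-imposed and the RMS re-equalised to the input.
    """
    if config.bin_width >= clip.rate / 2:
        raise ValueError("bin_width must be below the Nyquist frequency")
    if clip.duration * config.bin_width < 2:
        raise ValueError("clip too short: need >= 2 Fourier components per bin")

    rng = np.random.default_rng(config.seed)
    x = clip.samples
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / clip.rate)
    mag = np.abs(spec)
    phase = np.angle(spec)
    for ids in _bin_slices(freqs, config.bin_width, len(x)):
        if len(ids) < 2:
            continue
        mag[ids] = mag[rng.permutation(ids)]
        phase[ids] = phase[rng.permutation(ids)]
    scrambled = np.fft.irfft(mag * np.exp(1j * phase), n=len(x))

    if not apply_envelope:
        return clip.replace(scrambled)

    env_orig = extract_envelope(clip, config.envelope_cutoff)
    env_scr = extract_envelope(clip.replace(scrambled), config.envelope_cutoff)
    floor = 1e-3 * max(float(env_scr.max()), np.finfo(float).tiny)
    shaped = scrambled * env_orig / np.maximum(env_scr, floor)
    out = clip.replace(shaped)
    r = clip.rms()
    return rms_equalize(out, r) if r > 0 else out


# --------------------------------------------------------------------------
# sequence assembly
# --------------------------------------------------------------------------

def _pick_targets(spec: SequenceSpec, rng: np.random.Generator) -> set[int]:
    """Attentional-target slots: outside fades, pairwise spacing >= 2 s."""
    onsets = np.arange(spec.n_slots) * spec.soa
    ok = (onsets >= spec.fade_duration) & (
        onsets + spec.soa <= spec.total_duration - spec.fade_duration
    )
    candidates = np.flatnonzero(ok)
    min_gap = spec.target_min_spacing / spec.soa
    for _ in range(10000):
        chosen = np.sort(rng.choice(candidates, spec.n_attentional_targets, replace=False))
        if np.all(np.diff(chosen) >= min_gap):
            return set(int(i) for i in chosen)
    raise RuntimeError("could not place attentional targets with required spacing")


def build_sequence(
    vocal: Sequence[AudioClip],
    nonvocal: Sequence[AudioClip],
    spec: SequenceSpec,
) -> StimulusSequence:
    """Concatenate clips into a periodic sequence with oddball structure.

    Every slot whose 0-based index is ``oddball_period - 1`` modulo
    ``oddball_period`` receives a vocal clip; all other slots receive
    non-vocal clips sampled without immediate exemplar repetition.
    ``n_attentional_targets`` slots outside the fade windows play at RMS
    reduced by ``attenuation_factor``. A linear volume ramp of
    ``fade_duration`` is applied to the summed waveform at both ends.
    """
    if not vocal or not nonvocal:
        raise ValueError("need at least one clip per category")
    rate = vocal[0].rate
    for c in list(vocal) + list(nonvocal):
        if c.rate != rate:
            raise ValueError("all clips must share one sample rate")
        if abs(c.duration - spec.soa) * rate > 0.5:
            raise ValueError(
                f"clip {c.id!r} duration {c.duration:.4f}s does not equal soa {spec.soa}s"
            )

    rng = np.random.default_rng(spec.seed)
    n_slots = spec.n_slots
    n_clip = int(round(spec.soa * rate))
    targets = _pick_targets(spec, rng)

    waveform = np.zeros(n_slots * n_clip)
    events: list[SequenceEvent] = []
    prev_nonvocal = -1
    for i in range(n_slots):
        is_vocal = (i % spec.oddball_period) == spec.oddball_period - 1
        if is_vocal:
            j = int(rng.integers(len(vocal)))
            clip = vocal[j]
        else:
            # avoid immediate repetition of the same non-vocal exemplar
            while True:
                j = int(rng.integers(len(nonvocal)))
                if j != prev_nonvocal or len(nonvocal) == 1:
                    break
            prev_nonvocal = j
            clip = nonvocal[j]
        samples = clip.samples[:n_clip]
        if i in targets:
            samples = samples / spec.attenuation_factor
        waveform[i * n_clip : i * n_clip + len(samples)] = samples
        events.append(
            SequenceEvent(
                onset=i * spec.soa,
                stimulus_id=clip.id,
                category="vocal" if is_vocal else "nonvocal",
                is_target=i in targets,
            )
        )

    n_fade = int(round(spec.fade_duration * rate))
    if n_fade:
        ramp = np.linspace(0.0, 1.0, n_fade, endpoint=False)
        waveform[:n_fade] *= ramp
        waveform[-n_fade:] *= ramp[::-1]

    return StimulusSequence(
        waveform=waveform,
        rate=rate,
        events=events,
        base_freq=spec.base_freq,
        target_freq=spec.target_freq,
    )


# --------------------------------------------------------------------------
# acoustic descriptors
# --------------------------------------------------------------------------

def _normalized_autocorr(x: np.ndarray) -> np.ndarray:
    """Autocorrelation normalised to r[0] = 1, with lag-bias correction."""
    x = x - x.mean()
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec))[:n]
    if r[0] <= 0:
        return np.zeros(n)
    r = r / r[0]
    lags = np.arange(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = r * n / np.maximum(n - lags, 1)  # unbiased normalisation
    return r


def pitch_estimate(
    clip: AudioClip,
    fmin: float = 75.0,
    fmax: float = 600.0,
    voicing_threshold: float = 0.35,
) -> PitchResult:
    """Autocorrelation fundamental-frequency estimate in [fmin, fmax].

    Among autocorrelation peaks within 90% of the strongest one, the
    shortest lag is chosen (guards against octave-down errors on slightly
    aperiodic signals); the peak is refined by parabolic interpolation.
    Returns an unvoiced flag when the peak correlation is below
    ``voicing_threshold``.
    """
    if clip.duration < 3.0 / fmin:
        raise ValueError("clip too short for the requested pitch floor")
    r = _normalized_autocorr(clip.samples)
    lag_min = max(2, int(np.floor(clip.rate / fmax)))
    lag_max = min(len(r) - 2, int(np.ceil(clip.rate / fmin)))
    if lag_max <= lag_min:
        raise ValueError("pitch search range empty at this sample rate")
    seg = r[lag_min : lag_max + 1]
    peaks, _ = sps.find_peaks(seg)
    if len(peaks) == 0:
        return PitchResult(np.nan, float(seg.max(initial=0.0)), False)
    best = seg[peaks].max()
    lag = lag_min + int(peaks[seg[peaks] >= 0.9 * best][0])
    # parabolic interpolation around the integer-lag peak
    y0, y1, y2 = r[lag - 1], r[lag], r[lag + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    delta = float(np.clip(delta, -0.5, 0.5))
    strength = float(min(y1 - 0.25 * (y0 - y2) * delta, 1.0))
    f0 = clip.rate / (lag + delta)
    if strength < voicing_threshold:
        return PitchResult(np.nan, strength, False)
    return PitchResult(float(f0), strength, True)


def hnr_estimate(clip: AudioClip, fmin: float = 75.0, fmax: float = 600.0,
                 cap_db: float = 60.0) -> float:
    """Harmonics-to-noise ratio in dB from the autocorrelation peak r:
    HNR = 10 log10(r / (1 - r)), capped at ``cap_db`` as r approaches 1."""
    res = pitch_estimate(clip, fmin, fmax, voicing_threshold=0.0)
    r = res.strength
    if r <= 0:
        return -cap_db
    if r >= 1 - 10 ** (-cap_db / 10):
        return cap_db
    return float(10 * np.log10(r / (1 - r)))


def spectral_centroid(clip: AudioClip) -> float:
    """Amplitude-weighted mean frequency of the magnitude spectrum."""
    if clip.rms() == 0:
        raise ValueError("spectral centroid of silence is undefined")
    mag = np.abs(np.fft.rfft(clip.samples))
    freqs = np.fft.rfftfreq(clip.n_samples, 1.0 / clip.rate)
    mag[0] = 0.0  # DC carries no frequency information
    return float(np.sum(freqs * mag) / np.sum(mag))


def acoustic_profile(clip: AudioClip) -> AcousticProfile:
    p = pitch_estimate(clip)
    return AcousticProfile(
        pitch=p.f0,
        hnr=hnr_estimate(clip),
        spectral_cog=spectral_centroid(clip),
    )
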