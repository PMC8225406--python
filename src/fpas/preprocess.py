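"""Continuous-EEG preprocessing for steady-state (frequency-tagging) analysis.

The chain mirrors standard frequency-tagging practice: zero-phase Butterworth
band-pass, FFT multi-notch at the mains frequency and its harmonics,
polyphase downsampling, epoching around sequence onsets, nearest-neighbour
repair of noisy channels, common-average re-reference, and re-segmentation
of each epoch to an exact integer number of oddball cycles so that the
responses of interest fall exactly on FFT bins (zero leakage).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts (channels x samples)."""

    data: np.ndarray
    rate: float
    ch_names: list[str]
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        dur = self.data.shape[1] / self.rate
        for onset, _ in self.events:
            if not 0 <= onset <= dur:
                raise ValueError(f"event onset {onset} outside the record")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.rate

    def replace(self, **kw) -> "EEGRecording":
        return dataclasses.replace(self, **kw)


@dataclass
class Epoch:
    """Fixed-length cut of EEG aligned to a stimulation-sequence onset.

    ``t0`` is the time of the first sample relative to sequence onset
    (negative when the cut starts before the sequence).
    """

    data: np.ndarray
    rate: float
    ch_names: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.rate

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def replace(self, **kw) -> "Epoch":
        return dataclasses.replace(self, **kw)


ElectrodeLayout = dict  # label -> (x, y, z) on the unit sphere


def bandpass_butterworth(
    rec: EEGRecording, low: float, high: float, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward, so the effective
    attenuation corresponds to twice the design order)."""
    if not (0 < low < high < rec.rate / 2):
        raise ValueError("require 0 < low < high < Nyquist")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    return rec.replace(data=sps.sosfiltfilt(sos, rec.data, axis=1))


def fft_multinotch(
    rec: EEGRecording, freqs: list[float], width: float = 0.5
) -> EEGRecording:
    """Suppress narrow spectral lines (e.g. 50/100/150 Hz mains).

    Bins within ``width/2`` of each notch frequency have their amplitude
    replaced by the mean amplitude of the local flanking bins (phase kept),
    with a one-bin linear taper at the notch edges.
    """
    for f in freqs:
        if f >= rec.rate / 2:
            raise ValueError(f"notch frequency {f} above Nyquist")
    if not freqs:
        return rec.replace(data=rec.data.copy())
    n = rec.data.shape[1]
    spec = np.fft.rfft(rec.data, axis=1)
    fgrid = np.fft.rfftfreq(n, 1.0 / rec.rate)
    mag = np.abs(spec)
    for f0 in freqs:
        inside = np.abs(fgrid - f0) <= width / 2
        if not inside.any():
            continue
        flank = (np.abs(fgrid - f0) > width / 2) & (np.abs(fgrid - f0) <= width / 2 + 1.0)
        baseline = mag[:, flank].mean(axis=1, keepdims=True)
        idx = np.flatnonzero(inside)
        blend = np.ones(len(idx))
        blend[0] = blend[-1] = 0.5  # one-bin taper at the notch edges
        target = baseline * np.ones((1, len(idx)))
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(mag[:, idx] > 0, target / np.maximum(mag[:, idx], 1e-300), 0.0)
        gain = 1.0 + blend[None, :] * (gain - 1.0)
        spec[:, idx] *= gain
    return rec.replace(data=np.fft.irfft(spec, n=n, axis=1))


def resample(rec: EEGRecording, new_rate: float) -> EEGRecording:
    """Polyphase rational resampling; event onsets (seconds) are unchanged."""
    if new_rate > rec.rate:
        raise ValueError("upsampling not supported")
    if new_rate == rec.rate:
        return rec.replace(data=rec.data.copy())
    frac = Fraction(int(round(new_rate * 1_000_000)), int(round(rec.rate * 1_000_000)))
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.replace(data=data, rate=new_rate)


def segment_epochs(
    rec: EEGRecording,
    pre: float,
    post: float,
    seq_duration: float,
    code: str | None = None,
) -> list[Epoch]:
    """One epoch per sequence-onset event, spanning
    [onset - pre, onset + seq_duration + post). Out-of-bounds windows are
    skipped with a log entry."""
    n_len = int(round((pre + seq_duration + post) * rec.rate))
    epochs = []
    for onset, ev_code in rec.events:
        if code is not None and ev_code != code:
            continue
        start = int(round((onset - pre) * rec.rate))
        if start < 0 or start + n_len > rec.data.shape[1]:
            logger.warning("skipping event at %.3f s: window out of bounds", onset)
            continue
        epochs.append(
            Epoch(
                data=rec.data[:, start : start + n_len].copy(),
                rate=rec.rate,
                ch_names=list(rec.ch_names),
                t0=-pre,
            )
        )
    return epochs


def interpolate_channels(
    epoch: Epoch,
    bad: list[str],
    layout: ElectrodeLayout,
    k: int = 4,
) -> Epoch:
    """Replace each bad channel by the mean of its ``k`` nearest good
    neighbours (Euclidean distance on the electrode layout)."""
    if not bad:
        return epoch.replace(data=epoch.data.copy())
    if set(bad) >= set(epoch.ch_names):
        raise ValueError("cannot interpolate every channel")
    if k < 1:
        raise ValueError("k must be >= 1")
    pos = {lbl: np.asarray(layout[lbl], dtype=float) for lbl in epoch.ch_names}
    good = [c for c in epoch.ch_names if c not in bad]
    if len(good) < k:
        raise ValueError(f"fewer than k={k} good channels available")
    data = epoch.data.copy()
    index = {c: i for i, c in enumerate(epoch.ch_names)}
    for b in bad:
        d = np.array([np.linalg.norm(pos[b] - pos[g]) for g in good])
        nearest = [good[i] for i in np.argsort(d, kind="stable")[:k]]
        data[index[b]] = epoch.data[[index[g] for g in nearest]].mean(axis=0)
    return epoch.replace(data=data)


def rereference_average(epoch: Epoch) -> Epoch:
    """Common-average reference: subtract the instantaneous mean across
    channels (idempotent; commutes with channel permutation)."""
    if epoch.n_channels < 2:
        raise ValueError("average reference needs >= 2 channels")
    return epoch.replace(data=epoch.data - epoch.data.mean(axis=0, keepdims=True))


def resegment_integer_cycles(
    epoch: Epoch,
    target_freq: float,
    skip: float = 0.0,
    trailing: float = 0.0,
    max_duration: float | None = None,
) -> Epoch:
    """Trim an epoch to an exact integer number of target cycles.

    ``skip`` seconds at the start (pre-stimulus interval plus fade-in) and
    ``trailing`` seconds at the end are discarded; the remainder (optionally
    capped at ``max_duration``) is truncated to floor(duration * f) cycles.
    The sample count is rounded to the nearest sample, so the integer-cycle
    property is exact only up to half a sample when the cycle length is not
    sample-commensurate.
    """
    avail = epoch.duration - skip - trailing
    if max_duration is not None:
        avail = min(avail, max_duration)
    n_cycles = int(np.floor(avail * target_freq + 1e-9))
    if n_cycles < 1:
        raise ValueError("epoch too short for one target cycle")
    new_dur = n_cycles / target_freq
    start = int(round(skip * epoch.rate))
    n_samp = int(round(new_dur * epoch.rate))
    if start + n_samp > epoch.data.shape[1]:
        raise ValueError("resegmentation window exceeds the epoch")
    return epoch.replace(data=epoch.data[:, start : start + n_samp].copy(), t0=0.0)


def reject_peak_to_peak(
    epochs: list[Epoch], threshold_uv: float | None = None
) -> list[Epoch]:
    """Optional amplitude-based epoch rejection (off when threshold is None):
    drop epochs whose worst channel peak-to-peak amplitude exceeds the
    threshold in microvolts."""
    if threshold_uv is None:
        return list(epochs)
    kept = []
    for ep in epochs:
        ptp = (ep.data.max(axis=1) - ep.data.min(axis=1)).max()
        if ptp <= threshold_uv:
            kept.append(ep)
        else:
            logger.info("rejecting epoch: peak-to-peak %.1f uV", ptp)
    return kept


def preprocess_chain(
    rec: EEGRecording,
    band: tuple[float, float] = (0.1, 100.0),
    order: int = 4,
    notches: tuple[float, ...] = (50.0, 100.0, 150.0),
    notch_width: float = 0.5,
    new_rate: float = 256.0,
    pre: float = 2.0,
    post: float = 3.0,
    seq_duration: float = 64.0,
    bad: list[str] | None = None,
    layout: ElectrodeLayout | None = None,
    k_neighbors: int = 4,
) -> list[Epoch]:
    """The full standard chain: filter, notch, downsample, epoch, repair,
    common-average reference."""
    rec = bandpass_butterworth(rec, band[0], band[1], order)
    rec = fft_multinotch(rec, list(notches), notch_width)
    rec = resample(rec, new_rate)
    epochs = segment_epochs(rec, pre, post, seq_duration)
    out = []
    for ep in epochs:
        if bad:
            if layout is None:
                raise ValueError("layout required to interpolate channels")
            ep = interpolate_channels(ep, bad, layout, k_neighbors)
        out.append(rereference_average(ep))
    return out
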