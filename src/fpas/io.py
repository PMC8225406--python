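"""File formats.

WAV audio through ``scipy.io.wavfile`` (PCM16/PCM24-read/PCM32/float); EEG
recordings and epoch sets in an HDF5 container (datasets ``data``, string
``ch_names``, attributes ``rate``/``t0``, events as parallel onset/code
datasets); EDF/BDF continuous EEG through MNE when such a file is supplied;
event manifests, acoustic-profile reports, statistical reports and
topographies as tab-separated text.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .groupstats import ContrastResult
from .preprocess import EEGRecording, Epoch
from .stimgen import AcousticProfile, AudioClip, SequenceEvent, StimulusSequence


# --------------------------------------------------------------------------
# audio
# --------------------------------------------------------------------------

def read_wav(path: str | Path, category: str | None = None) -> AudioClip:
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return AudioClip(data, float(rate), category, Path(path).stem)


def write_wav(path: str | Path, clip: AudioClip | StimulusSequence,
              dtype: str = "float32") -> None:
    x = clip.waveform if isinstance(clip, StimulusSequence) else clip.samples
    if dtype == "float32":
        wavfile.write(str(path), int(clip.rate), x.astype(np.float32))
    elif dtype == "int16":
        peak = np.max(np.abs(x))
        scale = 32767 / peak if peak > 0 else 1.0
        wavfile.write(str(path), int(clip.rate), (x * scale).astype(np.int16))
    else:
        raise ValueError("dtype must be 'float32' or 'int16'")


# --------------------------------------------------------------------------
# event manifests and reports (TSV)
# --------------------------------------------------------------------------

def write_event_manifest(path: str | Path, seq: StimulusSequence) -> None:
    df = pd.DataFrame(
        {
            "onset_s": [e.onset for e in seq.events],
            "id": [e.stimulus_id for e in seq.events],
            "category": [e.category for e in seq.events],
            "is_target": [int(e.is_target) for e in seq.events],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_event_manifest(path: str | Path) -> list[SequenceEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        SequenceEvent(float(r.onset_s), str(r.id), str(r.category), bool(r.is_target))
        for r in df.itertuples()
    ]


def write_acoustic_report(
    path: str | Path, profiles: dict[str, AcousticProfile]
) -> None:
    df = pd.DataFrame(
        {
            "id": list(profiles),
            "pitch_hz": [p.pitch for p in profiles.values()],
            "hnr_db": [p.hnr for p in profiles.values()],
            "spectral_cog_hz": [p.spectral_cog for p in profiles.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_contrast_report(path: str | Path, res: ContrastResult) -> None:
    pd.DataFrame(
        {
            "electrode": res.ch_names,
            "t": res.t,
            "p": res.p,
            "p_bonf": res.p_bonf,
            "d": res.d,
            "significant": res.significant.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def write_topography(path: str | Path, values: np.ndarray, ch_names: list[str]) -> None:
    pd.DataFrame({"electrode": ch_names, "value": values}).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# EEG container (HDF5)
# --------------------------------------------------------------------------

def save_recording(path: str | Path, rec: EEGRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["rate"] = rec.rate
        f.create_dataset("ch_names", data=np.array(rec.ch_names, dtype="S"))
        f.create_dataset("event_onsets", data=[o for o, _ in rec.events])
        f.create_dataset(
            "event_codes", data=np.array([c for _, c in rec.events], dtype="S")
        )


def load_recording(path: str | Path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        return EEGRecording(
            data=f["data"][()],
            rate=float(f.attrs["rate"]),
            ch_names=[s.decode() for s in f["ch_names"][()]],
            events=list(
                zip(
                    (float(o) for o in f["event_onsets"][()]),
                    (c.decode() for c in f["event_codes"][()]),
                )
            ),
        )


def save_epochs(path: str | Path, epochs: list[Epoch]) -> None:
    with h5py.File(path, "w") as f:
        for i, ep in enumerate(epochs):
            g = f.create_group(f"epoch{i:03d}")
            g.create_dataset("data", data=ep.data)
            g.attrs["rate"] = ep.rate
            g.attrs["t0"] = ep.t0
            g.create_dataset("ch_names", data=np.array(ep.ch_names, dtype="S"))


def load_epochs(path: str | Path) -> list[Epoch]:
    epochs = []
    with h5py.File(path, "r") as f:
        for key in sorted(f):
            g = f[key]
            epochs.append(
                Epoch(
                    data=g["data"][()],
                    rate=float(g.attrs["rate"]),
                    ch_names=[s.decode() for s in g["ch_names"][()]],
                    t0=float(g.attrs["t0"]),
                )
            )
    return epochs


def read_raw_edf(path: str | Path, onset_code: str = "seq") -> EEGRecording:
    """Read continuous EEG from an EDF/BDF file (via MNE); annotations become
    events."""
    import mne

    reader = mne.io.read_raw_bdf if str(path).lower().endswith(".bdf") else mne.io.read_raw_edf
    raw = reader(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = [
        (float(a["onset"]), str(a["description"]) or onset_code)
        for a in raw.annotations
    ]
    return EEGRecording(
        data=data, rate=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names), events=events,
    )
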