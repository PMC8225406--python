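"""128-channel electrode layout on the unit sphere.

Positions come from the extended 10-05 montage; a deterministic
farthest-point subsample of 128 labels approximates the spatial coverage of
a 128-channel cap while guaranteeing that the electrodes named in the
analyses (TP8h, CP6, C6, T8 and their left homologues) are present under
their standard names.  Layouts are plain mappings ``label -> (x, y, z)``
with unit-norm coordinates, and round-trip through a whitespace text table.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

import numpy as np

# electrodes any layout must contain (analysis ROIs + midline anchors)
REQUIRED = [
    "TP8h", "CP6", "C6", "T8", "T8h",
    "TP7", "T7", "T7h", "C5", "CP5",
    "Cz", "Oz", "Fz", "Pz", "Fpz",
]


@lru_cache(maxsize=1)
def biosemi128_layout() -> dict[str, np.ndarray]:
    """Build the default 128-channel layout (deterministic)."""
    import warnings

    import mne  # deferred: slow import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mont = mne.channels.make_standard_montage("standard_1005")
    pos = mont.get_positions()["ch_pos"]
    names = [n for n in mont.ch_names if n in pos and np.isfinite(pos[n]).all()]
    xyz = np.array([pos[n] for n in names])
    xyz = xyz - xyz.mean(axis=0)  # approx. sphere centre
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    index = {n: i for i, n in enumerate(names)}
    missing = [r for r in REQUIRED if r not in index]
    if missing:
        raise RuntimeError(f"montage lacks required electrodes: {missing}")

    chosen = [index[r] for r in REQUIRED]
    dist = np.linalg.norm(xyz[:, None, :] - xyz[None, chosen, :], axis=2).min(axis=1)
    while len(chosen) < 128:
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(xyz - xyz[nxt], axis=1))
    order = sorted(chosen, key=lambda i: names[i])
    return {names[i]: xyz[i] for i in order}


def write_layout(layout: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, p in layout.items():
            fh.write(f"{label} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_layout(path: str | Path) -> dict[str, np.ndarray]:
    layout: dict[str, np.ndarray] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        label, x, y, z = line.split()
        p = np.array([float(x), float(y), float(z)])
        n = np.linalg.norm(p)
        layout[label] = p / n if n > 0 else p
    return layout
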