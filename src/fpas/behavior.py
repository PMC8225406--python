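"""Signal-detection scoring of the voice-detection tasks.

Participants hear either five-sound mini-sequences (the voice, when present,
always in third position, mirroring the oddball structure) or isolated
sounds, and report voice present/absent.  Sensitivity is summarised by
d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate) under the equal-variance
Gaussian model, after a correction that keeps extreme rates away from 0/1.

The default correction is log-linear (add 0.5 to both counts, 1 to both
trial totals): its exact binomial expectation is within 0.013 of the true
d' at n = 40/40 for sensitivities up to ~2, whereas clipping rates to
[1/(2N), 1 - 1/(2N)] overshoots by ~0.07 there.  Both saturate for very
high sensitivity (d' ~ 4 at n = 40 means at most one error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class DetectionOutcome:
    n_signal: int
    n_noise: int
    hits: int
    false_alarms: int

    def __post_init__(self) -> None:
        if not (0 <= self.hits <= self.n_signal):
            raise ValueError("hits out of range")
        if not (0 <= self.false_alarms <= self.n_noise):
            raise ValueError("false alarms out of range")
        if self.n_signal < 1 or self.n_noise < 1:
            raise ValueError("need at least one signal and one noise trial")


@dataclass
class Trial:
    stimulus_ids: list[str]
    voice_present: bool
    condition: str
    task: str  # "sequence" | "isolation"


@dataclass
class TrialSet:
    trials: list[Trial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_signal(self) -> int:
        return sum(t.voice_present for t in self.trials)

    @property
    def n_noise(self) -> int:
        return len(self.trials) - self.n_signal


def _corrected_rate(count: int, n: int, correction: str) -> float:
    if correction == "loglinear":
        return (count + 0.5) / (n + 1)
    if correction == "clip":
        return float(np.clip(count / n, 1 / (2 * n), 1 - 1 / (2 * n)))
    raise ValueError("correction must be 'loglinear' or 'clip'")


def d_prime(outcome: DetectionOutcome, correction: str = "loglinear") -> float:
    """Sensitivity d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate)."""
    hr = _corrected_rate(outcome.hits, outcome.n_signal, correction)
    fa = _corrected_rate(outcome.false_alarms, outcome.n_noise, correction)
    return float(stats.norm.ppf(hr) - stats.norm.ppf(fa))


def criterion_c(outcome: DetectionOutcome, correction: str = "loglinear") -> float:
    """Response bias c = -(Phi^-1(HR) + Phi^-1(FA)) / 2 (optional output)."""
    hr = _corrected_rate(outcome.hits, outcome.n_signal, correction)
    fa = _corrected_rate(outcome.false_alarms, outcome.n_noise, correction)
    return float(-(stats.norm.ppf(hr) + stats.norm.ppf(fa)) / 2)


# task-design constants
SEQUENCE_LENGTH = 5
VOICE_POSITION = 2  # 0-based third sound
N_PRESENT = 40
N_ABSENT = 40
ISOLATION_COUNTS = {  # condition -> (n vocal, n non-vocal)
    "standard": (33, 67),
    "scrambled": (33, 67),
    "harmonic": (16, 16),
}


def build_behavior_trials(
    vocal_ids: Sequence[str],
    nonvocal_ids: Sequence[str],
    condition: str,
    task: str,
    seed: int = 0,
) -> TrialSet:
    """Assemble one condition's trial list.

    Sequence task: 40 voice-present and 40 voice-absent five-sound
    sequences; a present voice always occupies the third position.
    Isolation task: single sounds at the per-condition vocal:non-vocal
    counts (33/67 for the standard and scrambled pools, 16/16 for the
    matched harmonic pool).
    """
    if condition not in ISOLATION_COUNTS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    if task == "sequence":
        if not vocal_ids or len(nonvocal_ids) < SEQUENCE_LENGTH:
            raise ValueError("insufficient clip pools for the sequence task")
        order = rng.permutation(N_PRESENT + N_ABSENT)
        for i in order:
            present = i < N_PRESENT
            ids = list(rng.choice(nonvocal_ids, SEQUENCE_LENGTH, replace=False))
            if present:
                ids[VOICE_POSITION] = str(rng.choice(vocal_ids))
            trials.append(Trial(ids, present, condition, task))
    elif task == "isolation":
        n_voc, n_non = ISOLATION_COUNTS[condition]
        if len(vocal_ids) < min(n_voc, len(vocal_ids)) or not vocal_ids:
            raise ValueError("insufficient vocal pool")
        if not nonvocal_ids:
            raise ValueError("insufficient non-vocal pool")
        voc = rng.choice(vocal_ids, n_voc, replace=len(vocal_ids) < n_voc)
        non = rng.choice(nonvocal_ids, n_non, replace=len(nonvocal_ids) < n_non)
        pool = [(str(v), True) for v in voc] + [(str(s), False) for s in non]
        for j in rng.permutation(len(pool)):
            sid, present = pool[j]
            trials.append(Trial([sid], present, condition, task))
    else:
        raise ValueError("task must be 'sequence' or 'isolation'")
    return TrialSet(trials)


def score_responses(trials: TrialSet, responses: Sequence[bool]) -> DetectionOutcome:
    """Tally hits and false alarms of yes/no responses against the labels."""
    if len(responses) != len(trials):
        raise ValueError("one response per trial required")
    hits = sum(r and t.voice_present for r, t in zip(responses, trials.trials))
    fas = sum(r and not t.voice_present for r, t in zip(responses, trials.trials))
    return DetectionOutcome(
        n_signal=trials.n_signal, n_noise=trials.n_noise,
        hits=hits, false_alarms=fas,
    )
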