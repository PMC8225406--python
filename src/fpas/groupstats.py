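"""Group- and subject-level inference on summed harmonic responses.

One-sample and paired electrode-wise contrasts with Bonferroni correction
over the electrode count, Cohen's d (for one-sample tests d = mean/SD =
t/sqrt(n)), Spearman rank correlation, Welch's t (from raw samples or from
printed summary statistics), the Mann-Whitney test (reported both as U and
as the rank-sum W convention), and the single-pass 3-SD outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    d: float


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


@dataclass
class MannWhitneyResult:
    u: float  # Mann-Whitney U of the first sample
    w: float  # rank-sum statistic of the first sample (W convention)
    p: float


@dataclass
class ContrastResult:
    """Per-electrode paired contrast, Bonferroni corrected."""

    ch_names: list[str]
    t: np.ndarray
    p: np.ndarray  # uncorrected, one-tailed
    p_bonf: np.ndarray  # p * n_comparisons, capped at 1
    d: np.ndarray
    significant: np.ndarray  # p_bonf < .05


def one_sample_t(
    values: np.ndarray, mu: float = 0.0, tail: str = "greater"
) -> TTestResult:
    """One-sample t against ``mu``; one-tailed by default (signal > mu)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 2 finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    n = len(x)
    return one_sample_t_summary(float(x.mean()), float(sd), n, mu, tail)


def one_sample_t_summary(
    mean: float, sd: float, n: int, mu: float = 0.0, tail: str = "greater"
) -> TTestResult:
    """Same test from printed summary statistics."""
    if n < 2 or sd <= 0:
        raise ValueError("need n >= 2 and sd > 0")
    t = (mean - mu) / (sd / np.sqrt(n))
    df = n - 1
    if tail == "greater":
        p = float(stats.t.sf(t, df))
    elif tail == "two-sided":
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        raise ValueError("tail must be 'greater' or 'two-sided'")
    return TTestResult(t=float(t), df=df, p=p, d=float((mean - mu) / sd))


def cohens_d_from_t(t: float, n: int) -> float:
    """One-sample / paired effect size from the t statistic: d = t / sqrt(n)."""
    return float(t / np.sqrt(n))


def paired_t_contrast(
    topo_a: np.ndarray,
    topo_b: np.ndarray,
    ch_names: list[str],
    n_comparisons: int | None = None,
    alpha: float = 0.05,
) -> ContrastResult:
    """Electrode-wise paired t test (A > B, one-tailed) across matched
    subjects, Bonferroni corrected over ``n_comparisons`` electrodes.

    ``topo_a`` and ``topo_b`` are subjects x channels.
    """
    a = np.asarray(topo_a, dtype=float)
    b = np.asarray(topo_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must have matched subjects x channels")
    if a.shape[1] != len(ch_names):
        raise ValueError("one label per channel required")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    if n_comparisons is None:
        n_comparisons = a.shape[1]
    diff = a - b
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    p = stats.t.sf(t, n - 1)
    p_bonf = np.minimum(p * n_comparisons, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sd > 0, mean / sd, 0.0)
    return ContrastResult(
        ch_names=list(ch_names), t=t, p=p, p_bonf=p_bonf, d=d,
        significant=p_bonf < alpha,
    )


@dataclass
class ROIDefinition:
    name: str
    electrodes: list[str]


# The right superior-temporal region defined by the standard > scrambled
# contrast, used by name throughout.
ROI_VOICE = ROIDefinition("ROIvoice", ["TP8h", "CP6", "C6", "T8"])
ROI_LEFT = ROIDefinition("left", ["T7h", "T7", "TP7"])
ROI_RIGHT = ROIDefinition("right", ["TP8h", "CP6", "T8h", "T8"])


def roi_average(topo: np.ndarray, ch_names: list[str], roi: ROIDefinition) -> float:
    """Arithmetic mean of a per-channel topography over the ROI electrodes."""
    index = {c: i for i, c in enumerate(ch_names)}
    missing = [e for e in roi.electrodes if e not in index]
    if missing:
        raise ValueError(f"ROI electrodes missing from the montage: {missing}")
    topo = np.asarray(topo, dtype=float)
    return float(topo[[index[e] for e in roi.electrodes]].mean())


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation with two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need matched samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> WelchResult:
    """Welch's two-sample t with Welch-Satterthwaite degrees of freedom,
    from summary statistics; two-tailed p."""
    if min(n1, n2) < 2 or sd1 <= 0 or sd2 <= 0:
        raise ValueError("need n >= 2 and positive SDs in both groups")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=p)


def welch_t_samples(x: np.ndarray, y: np.ndarray) -> WelchResult:
    """Welch's t from raw samples; identical to the summary-statistic mode."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t(
        float(x.mean()), float(x.std(ddof=1)), len(x),
        float(y.mean()), float(y.std(ddof=1)), len(y),
    )


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> MannWhitneyResult:
    """Mann-Whitney U (exact for small tie-free samples, normal
    approximation otherwise); W = U + n1(n1+1)/2 is the rank-sum form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    small = len(x) <= 20 and len(y) <= 20
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if small and not ties else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    w = u + len(x) * (len(x) + 1) / 2
    return MannWhitneyResult(u=u, w=w, p=float(res.pvalue))


def outlier_3sd(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass exclusion of points beyond 3 SD from the full-sample mean.

    Returns (kept values, excluded indices)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    mean, sd = x.mean(), x.std(ddof=1)
    out = np.flatnonzero(np.abs(x - mean) > 3 * sd)
    keep = np.setdiff1d(np.arange(len(x)), out)
    return x[keep], out
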