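"""Seizure-time normalization, baseline-outlier engagement, onset scan.

Every seizure is mapped onto 100 equal-duration bins so engagement can be
compared across seizures of different lengths.  Per contact and bin, the
mean |CSD| is compared with a pre-ictal baseline (binned at the same bin
duration); values exceeding baseline mean + 2 SD count as engaged, and the
per-bin engagement is normalized to a distribution across contacts or
layer groups.  ``engagement_onset`` estimates the normalized-time fraction
at which a group's engagement rises, by a two-sample (Welch) split scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .csd import CSDMatrix
from .laminar import GROUP_ORDER, LayerPartition


@dataclass
class BinnedBaseline:
    mean: np.ndarray  # per contact
    sd: np.ndarray


@dataclass
class EngagementMatrix:
    values: np.ndarray            # rows (contacts or groups) x n_bins, per-bin distribution
    excess: np.ndarray            # same shape, un-normalized thresholded excess
    row_labels: list
    basis: str                    # excess | binary


def normalize_seizure_time(
    csd: CSDMatrix, interval: tuple[float, float], n_bins: int = 100
) -> np.ndarray:
    """Per-contact mean |CSD| in ``n_bins`` equal-duration bins spanning the
    interval (the last bin absorbs the sample remainder)."""
    i0, i1 = csd.sample_at(interval[0]), csd.sample_at(interval[1])
    i0, i1 = max(0, i0), min(csd.values.shape[1], i1)
    n = i1 - i0
    if n < n_bins:
        raise ValueError(f"interval has {n} samples, fewer than {n_bins} bins")
    x = np.abs(csd.values[:, i0:i1])
    per = n // n_bins
    edges = np.arange(n_bins) * per
    sums = np.add.reduceat(x, edges, axis=1)
    widths = np.diff(np.append(edges, n))
    return sums / widths


def baseline_from_interval(
    csd: CSDMatrix, baseline_interval: tuple[float, float], bin_duration_s: float
) -> BinnedBaseline:
    """Per-contact mean and SD of |CSD| over baseline bins of the same
    duration as the ictal bins.  Requires >= 10 s of baseline."""
    t0, t1 = baseline_interval
    if t1 - t0 < 10.0 - 1e-9:
        raise ValueError("baseline interval must be at least 10 s")
    per = max(1, int(round(bin_duration_s * csd.fs_hz)))
    x = np.abs(csd.slice(t0, t1))
    n_bins = x.shape[1] // per
    x = x[:, : n_bins * per].reshape(x.shape[0], n_bins, per).mean(axis=2)
    return BinnedBaseline(mean=x.mean(axis=1), sd=x.std(axis=1))


def engagement_matrix(
    binned: np.ndarray,
    baseline: BinnedBaseline,
    sd_mult: float = 2.0,
    partition: LayerPartition | None = None,
    binary: bool = False,
    first_contact: int = 0,
) -> EngagementMatrix:
    """Baseline-outlier engagement: per contact-bin, the excess of binned
    |CSD| over baseline mean + ``sd_mult`` SD (or a 0/1 outlier flag with
    ``binary=True``), optionally aggregated into layer groups, then
    normalized per bin to a distribution across rows."""
    if baseline.mean.shape[0] != binned.shape[0]:
        raise ValueError("baseline and binned matrices have different channel counts")
    thr = baseline.mean + sd_mult * baseline.sd
    excess = np.maximum(binned - thr[:, None], 0.0)
    if binary:
        excess = (excess > 0).astype(float)
    labels: list = list(range(first_contact, first_contact + binned.shape[0]))
    if partition is not None:
        rows = []
        labels = list(GROUP_ORDER)
        for g in GROUP_ORDER:
            idx = partition.groups[g] - first_contact
            idx = idx[(idx >= 0) & (idx < binned.shape[0])]
            rows.append(excess[idx].sum(axis=0) if idx.size else np.zeros(binned.shape[1]))
        excess = np.vstack(rows)
    col = excess.sum(axis=0)
    values = np.divide(excess, col, out=np.zeros_like(excess), where=col > 0)
    return EngagementMatrix(values, excess, labels, "binary" if binary else "excess")


def _welch(early: np.ndarray, late: np.ndarray) -> tuple[float, float]:
    """Welch t (late - early) and two-sided p, valid for zero variances."""
    n1, n2 = early.size, late.size
    m1, m2 = early.mean(), late.mean()
    v1, v2 = early.var(ddof=1), late.var(ddof=1)
    if np.isclose(m1, m2, rtol=1e-9, atol=1e-12):  # numerically identical
        return 0.0, 1.0
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return (np.inf if m2 > m1 else -np.inf), 0.0
    t = (m2 - m1) / np.sqrt(se2)
    df_num = se2**2
    df_den = (v1 / n1) ** 2 / max(n1 - 1, 1) + (v2 / n2) ** 2 / max(n2 - 1, 1)
    df = df_num / df_den if df_den > 0 else n1 + n2 - 2
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def engagement_onset(
    series: np.ndarray, alpha: float = 0.01, min_seg: int = 5
) -> tuple[int, float] | None:
    """Estimate the bin at which a 100-bin engagement series steps up.

    Every split k (early = bins < k) is tested with a Welch t-test; among
    significant splits with late mean > early mean, the one maximizing the
    t statistic is taken (binary-segmentation style), and the returned onset
    is the first bin of the elevated regime (1-based, i.e. percent of
    normalized seizure time).  Returns (onset_bin, p) or None.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    best: tuple[float, int, float] | None = None
    for k in range(min_seg, n - min_seg + 1):
        t, p = _welch(x[:k], x[k:])
        if p < alpha and t > 0:
            if best is None or t > best[0]:
                best = (t, k, p)
    if best is None:
        return None
    return best[1] + 1, best[2]


def group_engagement_series(eng: EngagementMatrix, group: str) -> np.ndarray:
    """Row of a group-aggregated engagement matrix."""
    if group not in eng.row_labels:
        raise KeyError(f"group {group!r} not in engagement rows {eng.row_labels}")
    return eng.values[eng.row_labels.index(group)]
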