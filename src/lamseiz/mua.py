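"""Multi-unit-activity firing-rate estimation and depth statistics.

MUA is quantified by robust threshold-crossing counting on the high-passed
MUA band (no spike sorting): crossings of k x MAD with a 1 ms refractory
period are binned (10 ms), smoothed with a 100 ms boxcar and min-max
normalized to [0, 1] per recording (per channel optionally).  Channel-wise
baselines come from the 10 s pre-ictal window, and ``depth_fraction``
reports the share of baseline-exceeding ictal activity carried by the
deepest fraction of contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LaminarRecording


class CapabilityError(RuntimeError):
    """The recording lacks an analyzable MUA band."""


@dataclass
class MuaParams:
    k_mad: float = 4.0
    refractory_ms: float = 1.0
    bin_ms: float = 10.0
    smooth_ms: float = 100.0
    normalize: str = "recording"  # recording | channel


@dataclass
class MuaRate:
    rates: np.ndarray           # n_contacts x n_bins
    bin_s: float
    baseline_mean: np.ndarray   # per contact, in the rates' units
    baseline_sd: np.ndarray
    normalized: bool
    spike_counts: np.ndarray    # raw crossings per contact

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    def bin_of(self, t_s: float) -> int:
        return min(int(t_s / self.bin_s), self.n_bins - 1)


def threshold_crossing_times(
    x: np.ndarray, fs: float, k_mad: float = 4.0, refractory_ms: float = 1.0
) -> np.ndarray:
    """Times of |x| threshold crossings at k x MAD with a refractory period."""
    med = np.median(x)
    mad = np.median(np.abs(x - med)) or 1e-12
    thr = k_mad * 1.4826 * mad
    a = np.abs(x - med) > thr
    onsets = np.nonzero(a[1:] & ~a[:-1])[0] + 1
    if a[0]:
        onsets = np.concatenate([[0], onsets])
    if onsets.size == 0:
        return np.empty(0)
    refr = refractory_ms / 1000.0 * fs
    keep = [onsets[0]]
    for i in onsets[1:]:
        if i - keep[-1] >= refr:
            keep.append(i)
    return np.asarray(keep) / fs


def estimate_mua_rate(rec: LaminarRecording, params: MuaParams | None = None) -> MuaRate:
    """Per-channel MUA firing rate from threshold crossings of the MUA band."""
    params = params or MuaParams()
    if rec.mua is None:
        raise CapabilityError("recording has no analyzable MUA band")
    if "preictal" not in rec.annotations:
        raise ValueError("a 'preictal' annotation is required for the MUA baseline")
    fs = rec.fs_mua_hz
    nch = rec.mua.shape[0]
    bin_s = params.bin_ms / 1000.0
    n_bins = int(np.ceil(rec.mua.shape[1] / fs / bin_s))
    rates = np.zeros((nch, n_bins))
    counts = np.zeros(nch, dtype=int)
    for c in range(nch):
        t = threshold_crossing_times(
            np.asarray(rec.mua[c], dtype=np.float64), fs, params.k_mad, params.refractory_ms
        )
        counts[c] = t.size
        if t.size:
            idx = np.minimum((t / bin_s).astype(int), n_bins - 1)
            np.add.at(rates[c], idx, 1.0)
    rates /= bin_s  # events/s
    w = max(1, int(round(params.smooth_ms / params.bin_ms)))
    if w > 1:
        kernel = np.ones(w) / w
        rates = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, rates)

    if params.normalize == "recording":
        lo, hi = rates.min(), rates.max()
        rates = (rates - lo) / (hi - lo) if hi > lo else np.zeros_like(rates)
    elif params.normalize == "channel":
        lo = rates.min(axis=1, keepdims=True)
        hi = rates.max(axis=1, keepdims=True)
        rng = np.where(hi > lo, hi - lo, 1.0)
        rates = (rates - lo) / rng
    else:
        raise ValueError(f"unknown normalize mode {params.normalize!r}")

    p0, p1 = rec.annotations["preictal"]
    j0, j1 = int(p0 / bin_s), int(p1 / bin_s)
    base = rates[:, j0:j1]
    return MuaRate(
        rates=rates,
        bin_s=bin_s,
        baseline_mean=base.mean(axis=1),
        baseline_sd=base.std(axis=1),
        normalized=True,
        spike_counts=counts,
    )


def depth_fraction(
    mua: MuaRate, ictal: tuple[float, float], deepest_fraction: float = 0.2
) -> float:
    """Share of above-baseline ictal MUA carried by the deepest contacts.

    The deepest ceil(fraction x n) channels are used; per-channel
    contributions are mean ictal rate minus baseline mean, floored at zero.
    """
    if not 0.0 < deepest_fraction <= 1.0:
        raise ValueError("deepest_fraction must be in (0, 1]")
    n = mua.rates.shape[0]
    k = int(np.ceil(deepest_fraction * n))
    j0, j1 = mua.bin_of(ictal[0]), mua.bin_of(ictal[1])
    excess = np.maximum(mua.rates[:, j0:j1].mean(axis=1) - mua.baseline_mean, 0.0)
    total = excess.sum()
    if total == 0:
        return 0.0
    return float(np.clip(excess[n - k :].sum() / total, 0.0, 1.0))
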