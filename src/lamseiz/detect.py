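"""Automated ictal-discharge detection and scoring.

Detection operates on the successive-contact potential-gradient channels
(the native differential recordings of a laminar probe; monopolar input is
converted internally).  Per channel, the signal is expressed in robust z
units against a pre-ictal median/MAD baseline; candidate events are maximal
suprathreshold runs that additionally satisfy bidirectional slope and
duration criteria.  Per-channel events are then collapsed across channels
into single discharges.

Because ground truth here is a point process, detector performance is
scored two ways: event-wise sensitivity/precision by greedy one-to-one
nearest matching within a tolerance, and binwise specificity over fixed
bins (default 100 ms) that contain no true event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LaminarRecording, make_event_table
from .preprocess import monopolar_to_gradient


@dataclass
class DetectorParams:
    amp_threshold: float = 4.0          # robust z
    min_rise_slope: float = 0.5         # robust z per ms
    min_fall_slope: float = 0.5
    min_duration_ms: float = 20.0
    max_duration_ms: float = 200.0
    merge_gap_ms: float = 20.0
    cross_channel_window_ms: float = 25.0
    min_separation_ms: float = 60.0     # discharge-level dedup (rebound lobes)
    baseline: str = "preictal"          # annotation name used for median/MAD

    def __post_init__(self) -> None:
        if min(self.amp_threshold, self.min_rise_slope, self.min_fall_slope) <= 0:
            raise ValueError("thresholds must be > 0")
        if not self.min_duration_ms < self.max_duration_ms:
            raise ValueError("min_duration must be < max_duration")


@dataclass
class DischargeSet:
    events: pd.DataFrame
    params: DetectorParams
    n_channels: int
    channel_events: pd.DataFrame | None = None

    @property
    def times_s(self) -> np.ndarray:
        return self.events["time_s"].to_numpy()

    def __len__(self) -> int:
        return len(self.events)


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not runs:
        return runs
    merged = [runs[0]]
    for a, b in runs[1:]:
        if a - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def detect_discharges(rec: LaminarRecording, params: DetectorParams | None = None) -> DischargeSet:
    """Detect ictal discharges on the gradient channels of ``rec``."""
    params = params or DetectorParams()
    if params.baseline not in rec.annotations:
        raise ValueError(
            f"no {params.baseline!r} annotation: a pre-ictal baseline interval is required"
        )
    grad = rec if rec.signal_kind == "gradient" else monopolar_to_gradient(rec)
    fs = grad.fs_lfp_hz
    b0, b1 = rec.annotations[params.baseline]
    i0, i1 = int(round(b0 * fs)), int(round(b1 * fs))
    base = grad.lfp[:, i0:i1]
    med = np.median(base, axis=1, keepdims=True)
    mad = np.median(np.abs(base - med), axis=1, keepdims=True)
    mad[mad == 0] = 1e-12
    z = (grad.lfp - med) / (1.4826 * mad)

    gap = max(1, int(round(params.merge_gap_ms / 1000.0 * fs)))
    dmin = params.min_duration_ms / 1000.0 * fs
    dmax = params.max_duration_ms / 1000.0 * fs
    ms_per_sample = 1000.0 / fs

    ch_rows = []
    for c in range(z.shape[0]):
        zc = z[c]
        mask = np.abs(zc) > params.amp_threshold
        if not mask.any():
            continue
        # slope in z/ms from a 3-sample-smoothed trace
        zs = np.convolve(zc, np.ones(3) / 3.0, mode="same")
        dz = np.gradient(zs) / ms_per_sample
        for a, b in _merge_runs(_runs_from_mask(mask), gap):
            dur = b - a
            if not (dmin <= dur <= dmax):
                continue
            seg = np.abs(zc[a:b])
            sl = dz[a:b] if np.mean(zc[a:b]) >= 0 else -dz[a:b]
            if sl.max(initial=-np.inf) < params.min_rise_slope:
                continue
            if (-sl).max(initial=-np.inf) < params.min_fall_slope:
                continue
            p = a + int(np.argmax(seg))
            ch_rows.append((p / fs, dur * ms_per_sample, c, float(np.abs(zc[p]))))

    if not ch_rows:
        empty = make_event_table([])
        return DischargeSet(empty, params, z.shape[0], make_event_table([]))

    ch = pd.DataFrame(ch_rows, columns=["time_s", "duration_ms", "channel", "peak_z"])
    ch = ch.sort_values("time_s", kind="mergesort").reset_index(drop=True)

    # collapse per-channel events into discharges
    win = params.cross_channel_window_ms / 1000.0
    t = ch["time_s"].to_numpy()
    cluster = np.zeros(len(ch), dtype=int)
    cid = 0
    for i in range(1, len(ch)):
        if t[i] - t[i - 1] > win:
            cid += 1
        cluster[i] = cid
    ch["cluster"] = cluster
    rows = []
    for _, g in ch.groupby("cluster"):
        k = g["peak_z"].idxmax()
        rows.append(
            (
                float(g["time_s"].median()),
                float(g["duration_ms"].median()),
                int(g.loc[k, "channel"]),
                float(g.loc[k, "peak_z"]),
            )
        )
    # discharge-level dedup: a biphasic discharge can yield a secondary
    # (rebound) cluster within its waveform extent; keep the stronger peak
    rows.sort(key=lambda r: r[0])
    min_sep = params.min_separation_ms / 1000.0
    dedup: list[tuple] = []
    for r in rows:
        if dedup and r[0] - dedup[-1][0] < min_sep:
            if r[3] > dedup[-1][3]:
                dedup[-1] = r
        else:
            dedup.append(r)
    times, durs, chans, amps = zip(*dedup)
    events = make_event_table(times, durs, chans, amps, label="discharge")
    return DischargeSet(events, params, z.shape[0], ch)


def evaluate_detection(
    detected_times_s,
    truth_times_s,
    duration_s: float,
    tol_ms: float = 50.0,
    bin_ms: float = 100.0,
) -> dict:
    """Score detections against ground truth.

    Returns sensitivity and precision from greedy one-to-one nearest
    matching within ``tol_ms``, binwise specificity = TN/(TN+FP) over
    ``bin_ms`` bins containing no true event (FP bins hold an *unmatched*
    detection), and the unmatched-detection rate per minute.
    """
    if tol_ms <= 0:
        raise ValueError("tol_ms must be > 0")
    det = np.sort(np.asarray(detected_times_s, dtype=float))
    tru = np.sort(np.asarray(truth_times_s, dtype=float))
    tol = tol_ms / 1000.0

    pairs = []
    if det.size and tru.size:
        for i, td in enumerate(det):
            j0 = np.searchsorted(tru, td - tol)
            j1 = np.searchsorted(tru, td + tol, side="right")
            for j in range(j0, j1):
                pairs.append((abs(td - tru[j]), i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    for _, i, j in pairs:
        if i not in used_d and j not in used_t:
            used_d.add(i)
            used_t.add(j)
    n_match = len(used_t)
    sensitivity = n_match / tru.size if tru.size else float("nan")
    precision = n_match / det.size if det.size else float("nan")

    n_bins = int(np.ceil(duration_s * 1000.0 / bin_ms))
    width = bin_ms / 1000.0
    truth_bins = set(np.minimum((tru / width).astype(int), n_bins - 1))
    unmatched = [det[i] for i in range(det.size) if i not in used_d]
    fp_bins = {
        b for b in np.minimum((np.asarray(unmatched) / width).astype(int), n_bins - 1)
        if b not in truth_bins
    } if unmatched else set()
    n_neg = n_bins - len(truth_bins)
    specificity = (n_neg - len(fp_bins)) / n_neg if n_neg else float("nan")
    false_per_min = len(unmatched) / (duration_s / 60.0)
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "false_per_min": false_per_min,
        "n_matched": n_match,
        "n_detected": int(det.size),
        "n_truth": int(tru.size),
    }
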