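"""Layer-group statistics of laminar CSD.

Contacts are partitioned into supragranular / granular / infragranular
groups (default for 24 contacts at 150 um pitch: 1-10 / 11-13 / 14-24,
superficial first; fully configurable).  Provided statistics:

* per-discharge peak-layer assignment and the zone x layer chi-square;
* per-recording normalized sink/source means and variances per group, with
  Welch t-tests across recordings;
* the sink<->source alternation index at a +50 ms lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .csd import CSDMatrix

GROUP_ORDER = ("supragranular", "granular", "infragranular")


@dataclass
class LayerPartition:
    """Contiguous, depth-ordered map of contact rows to layer groups."""

    groups: dict[str, np.ndarray]
    n_contacts: int

    def __post_init__(self) -> None:
        seen = np.concatenate([np.asarray(self.groups[g], dtype=int) for g in GROUP_ORDER])
        if not np.array_equal(np.sort(seen), np.arange(self.n_contacts)):
            raise ValueError("every contact must belong to exactly one group")
        prev_max = -1
        for g in GROUP_ORDER:
            idx = np.asarray(self.groups[g], dtype=int)
            if idx.size and (np.any(np.diff(idx) != 1) or idx.min() != prev_max + 1):
                raise ValueError("groups must be contiguous and ordered in depth")
            if idx.size:
                prev_max = idx.max()
        self.groups = {g: np.asarray(self.groups[g], dtype=int) for g in GROUP_ORDER}

    @classmethod
    def default(cls, n_contacts: int = 24) -> "LayerPartition":
        from .synthetic import default_layer_rows

        return cls(default_layer_rows(n_contacts), n_contacts)

    def group_of(self, contact: int) -> str:
        for g in GROUP_ORDER:
            if contact in self.groups[g]:
                return g
        raise IndexError(contact)

    def labels(self) -> np.ndarray:
        lab = np.empty(self.n_contacts, dtype=object)
        for g in GROUP_ORDER:
            lab[self.groups[g]] = g
        return lab


def peak_layer_counts(
    csd: CSDMatrix,
    event_times_s,
    partition: LayerPartition,
    window_ms: float = 25.0,
) -> dict[str, int]:
    """Count, per layer group, the contact of maximum |CSD| in a +/-window
    around each event peak.  Ties go to the deepest tied contact."""
    counts = {g: 0 for g in GROUP_ORDER}
    half = int(round(window_ms / 1000.0 * csd.fs_hz))
    n = csd.values.shape[1]
    for t in np.atleast_1d(np.asarray(event_times_s, dtype=float)):
        s = csd.sample_at(t)
        seg = np.abs(csd.values[:, max(0, s - half) : min(n, s + half + 1)])
        if seg.size == 0:
            raise ValueError(f"event at {t} s outside CSD time range")
        prof = seg.max(axis=1)
        best = np.max(prof)
        contact = int(np.nonzero(prof == best)[0][-1])  # deepest tied contact
        counts[partition.group_of(contact + csd.first_contact)] += 1
    return counts


def zone_layer_chi2(
    counts_onset, counts_outside, rng_seed: int = 0
) -> tuple[float, float]:
    """Pearson chi-square (df=2) on the 2x3 zone-by-layer count table, with a
    seeded permutation fallback when an expected cell drops below 5."""
    table = np.asarray([list(counts_onset), list(counts_outside)], dtype=float)
    if table.shape != (2, 3):
        raise ValueError("expected two 3-vectors of counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero row or column margin")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected < 5):
        warnings.warn("expected cell count < 5; using permutation test", RuntimeWarning)
        res = stats.chi2_contingency(table, correction=False)
        perm = _permutation_chi2(table, res.statistic, rng_seed)
        return float(res.statistic), perm
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def _permutation_chi2(
    table: np.ndarray, observed: float, seed: int, n_perm: int = 99999
) -> float:
    """Conditional (fixed-margin) permutation p-value, sampled with
    vectorized multivariate-hypergeometric draws."""
    rng = np.random.default_rng(seed)
    col = table.sum(axis=0).astype(int)
    n1 = int(table[0].sum())
    n = int(col.sum())
    x1 = rng.hypergeometric(col[0], n - col[0], n1, size=n_perm)
    x2 = rng.hypergeometric(col[1], n - col[0] - col[1], n1 - x1)
    x3 = n1 - x1 - x2
    row1 = np.stack([x1, x2, x3], axis=1).astype(float)
    row2 = col[None, :] - row1
    expected = stats.contingency.expected_freq(table)
    stat = ((row1 - expected[0]) ** 2 / expected[0]).sum(axis=1)
    stat += ((row2 - expected[1]) ** 2 / expected[1]).sum(axis=1)
    count = int(np.sum(stat >= observed - 1e-12))
    return (count + 1) / (n_perm + 1)


@dataclass
class LayerStatsReport:
    per_recording: pd.DataFrame   # recording, group, polarity, mean, variance, n
    tests: pd.DataFrame           # polarity, statistic x {mean, variance}, t, p
    zone: str
    characteristic_groups: tuple[str, ...]


def sink_source_layer_stats(
    csds: list[CSDMatrix],
    partition: LayerPartition,
    zone: str,
    ictal_intervals: list[tuple[float, float]] | None = None,
) -> LayerStatsReport:
    """Normalized sink/source mean and variance per layer group and
    recording, plus Welch t-tests comparing the zone-characteristic groups
    (granular+infragranular inside the onset zone, supragranular outside)
    against the remaining groups across recordings."""
    rows = []
    for r, csd in enumerate(csds):
        if csd.normalized != "sink01_sourceneg1":
            raise ValueError("sink/source stats need normalized CSD")
        vals = csd.slice(*ictal_intervals[r]) if ictal_intervals else csd.values
        for g in GROUP_ORDER:
            idx = partition.groups[g] - csd.first_contact
            idx = idx[(idx >= 0) & (idx < csd.n_channels)]
            if idx.size == 0:
                warnings.warn(f"group {g} has no contacts; skipped", RuntimeWarning)
                continue
            sub = vals[idx]
            for polarity, sel in (("sink", sub[sub > 0]), ("source", sub[sub < 0])):
                rows.append(
                    {
                        "recording": r,
                        "group": g,
                        "polarity": polarity,
                        "mean": float(sel.mean()) if sel.size else 0.0,
                        "variance": float(sel.var()) if sel.size else 0.0,
                        "n": int(sel.size),
                    }
                )
    per_rec = pd.DataFrame(rows)

    char = ("granular", "infragranular") if zone == "onset" else ("supragranular",)
    tests = []
    for polarity in ("sink", "source"):
        sub = per_rec[per_rec["polarity"] == polarity]
        for stat_col in ("mean", "variance"):
            a = sub[sub["group"].isin(char)].groupby("recording")[stat_col].mean()
            b = sub[~sub["group"].isin(char)].groupby("recording")[stat_col].mean()
            if len(a) >= 2 and len(b) >= 2:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            else:
                t, p = np.nan, np.nan
            tests.append({"polarity": polarity, "statistic": stat_col,
                          "t": float(t), "p": float(p)})
    return LayerStatsReport(per_rec, pd.DataFrame(tests), zone, char)


def alternation_index(
    csd: CSDMatrix,
    event_times_s,
    lag_ms: float = 50.0,
    noise_floor: np.ndarray | float | None = None,
    baseline_interval: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-contact fraction of events whose CSD sign flips ``lag_ms`` later.

    Contacts whose |CSD| at the event is below the noise floor (default:
    1 robust SD of baseline CSD per contact) are excluded from that event's
    denominator; contacts with an empty denominator return NaN.
    """
    times = np.atleast_1d(np.asarray(event_times_s, dtype=float))
    lag = int(round(lag_ms / 1000.0 * csd.fs_hz))
    n = csd.values.shape[1]
    if noise_floor is None:
        if baseline_interval is not None:
            base = csd.slice(*baseline_interval)
        else:
            base = csd.values
        med = np.median(base, axis=1, keepdims=True)
        noise_floor = 1.4826 * np.median(np.abs(base - med), axis=1)
    floor = np.broadcast_to(np.asarray(noise_floor, dtype=float), (csd.n_channels,))

    flips = np.zeros(csd.n_channels)
    denom = np.zeros(csd.n_channels)
    for t in times:
        s = csd.sample_at(t)
        if s < 0 or s + lag >= n:
            continue
        v0 = csd.values[:, s]
        v1 = csd.values[:, s + lag]
        active = np.abs(v0) > floor
        denom += active
        flips += active & (np.sign(v0) != np.sign(v1))
    if not denom.any():
        raise ValueError("no event has both samples in range above the noise floor")
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, flips / denom, np.nan)
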