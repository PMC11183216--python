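"""Filtering, line-noise removal, bad-channel handling, signal-kind conversion.

All filters are zero-phase (4th-order IIR applied forward-backward).  The
LFP band is band-passed 0.2-500 Hz and the MUA band high-passed above
300 Hz by default (a 200-5000 Hz band-pass is available).  Line noise is
removed with a 2 Hz-bandwidth notch at 50 or 60 Hz.  Channels flagged bad
are linearly interpolated, in depth, from the nearest good neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, iirnotch, filtfilt, sosfiltfilt, tf2sos

from .io import LaminarRecording


class StateError(RuntimeError):
    """Operation applied to a recording in the wrong signal state."""


@dataclass
class PreprocessParams:
    lfp_band_hz: tuple[float, float] = (0.2, 500.0)
    mua_highpass_hz: float = 300.0
    mua_band_hz: tuple[float, float] | None = None  # e.g. (200, 5000)
    notch_bandwidth_hz: float = 2.0
    artifact_z_threshold: float = 10.0
    max_bad_fraction: float = 0.25

    def __post_init__(self) -> None:
        lo, hi = self.lfp_band_hz
        if not 0 < lo < hi:
            raise ValueError("LFP band edges must satisfy 0 < low < high")
        if self.notch_bandwidth_hz <= 0:
            raise ValueError("notch bandwidth must be > 0")


def _check_nyquist(edge: float, fs: float, what: str) -> None:
    if edge >= fs / 2:
        raise ValueError(f"{what} edge {edge} Hz is at or above Nyquist ({fs / 2} Hz)")


def filter_bands(
    rec: LaminarRecording, params: PreprocessParams | None = None, notch: bool = True
) -> LaminarRecording:
    """Band-limit the LFP and MUA bands, zero-phase, optionally notching the
    recording's line frequency out of the LFP band."""
    params = params or PreprocessParams()
    lo, hi = params.lfp_band_hz
    _check_nyquist(hi, rec.fs_lfp_hz, "LFP band high")
    sos = butter(4, [lo, hi], btype="bandpass", fs=rec.fs_lfp_hz, output="sos")
    lfp = sosfiltfilt(sos, rec.lfp, axis=1)
    if notch:
        lfp = notch_filter(lfp, rec.fs_lfp_hz, rec.line_freq_hz, params.notch_bandwidth_hz)

    mua = rec.mua
    if mua is not None:
        if params.mua_band_hz is not None:
            mlo, mhi = params.mua_band_hz
            _check_nyquist(mhi, rec.fs_mua_hz, "MUA band high")
            msos = butter(4, [mlo, mhi], btype="bandpass", fs=rec.fs_mua_hz, output="sos")
        else:
            _check_nyquist(params.mua_highpass_hz, rec.fs_mua_hz, "MUA high-pass")
            msos = butter(4, params.mua_highpass_hz, btype="highpass", fs=rec.fs_mua_hz, output="sos")
        mua = sosfiltfilt(msos, mua.astype(np.float64), axis=1).astype(np.float32)
    return rec.copy_with(lfp=lfp, mua=mua)


def notch_filter(x: np.ndarray, fs: float, f0: float, bandwidth_hz: float = 2.0) -> np.ndarray:
    """Zero-phase notch at ``f0`` with the given -3 dB bandwidth."""
    b, a = iirnotch(f0, f0 / bandwidth_hz, fs=fs)
    return sosfiltfilt(tf2sos(b, a), x, axis=1)


def interpolate_bad_channels(rec: LaminarRecording, bad: list[int]) -> LaminarRecording:
    """Replace bad channels by depth-linear interpolation between the nearest
    good channels above and below; edge channels copy the nearest good one."""
    n = rec.lfp.shape[0]
    bad = sorted(set(int(b) for b in bad))
    if any(b < 0 or b >= n for b in bad):
        raise IndexError("bad channel index out of range")
    good = np.array([i for i in range(n) if i not in bad])
    if good.size == 0:
        raise ValueError("unrecoverable recording: all channels bad")
    lfp = rec.lfp.copy()
    for b in bad:
        above = good[good < b]
        below = good[good > b]
        if above.size and below.size:
            i, j = above.max(), below.min()
            w = (b - i) / (j - i)
            lfp[b] = (1 - w) * lfp[i] + w * lfp[j]
        else:  # edge: copy nearest good neighbour
            nearest = good[np.argmin(np.abs(good - b))]
            lfp[b] = lfp[nearest]
    status = rec.channel_status.copy()
    status[bad] = True  # interpolated channels are usable downstream
    return rec.copy_with(lfp=lfp, channel_status=status)


def flag_bad_channels(rec: LaminarRecording, z_threshold: float = 10.0,
                      max_fraction: float = 0.25) -> list[int]:
    """Automated replacement for visual channel rejection: flag channels whose
    robust amplitude (MAD of the channel) is an outlier among channels."""
    amp = np.median(np.abs(rec.lfp - np.median(rec.lfp, axis=1, keepdims=True)), axis=1)
    med = np.median(amp)
    mad = np.median(np.abs(amp - med)) or 1e-12
    z = (amp - med) / (1.4826 * mad)
    bad = list(np.nonzero(np.abs(z) > z_threshold)[0])
    if len(bad) > max_fraction * rec.lfp.shape[0]:
        raise ValueError(
            f"{len(bad)} channels flagged bad, exceeding the {max_fraction:.0%} guard"
        )
    return bad


def flag_artifact_intervals(
    rec: LaminarRecording, z_threshold: float = 10.0, pad_ms: float = 100.0
) -> list[tuple[float, float]]:
    """Automated amplitude-artifact flagger: intervals where any channel's
    robust z exceeds the threshold, padded and merged."""
    med = np.median(rec.lfp, axis=1, keepdims=True)
    mad = np.median(np.abs(rec.lfp - med), axis=1, keepdims=True)
    mad[mad == 0] = 1e-12
    z = (rec.lfp - med) / (1.4826 * mad)
    mask = np.any(np.abs(z) > z_threshold, axis=0)
    if not mask.any():
        return []
    pad = int(round(pad_ms / 1000.0 * rec.fs_lfp_hz))
    idx = np.nonzero(mask)[0]
    intervals: list[tuple[float, float]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > 2 * pad:
            intervals.append((start, prev))
            start = i
        prev = i
    intervals.append((start, prev))
    fs = rec.fs_lfp_hz
    return [
        (max(0.0, (a - pad) / fs), min(rec.duration_s, (b + pad) / fs))
        for a, b in intervals
    ]


def monopolar_to_gradient(rec: LaminarRecording) -> LaminarRecording:
    """Successive-contact potential gradient, g[i] = phi[i+1] - phi[i]
    (deep minus superficial); n_contacts - 1 rows."""
    if rec.signal_kind != "monopolar":
        raise StateError("recording is not monopolar")
    return rec.copy_with(
        lfp=np.diff(rec.lfp, axis=0),
        signal_kind="gradient",
        channel_status=rec.channel_status[:-1] & rec.channel_status[1:],
    )


def gradient_to_monopolar(rec: LaminarRecording) -> LaminarRecording:
    """Cumulative-sum reconstruction of monopolar potentials with a zero
    reference at the virtual contact above the array (known only up to that
    reference constant)."""
    if rec.signal_kind != "gradient":
        raise StateError("recording is not gradient")
    n1, m = rec.lfp.shape
    mono = np.zeros((n1 + 1, m))
    mono[1:] = np.cumsum(rec.lfp, axis=0)
    return rec.copy_with(
        lfp=mono,
        signal_kind="monopolar",
        channel_status=np.ones(n1 + 1, dtype=bool),
    )
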