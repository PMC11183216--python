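"""Current-source-density estimation and sink/source normalization.

CSD is the second spatial difference of the monopolar laminar LFP,
csd[i] = (phi[i-1] - 2 phi[i] + phi[i+1]) / h^2, with the sign convention
that a potential minimum in depth (a current sink) is positive.  Edge
contacts are handled by appending pseudo-channels (zeros by default, the
classical duplicate-edge variant is available), and the profile is
optionally smoothed with a 5-point Hamming window.  Sinks and sources are
normalized to [0, 1] and [-1, 0] respectively for cross-recording
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import LaminarRecording
from .preprocess import StateError

HAMMING5 = np.array([0.08, 0.54, 1.0, 0.54, 0.08])
HAMMING5_NORM = HAMMING5 / HAMMING5.sum()


@dataclass
class CSDMatrix:
    """channels x samples CSD values (arbitrary units; sinks positive)."""

    values: np.ndarray
    spacing_um: float
    fs_hz: float
    smoothing: str = "none"          # none | hamming5
    normalized: str = "raw"          # raw | sink01_sourceneg1
    first_contact: int = 0           # row 0 corresponds to this contact index

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.values.shape[1] / self.fs_hz

    def sample_at(self, t_s: float) -> int:
        return int(round(t_s * self.fs_hz))

    def slice(self, t0: float, t1: float) -> np.ndarray:
        return self.values[:, max(0, self.sample_at(t0)) : self.sample_at(t1)]


def _hamming5_matrix(n: int) -> np.ndarray:
    """Dense spatial smoothing operator: length-5 Hamming kernel normalized
    to unit sum, truncated and renormalized at the edges."""
    w = np.zeros((n, n))
    for i in range(n):
        lo, hi = max(0, i - 2), min(n, i + 3)
        k = HAMMING5[(lo - i + 2) : (hi - i + 2)]
        w[i, lo:hi] = k / k.sum()
    return w


def compute_csd(
    rec: LaminarRecording | np.ndarray,
    spacing_um: float | None = None,
    fs_hz: float | None = None,
    vaknin: bool = True,
    smooth: bool = True,
    edge_mode: str = "zeros",
) -> CSDMatrix:
    """Second-spatial-difference CSD of a monopolar laminar LFP.

    With ``vaknin=True`` pseudo-channels are appended above and below the
    array (``edge_mode='zeros'`` per the hardware convention here, or
    ``'duplicate'`` for the classical variant), yielding n output channels;
    otherwise only the n-2 interior channels are returned.
    """
    if isinstance(rec, LaminarRecording):
        if rec.signal_kind != "monopolar":
            raise StateError("CSD requires monopolar LFP; convert the gradient first")
        lfp, spacing_um, fs_hz = rec.lfp, rec.spacing_um, rec.fs_lfp_hz
    else:
        lfp = np.asarray(rec, dtype=float)
        if spacing_um is None or fs_hz is None:
            raise ValueError("spacing_um and fs_hz are required for array input")
    one_d = lfp.ndim == 1
    if one_d:
        lfp = lfp[:, None]
    n = lfp.shape[0]
    if n < 3:
        raise ValueError("CSD needs at least 3 contacts")
    h = spacing_um / 1000.0  # mm

    if vaknin:
        if edge_mode == "zeros":
            top = np.zeros((1, lfp.shape[1]))
            bot = np.zeros((1, lfp.shape[1]))
        elif edge_mode == "duplicate":
            top, bot = lfp[:1], lfp[-1:]
        else:
            raise ValueError(f"unknown edge_mode {edge_mode!r}")
        padded = np.vstack([top, lfp, bot])
        values = (padded[:-2] - 2 * padded[1:-1] + padded[2:]) / (h * h)
        first = 0
    else:
        values = (lfp[:-2] - 2 * lfp[1:-1] + lfp[2:]) / (h * h)
        first = 1

    smoothing = "none"
    if smooth:
        values = _hamming5_matrix(values.shape[0]) @ values
        smoothing = "hamming5"
    if one_d:
        values = values[:, 0]
    return CSDMatrix(values, spacing_um, fs_hz, smoothing=smoothing, first_contact=first)


def rescale_sinks_sources(
    csd: CSDMatrix, scope: tuple[float, float] | None = None, invert: bool = False
) -> CSDMatrix:
    """Map sinks (positive CSD) to [0, 1] and sources (negative) to [-1, 0].

    ``scope`` restricts the min/max reference to a time interval (seconds),
    typically the annotated ictal interval; the whole matrix is rescaled
    with those bounds.  ``invert=True`` reproduces the orientation-flipping
    literal rescaling formula (min -> 1, max -> 0) instead of the standard
    one.
    """
    if csd.normalized != "raw":
        raise ValueError("CSD is already normalized")
    x = csd.values
    ref = csd.slice(*scope) if scope is not None else x

    out = np.zeros_like(x, dtype=float)
    if not (np.any(ref > 0) or np.any(ref < 0)):
        warnings.warn("degenerate CSD range: all values are zero", RuntimeWarning)
        return CSDMatrix(out, csd.spacing_um, csd.fs_hz, csd.smoothing,
                         "sink01_sourceneg1", csd.first_contact)

    def _unit(v, lo, hi):
        if hi - lo <= 0:
            warnings.warn("degenerate range in rescaling", RuntimeWarning)
            return np.ones_like(v)
        u = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
        return 1.0 - u if invert else u

    # zeros count towards the sink-side minimum reference, so {0, 2, 4}
    # rescales to {0, 0.5, 1}
    pos = x > 0
    neg = x < 0
    if np.any(ref > 0):
        out[pos] = _unit(x[pos], ref[ref >= 0].min(), ref.max())
    if np.any(ref < 0):
        out[neg] = -_unit(-x[neg], -ref[ref <= 0].max(), -ref.min())
    return CSDMatrix(out, csd.spacing_um, csd.fs_hz, csd.smoothing,
                     "sink01_sourceneg1", csd.first_contact)
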