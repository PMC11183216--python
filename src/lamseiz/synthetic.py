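"""Synthetic laminar seizure generator with full ground truth.

Recordings are built through an explicit forward model: each ictal discharge
is a prescribed zero-sum laminar current-source-density (CSD) motif whose
extracellular potential profile is the exact discrete antiderivative of the
second-difference CSD operator (zero virtual boundary channels above and
below the array).  The analysis stages can therefore be validated against
known discharge times, motifs, phase schedules and multi-unit spike trains.

The default configurations emulate two recording situations:

* ``onset`` zone — two temporally disjoint deep motifs.  Discharge rate
  ramps from 1.3 Hz (mean over the first second) to 8.9 Hz over the first
  5.3 s (motif 1: sinks at the top and bottom of the infragranular cortex
  flanking a source), then stays at 7.1 Hz for 57 s (motif 2: superficial
  infragranular sink over a deep source).
* ``propagation`` zone — a single supragranular motif active throughout,
  with additional granular weights switching on at 28 % of normalized
  seizure time and infragranular weights at 42 %.

Each discharge kernel is biphasic: a raised-cosine main lobe (0-50 ms)
followed by a smaller rebound lobe (60-90 ms) whose spatial polarity is
inverted, so every sink at the discharge peak becomes a source 50 ms later
(alternation probability configurable, default 1).  Amplitudes are in
arbitrary units because extracellular conductivity is not modelled; the
discharge peak is calibrated to ``discharge_snr`` times the pink-noise SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded
from scipy.signal import fftconvolve

from .io import LaminarRecording

LAYER_GROUPS = ("supragranular", "granular", "infragranular")


class ConservationError(ValueError):
    pass


def forward_lfp_from_csd(csd_profile: np.ndarray, spacing_um: float = 150.0) -> np.ndarray:
    """Potential snapshot whose second spatial difference is ``csd_profile``.

    Solves (phi[i-1] - 2 phi[i] + phi[i+1]) / h^2 = csd[i] with zero virtual
    boundary potentials, i.e. the exact inverse of the CSD estimator used in
    :mod:`lamseiz.csd` with zero (Vaknin-style) edge padding.
    """
    c = np.asarray(csd_profile, dtype=float)
    if c.ndim != 1 or c.size < 3:
        raise ValueError("csd_profile must be 1-D with length >= 3")
    total = c.sum()
    # tolerance covers float cancellation when zero-summing large profiles
    tol = 1e-8 * c.size * max(1.0, float(np.abs(c).max(initial=0.0)))
    if abs(total) > tol:
        raise ConservationError(
            f"csd_profile must conserve current (zero sum); got sum={total:g}"
        )
    n = c.size
    h = spacing_um / 1000.0  # mm
    ab = np.zeros((3, n))
    ab[0, 1:] = 1.0
    ab[1, :] = -2.0
    ab[2, :-1] = 1.0
    return solve_banded((1, 1), ab, c * h * h)


@dataclass
class DischargeWaveform:
    """Biphasic temporal kernel of a single ictal discharge.

    A raised-cosine main lobe on [0, main_ms] and a rebound lobe of relative
    amplitude ``rebound_amp`` on [rebound_start_ms, duration_ms].  The
    rebound carries the spatially inverted motif when alternation occurs;
    its peak sits at main-peak + 50 ms so that the CSD sign 50 ms after the
    discharge peak is reliably flipped.
    """

    duration_ms: float = 90.0
    main_ms: float = 50.0
    rebound_start_ms: float = 60.0
    rebound_amp: float = 0.35
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("waveform duration must be > 0")
        if not (0 < self.main_ms <= self.rebound_start_ms <= self.duration_ms):
            raise ValueError("waveform lobes must be ordered and positive")

    @property
    def peak_offset_ms(self) -> float:
        return self.main_ms / 2.0

    def lobes(self, fs_hz: float) -> tuple[np.ndarray, np.ndarray]:
        """Sampled (main, rebound) lobes, both non-negative, peak(main)=amplitude."""
        n = int(round(self.duration_ms / 1000.0 * fs_hz))
        t = np.arange(n) / fs_hz * 1000.0  # ms
        main = np.zeros(n)
        m = t < self.main_ms
        main[m] = self.amplitude * np.sin(np.pi * t[m] / self.main_ms) ** 2
        reb = np.zeros(n)
        width = self.duration_ms - self.rebound_start_ms
        r = t >= self.rebound_start_ms
        reb[r] = (
            self.amplitude
            * self.rebound_amp
            * np.sin(np.pi * (t[r] - self.rebound_start_ms) / width) ** 2
        )
        return main, reb


@dataclass
class LaminarMotif:
    """Spatial CSD motif of a discharge class, plus its MUA depth profile.

    ``group_profiles`` holds optional zero-sum add-on profiles per layer
    group that switch on at fractions of normalized seizure time given by a
    phase's ``recruitment_schedule``.
    """

    motif_id: str
    csd_profile: np.ndarray
    waveform: DischargeWaveform = field(default_factory=DischargeWaveform)
    alternation_lag_ms: float = 50.0
    alternation_prob: float = 1.0
    mua_depth_profile: np.ndarray | None = None
    group_profiles: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.csd_profile = np.asarray(self.csd_profile, dtype=float)
        scale = np.abs(self.csd_profile).sum() or 1.0
        if abs(self.csd_profile.sum()) > 1e-9 * scale:
            raise ConservationError(f"motif {self.motif_id}: csd_profile must be zero-sum")
        for g, p in self.group_profiles.items():
            p = np.asarray(p, dtype=float)
            if abs(p.sum()) > 1e-9 * (np.abs(p).sum() or 1.0):
                raise ConservationError(f"motif {self.motif_id}: group profile {g} not zero-sum")
            self.group_profiles[g] = p
        if self.mua_depth_profile is None:
            self.mua_depth_profile = np.zeros_like(self.csd_profile)
        self.mua_depth_profile = np.asarray(self.mua_depth_profile, dtype=float)
        if np.any(self.mua_depth_profile < 0):
            raise ValueError("mua_depth_profile must be >= 0")

    @property
    def n_contacts(self) -> int:
        return self.csd_profile.size


@dataclass
class PhaseSpec:
    """One seizure phase: a linear discharge-rate ramp and its active motif."""

    duration_s: float
    rate_start_hz: float
    rate_end_hz: float
    motif_id: str
    recruitment_schedule: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("phase duration must be > 0")
        if self.rate_start_hz < 0 or self.rate_end_hz < 0:
            raise ValueError("rates must be >= 0")
        for g, f in self.recruitment_schedule.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"recruitment fraction for {g} must be in [0,1]")

    def rate_at(self, t_in_phase: float) -> float:
        u = np.clip(t_in_phase / self.duration_s, 0.0, 1.0)
        return self.rate_start_hz + (self.rate_end_hz - self.rate_start_hz) * u


@dataclass
class NoiseSpec:
    pink_sigma: float = 20.0       # per-channel 1/f noise SD, arbitrary units (uV-like)
    line_freq_hz: float = 60.0
    line_amplitude: float = 5.0
    common_mode_sigma: float = 0.0  # shared-across-channels pink noise, off by default
    mua_white_sigma: float = 5.0


@dataclass
class SimulationConfig:
    n_contacts: int = 24
    spacing_um: float = 150.0
    fs_lfp_hz: float = 2000.0
    fs_mua_hz: float = 20000.0
    zone: str = "onset"
    preictal_s: float = 10.0
    phases: list[PhaseSpec] = field(default_factory=list)
    motifs: dict[str, LaminarMotif] = field(default_factory=dict)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    discharge_snr: float = 10.0       # peak gradient amplitude / gradient noise SD
    mua_spike_rate_peak_hz: float = 150.0
    mua_baseline_hz: float = 2.0
    interictal_spike_rate_hz: float = 0.0
    include_mua: bool = True

    def __post_init__(self) -> None:
        if self.n_contacts < 5:
            raise ValueError("n_contacts must be >= 5 (CSD needs interior channels)")
        if self.preictal_s < 10.0:
            raise ValueError("preictal_s must be >= 10 (baseline rule)")
        if self.fs_mua_hz <= 2 * self.fs_lfp_hz:
            raise ValueError("fs_mua_hz must exceed 2x fs_lfp_hz")
        if self.noise.line_freq_hz not in (50.0, 60.0):
            raise ValueError("line frequency must be 50 or 60 Hz")

    @property
    def seizure_duration_s(self) -> float:
        return float(sum(p.duration_s for p in self.phases))

    @property
    def duration_s(self) -> float:
        return self.preictal_s + self.seizure_duration_s


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    discharge_times_s: np.ndarray            # times of the discharge main peak
    discharge_motif_ids: list[str]
    discharge_alternated: np.ndarray         # bool per discharge
    phase_boundaries_s: np.ndarray           # absolute, len = n_phases + 1
    recruitment_onset_fractions: dict[str, float]
    mua_spike_times: list[np.ndarray]
    seizure_onset_s: float
    seizure_end_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.discharge_times_s, dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError("discharge times must be sorted")
        if not self.seizure_onset_s < self.seizure_end_s:
            raise ValueError("seizure onset must precede end")
        self.discharge_times_s = t


# ---------------------------------------------------------------------------
# Default configurations (study conditions)
# ---------------------------------------------------------------------------

def ramp_endpoints_from_second_means(
    first_second_hz: float, last_second_hz: float, duration_s: float
) -> tuple[float, float]:
    """Endpoint rates of a linear ramp whose *mean* rate over the first and
    last 1-s windows of the phase equals the given values (the convention in
    which ramping discharge frequencies are reported)."""
    if duration_s <= 1.0:
        return first_second_hz, last_second_hz
    slope = (last_second_hz - first_second_hz) / (duration_s - 1.0)
    start = first_second_hz - 0.5 * slope
    return start, start + slope * duration_s


def _profile(n: int, entries: dict[int, float]) -> np.ndarray:
    p = np.zeros(n)
    for i, v in entries.items():
        p[i] = v
    return p


def default_layer_rows(n_contacts: int = 24) -> dict[str, np.ndarray]:
    """Default contact->layer-group map (rows, superficial first):
    supragranular 0-9, granular 10-12, infragranular 13-23 for 24 contacts;
    proportionally scaled otherwise."""
    sup = int(round(n_contacts * 10 / 24))
    gra = int(round(n_contacts * 13 / 24))
    return {
        "supragranular": np.arange(0, sup),
        "granular": np.arange(sup, gra),
        "infragranular": np.arange(gra, n_contacts),
    }


def onset_motifs(n_contacts: int = 24) -> dict[str, LaminarMotif]:
    """Deep motifs of the seizure-onset zone.

    Motif 1 (initial): sinks in the granular/upper-infragranular cortex and
    in the deepest infragranular contacts, flanking a mid-infragranular
    source.  Motif 2 (sustained): a sink spanning the granular and upper
    infragranular cortex over a source in the deepest contacts.
    """
    if n_contacts != 24:
        raise ValueError("default onset motifs are defined for 24 contacts")
    infra_ramp = np.zeros(24)
    infra_ramp[13:] = np.exp((np.arange(13, 24) - 13) / 3.5)
    infra_ramp /= infra_ramp.max()
    p1 = _profile(24, {11: 1, 12: 1, 13: 1, 22: 1, 23: 1,
                       16: -1, 17: -1, 18: -1, 19: -1, 20: -1})
    p2 = _profile(24, {10: 1, 11: 1, 12: 1, 13: 1, 14: 1, 15: 1, 16: 1,
                       21: -7 / 3, 22: -7 / 3, 23: -7 / 3})
    return {
        "onset_initial": LaminarMotif("onset_initial", p1, mua_depth_profile=infra_ramp),
        "onset_sustained": LaminarMotif("onset_sustained", p2, mua_depth_profile=infra_ramp),
    }


def propagation_motifs(n_contacts: int = 24) -> dict[str, LaminarMotif]:
    """Supragranular motif with progressive deep recruitment."""
    if n_contacts != 24:
        raise ValueError("default propagation motifs are defined for 24 contacts")
    base = _profile(24, {1: 1, 2: 1, 3: 1, 5: -1, 6: -1, 7: -1})
    gran = 0.9 * _profile(24, {10: 1, 11: 1, 12: -2})
    infra = 0.35 * _profile(24, {13: 1, 14: 1, 15: 1, 16: 1, 20: -1, 21: -1, 22: -1, 23: -1})
    mua = np.zeros(24)
    mua[0:5] = 1.0       # superficial half of the supragranular layers
    mua[10:13] = 0.4
    mua[13:18] = 0.25
    return {
        "propagation": LaminarMotif(
            "propagation",
            base,
            mua_depth_profile=mua,
            group_profiles={"granular": gran, "infragranular": infra},
        )
    }


def default_onset_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Onset-zone study conditions: 5.3 s ramp (1.3 -> 8.9 Hz as first/last
    second means) then 57 s at a constant 7.1 Hz."""
    r0, r1 = ramp_endpoints_from_second_means(1.3, 8.9, 5.3)
    phases = [
        PhaseSpec(5.3, r0, r1, "onset_initial"),
        PhaseSpec(57.0, 7.1, 7.1, "onset_sustained"),
    ]
    cfg = SimulationConfig(
        zone="onset", phases=phases, motifs=onset_motifs(), seed=seed, **overrides
    )
    return cfg


def default_propagation_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Propagation-zone study conditions: one 60 s phase at 7.1 Hz, granular
    recruitment at 28 % and infragranular at 42 % of normalized time."""
    phases = [
        PhaseSpec(
            60.0,
            7.1,
            7.1,
            "propagation",
            recruitment_schedule={"granular": 0.28, "infragranular": 0.42},
        )
    ]
    return SimulationConfig(
        zone="propagation", phases=phases, motifs=propagation_motifs(), seed=seed, **overrides
    )


def default_config(zone: str, seed: int = 0, **overrides) -> SimulationConfig:
    if zone == "onset":
        return default_onset_config(seed, **overrides)
    if zone == "propagation":
        return default_propagation_config(seed, **overrides)
    raise ValueError(f"no default motif set for zone {zone!r}")


# ---------------------------------------------------------------------------
# Event-train generation
# ---------------------------------------------------------------------------

def _draw_discharge_onsets(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Inhomogeneous Poisson onsets with a dead time equal to the waveform
    duration, generated by thinning of the renewal hazard lambda/(1 - lambda*d)
    so that the *realized* rate matches the configured ramp."""
    onset = config.preictal_s
    end = onset + config.seizure_duration_s
    bounds = np.cumsum([onset] + [p.duration_s for p in config.phases])

    def phase_at(t: float) -> int:
        return int(np.searchsorted(bounds, t, side="right") - 1)

    def rate(t: float) -> float:
        k = min(phase_at(t), len(config.phases) - 1)
        return config.phases[k].rate_at(t - bounds[k])

    dead = {
        pid: config.motifs[p.motif_id].waveform.duration_ms / 1000.0
        for pid, p in enumerate(config.phases)
    }

    def hazard(t: float) -> float:
        k = min(phase_at(t), len(config.phases) - 1)
        lam = rate(t)
        ld = min(lam * dead[k], 0.95)
        return lam / (1.0 - ld) if lam > 0 else 0.0

    h_max = 0.0
    for k, p in enumerate(config.phases):
        for lam in (p.rate_start_hz, p.rate_end_hz):
            ld = min(lam * dead[k], 0.95)
            h_max = max(h_max, lam / (1.0 - ld) if lam > 0 else 0.0)
    times = []
    phase_ids = []
    if h_max > 0:
        t = onset
        while True:
            t += rng.exponential(1.0 / h_max)
            if t >= end:
                break
            if rng.uniform() * h_max < hazard(t):
                k = min(phase_at(t), len(config.phases) - 1)
                if t + dead[k] <= end:  # whole waveform must fit in the seizure
                    times.append(t)
                    phase_ids.append(k)
                    t += dead[k]
            # rejected proposals just advance the clock
    return np.asarray(times), np.asarray(phase_ids, dtype=int)


def _pink_noise(n_samples: int, n_channels: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-power noise, unit SD per channel scaled to ``sigma``."""
    if sigma == 0:
        return np.zeros((n_channels, n_samples))
    from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

    nfft = next_fast_len(n_samples)
    white = rng.standard_normal((n_channels, nfft))
    spec = rfft(white, axis=1)
    freqs = rfftfreq(nfft)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= amp
    x = irfft(spec, n=nfft, axis=1)[:, :n_samples]
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return sigma * x / sd


def _mua_spike_template(fs_hz: float) -> np.ndarray:
    """1 ms biphasic extracellular spike template (negative-first), peak 1."""
    n = int(round(fs_hz / 1000.0))
    t = np.arange(n) / n
    return -np.sin(2 * np.pi * t) * np.sin(np.pi * t)


def _active_profile(motif: LaminarMotif, schedule: dict[str, float], frac: float) -> tuple[np.ndarray, str]:
    prof = motif.csd_profile.copy()
    key = [motif.motif_id]
    for g in sorted(motif.group_profiles):
        if schedule.get(g) is not None and frac >= schedule[g]:
            prof += motif.group_profiles[g]
            key.append(g)
    return prof, "+".join(key)


def simulate_seizure(config: SimulationConfig) -> tuple[LaminarRecording, GroundTruth]:
    """Simulate one laminar seizure recording.

    Identical configs (including seed) give bit-identical output.  Event
    times, LFP noise and the MUA band are drawn from independently spawned
    RNG streams, so disabling the MUA band does not perturb the others.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_events, rng_lfp, rng_mua = (np.random.default_rng(s) for s in ss.spawn(3))

    for p in config.phases:
        if p.motif_id not in config.motifs:
            raise KeyError(f"phase motif {p.motif_id!r} missing from motif table")
        if config.motifs[p.motif_id].n_contacts != config.n_contacts:
            raise ValueError("motif profile length must equal n_contacts")

    fs = config.fs_lfp_hz
    n_samples = int(round(config.duration_s * fs))
    onset = config.preictal_s
    end = onset + config.seizure_duration_s
    bounds = np.cumsum([onset] + [p.duration_s for p in config.phases])

    onsets, phase_ids = _draw_discharge_onsets(config, rng_events)
    alternated = np.array(
        [rng_events.uniform() < config.motifs[config.phases[k].motif_id].alternation_prob
         for k in phase_ids],
        dtype=bool,
    ) if onsets.size else np.zeros(0, dtype=bool)

    # --- LFP band -----------------------------------------------------------
    lfp = _pink_noise(n_samples, config.n_contacts, config.noise.pink_sigma, rng_lfp)
    if config.noise.common_mode_sigma > 0:
        lfp += _pink_noise(n_samples, 1, config.noise.common_mode_sigma, rng_lfp)
    if config.noise.line_amplitude > 0:
        t = np.arange(n_samples) / fs
        phase0 = rng_lfp.uniform(0, 2 * np.pi)
        lfp += config.noise.line_amplitude * np.sin(
            2 * np.pi * config.noise.line_freq_hz * t + phase0
        )

    # discharge contributions, grouped by (profile epoch, alternation flag)
    seiz_dur = config.seizure_duration_s
    peak_times = np.empty_like(onsets)
    motif_ids: list[str] = []
    groups: dict[tuple[str, bool], list[int]] = {}
    profiles: dict[str, np.ndarray] = {}
    for i, (t0, k) in enumerate(zip(onsets, phase_ids)):
        motif = config.motifs[config.phases[k].motif_id]
        frac = (t0 - onset) / seiz_dur
        prof, key = _active_profile(motif, config.phases[k].recruitment_schedule, frac)
        profiles[key] = prof
        groups.setdefault((key, bool(alternated[i])), []).append(i)
        peak_times[i] = t0 + motif.waveform.peak_offset_ms / 1000.0
        motif_ids.append(motif.motif_id)

    # calibrate each motif on the potential-gradient channels (the native
    # differential recordings, where detection operates): base-profile peak
    # gradient = snr * sqrt(2) * pink_sigma (gradient noise SD for
    # independent per-channel noise); unit reference in the noiseless case.
    ref_sigma = config.noise.pink_sigma if config.noise.pink_sigma > 0 else 1.0
    lfp_scale: dict[str, float] = {}
    for mid, motif in config.motifs.items():
        phi = forward_lfp_from_csd(motif.csd_profile, config.spacing_um)
        peak = np.abs(np.diff(phi)).max()
        lfp_scale[mid] = (
            config.discharge_snr * np.sqrt(2.0) * ref_sigma / peak if peak > 0 else 0.0
        )

    for (key, alt), idx in groups.items():
        base_mid = key.split("+")[0]
        motif = config.motifs[base_mid]
        phi = forward_lfp_from_csd(profiles[key], config.spacing_um) * lfp_scale[base_mid]
        main, reb = motif.waveform.lobes(fs)
        kernel = main - reb if alt else main + reb
        train = np.zeros(n_samples)
        samp = np.round(onsets[idx] * fs).astype(int)
        np.add.at(train, samp, 1.0)
        sig = fftconvolve(train, kernel)[:n_samples]
        lfp += np.outer(phi, sig)

    order = np.argsort(peak_times, kind="mergesort")
    peak_times = peak_times[order]
    motif_ids = [motif_ids[i] for i in order]
    alternated = alternated[order] if alternated.size else alternated

    # --- MUA band -----------------------------------------------------------
    mua = None
    spike_times: list[np.ndarray] = [np.empty(0) for _ in range(config.n_contacts)]
    if config.include_mua:
        n_mua = int(round(config.duration_s * config.fs_mua_hz))
        mua = rng_mua.standard_normal((config.n_contacts, n_mua)).astype(np.float32)
        mua *= np.float32(config.noise.mua_white_sigma)
        template = (_mua_spike_template(config.fs_mua_hz) * 8.0 * config.noise.mua_white_sigma)
        bump_half_s = 0.025  # spikes locked within +/-25 ms of the discharge peak
        spikes_per_discharge = config.mua_spike_rate_peak_hz * 2 * bump_half_s
        for c in range(config.n_contacts):
            times_c = []
            if config.mua_baseline_hz > 0:
                n_base = rng_mua.poisson(config.mua_baseline_hz * config.duration_s)
                times_c.append(rng_mua.uniform(0, config.duration_s, n_base))
            for i, tp in enumerate(peak_times):
                w = config.motifs[motif_ids[i]].mua_depth_profile[c]
                if w <= 0:
                    continue
                n_sp = rng_mua.poisson(w * spikes_per_discharge)
                if n_sp:
                    # raised-cosine-distributed lags around the discharge peak
                    u = rng_mua.uniform(-1, 1, n_sp)
                    lags = bump_half_s * np.sign(u) * np.abs(u) ** 0.7
                    times_c.append(tp + lags)
            if times_c:
                tt = np.sort(np.concatenate(times_c))
                tt = tt[(tt >= 0) & (tt < config.duration_s - 1.5e-3)]
                if tt.size:
                    keep = np.ones(tt.size, dtype=bool)  # 1 ms refractory
                    last = tt[0]
                    for j in range(1, tt.size):
                        if tt[j] - last < 1e-3:
                            keep[j] = False
                        else:
                            last = tt[j]
                    tt = tt[keep]
                spike_times[c] = tt
                samp = np.round(tt * config.fs_mua_hz).astype(int)
                tr = np.zeros(n_mua, dtype=np.float32)
                np.add.at(tr, samp, 1.0)
                mua[c] += fftconvolve(tr, template)[:n_mua].astype(np.float32)

    rec = LaminarRecording(
        lfp=lfp,
        fs_lfp_hz=fs,
        spacing_um=config.spacing_um,
        mua=mua,
        fs_mua_hz=config.fs_mua_hz if config.include_mua else None,
        signal_kind="monopolar",
        zone=config.zone,
        line_freq_hz=config.noise.line_freq_hz,
        annotations={"preictal": (0.0, onset), "seizure": (onset, end)},
    )
    recruitment = {}
    for p in config.phases:
        recruitment.update(p.recruitment_schedule)
    truth = GroundTruth(
        discharge_times_s=peak_times,
        discharge_motif_ids=motif_ids,
        discharge_alternated=alternated,
        phase_boundaries_s=bounds,
        recruitment_onset_fractions=recruitment,
        mua_spike_times=spike_times,
        seizure_onset_s=onset,
        seizure_end_s=end,
    )
    return rec, truth
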