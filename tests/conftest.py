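import warnings

import numpy as np
import pytest

import lamseiz as lz
from lamseiz.detect import detect_discharges
from lamseiz.preprocess import filter_bands

warnings.filterwarnings("ignore", message="FastICA did not converge")


@pytest.fixture(scope="session")
def onset_run():
    """One default onset-zone seizure, filtered, with detections and CSD."""
    rec, truth = lz.simulate_seizure(lz.default_onset_config(seed=1, include_mua=False))
    rec = filter_bands(rec)
    detections = detect_discharges(rec)
    csd = lz.compute_csd(rec)
    return {"rec": rec, "truth": truth, "detections": detections, "csd": csd}


@pytest.fixture(scope="session")
def propagation_run():
    """One default propagation-zone seizure, filtered, with detections and CSD."""
    rec, truth = lz.simulate_seizure(
        lz.default_propagation_config(seed=1, include_mua=False)
    )
    rec = filter_bands(rec)
    detections = detect_discharges(rec)
    csd = lz.compute_csd(rec)
    return {"rec": rec, "truth": truth, "detections": detections, "csd": csd}


def make_noise_recording(
    n_contacts=24, duration_s=20.0, fs=2000.0, sigma=1.0, seed=0, preictal_s=10.0
):
    """Plain Gaussian-noise recording with preictal/seizure annotations."""
    rng = np.random.default_rng(seed)
    lfp = sigma * rng.standard_normal((n_contacts, int(duration_s * fs)))
    return lz.LaminarRecording(
        lfp=lfp,
        fs_lfp_hz=fs,
        spacing_um=150.0,
        annotations={"preictal": (0.0, preictal_s), "seizure": (preictal_s, duration_s)},
    )
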