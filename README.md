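# lamseiz

Laminar microelectrode seizure analysis: current-source-density (CSD)
estimation across cortical layers, automated ictal-discharge detection,
multi-unit-activity (MUA) rate estimation, layer-group sink/source
statistics, seizure-time-normalized engagement dynamics, and ICA-based
identification of discharge-generation patterns — together with a
ground-truth synthetic laminar-seizure generator that makes every stage
testable without clinical recordings.

## Who this is for

Epilepsy researchers working with penetrating laminar probes (24 contacts,
150 µm pitch, LFP band at 2 kHz plus an MUA band at 20 kHz) who want a
reproducible, scriptable version of the standard laminar seizure workflow:
which cortical layers (supragranular / granular / infragranular) generate
ictal discharges inside the seizure onset zone versus the propagation
pathway, how laminar engagement evolves over normalized seizure time, and
whether discharge generation switches between distinct laminar motifs.

## The methods in brief

- **CSD**: second spatial difference of the monopolar laminar LFP,
  `CSD_i = (φ_{i−1} − 2φ_i + φ_{i+1}) / h²`, with zero pseudo-channels
  appended above and below the array (Vaknin-style boundary handling) and a
  5-point Hamming spatial filter. Sinks are positive and normalized to
  [0, 1], sources negative in [−1, 0].
- **Discharge detection** on the potential-gradient (differential)
  channels: robust-z amplitude threshold against a pre-ictal median/MAD
  baseline, bidirectional slope and duration criteria, cross-channel
  collapse.
- **MUA rates** by threshold-crossing counting (k×MAD, 1 ms refractory),
  binned, smoothed, min-max normalized, and compared with a 10 s pre-ictal
  baseline; includes the fraction of above-baseline activity carried by
  the deepest 20 % of contacts.
- **Engagement dynamics**: each seizure normalized to 100 time bins;
  per contact the mean |CSD| per bin is compared with baseline mean + 2 SD;
  the thresholded excess is expressed as a per-bin distribution across
  layers, and a Welch split-scan estimates the normalized-time fraction at
  which a layer group becomes engaged.
- **Pattern identification**: 1 s CSD windows centered on each discharge,
  decomposed with a fixed-point (FastICA) unmixing into 8 components after
  uncentered whitening, then reduced to temporally contiguous patterns by
  correlation-template refinement.
- **Synthetic generator**: discharges are zero-sum laminar CSD motifs
  pushed through the exact discrete inverse of the CSD operator, with
  phase-specific rate ramps (dead-time renewal processes), sink→source
  polarity alternation 50 ms after each discharge peak, depth-profiled MUA
  spike trains, 1/f noise and 50/60 Hz line noise.

## Worked example

```python
import lamseiz as lz
from lamseiz.preprocess import filter_bands
from lamseiz.detect import detect_discharges, evaluate_detection
from lamseiz.ica import build_event_windows, decompose, count_patterns

rec, truth = lz.simulate_seizure(lz.default_onset_config(seed=1, include_mua=False))
rec = filter_bands(rec)                      # 0.2-500 Hz band + 60 Hz notch
ds = detect_discharges(rec)                  # robust-z detector on gradients
scores = evaluate_detection(ds.times_s, truth.discharge_times_s, rec.duration_s)
print(f"sensitivity {scores['sensitivity']:.3f} specificity {scores['specificity']:.3f}")

csd = lz.compute_csd(rec)                    # 24 x n_samples, sinks positive
wins, kept, _ = build_event_windows(csd, ds.times_s)
patterns = count_patterns(decompose(wins, kept, n_components=8, seed=1))
print(f"{patterns.n_patterns} patterns, switch at "
      f"{patterns.switch_times_s[0] - truth.seizure_onset_s:.2f} s after onset")
```

Output:

```
sensitivity 1.000 specificity 0.949
2 patterns, switch at 5.32 s after onset
```

The detector recovers all 430 simulated discharges with binwise
specificity above 0.9; the ICA stage finds the two discharge-generation
motifs of the onset zone, and the estimated switch time between them
recovers the generator's 5.3 s initial phase.

A command-line interface mirrors the library
(`lamseiz simulate|preprocess|detect|csd|mua|run`), e.g.

```bash
lamseiz run --zone onset --seed 1 --out runs/onset1
```

writes the recording container (HDF5), the discharge table (CSV), a JSON
report, and a provenance record.

## Layout

- `src/lamseiz/synthetic.py` — forward model and seizure generator
- `src/lamseiz/io.py` — HDF5 container, event CSVs, EDF export
- `src/lamseiz/preprocess.py` — filters, notch, bad channels, gradient↔monopolar
- `src/lamseiz/csd.py` — CSD estimator and sink/source normalization
- `src/lamseiz/detect.py` — discharge detector and scoring
- `src/lamseiz/mua.py` — MUA rates and depth statistics
- `src/lamseiz/laminar.py` — layer partition, chi-square, sink/source stats, alternation
- `src/lamseiz/temporal.py` — 100-bin normalization, engagement, onset scan
- `src/lamseiz/ica.py` — event windows, FastICA, pattern counting
- `src/lamseiz/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for the model, parameter choices, and limitations.
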