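# tremorkit

Analysis pipeline for tri-axial wrist/finger accelerometer recordings of hand
tremor: six-position static calibration, preprocessing (gap filling,
detrending, zero-phase Butterworth high-pass at 1 Hz), spectral
characterization (per-axis PSD, interpolated dominant frequency, dominant
axis, 2-Hz energy-concentration band, band-average amplitude, windowed
tri-axial energy), and cohort-level aggregation by age group and years since
diagnosis. A synthetic-data module generates recordings and calibration
fixtures with known ground truth, so the whole pipeline is testable without
access to raw patient data; transcriptions of the study's demographics and
per-test result tables ship with the package.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (printed age-group
summary reproduction, ≤0.5% frequency deviation / ≤0.02 Hz MAE on a 1–12 Hz
tone sweep, ≤2% amplitude error, ≤0.02 g calibrated gravity deviation, and
the property suite).

## CLI

```sh
# synthetic recording for clinical test 1, mild severity
tremorkit simulate --preset 1 --severity mild --seed 3 --out rec.csv

# preprocessing chain (CSV in -> CSV out + JSON processing log)
tremorkit preprocess --input rec.csv --units m_per_s2 --out clean.csv

# full single-recording analysis (results-table row + spectral summary JSON)
tremorkit analyze --input rec.csv --units m_per_s2 --test-id 1 --out-dir out/

# six-position calibration from labelled logs (note the '=' form: labels
# start with + or -)
tremorkit calibrate --orientation=+x=xp.csv --orientation=-x=xm.csv \
    --orientation=+y=yp.csv --orientation=-y=ym.csv \
    --orientation=+z=zp.csv --orientation=-z=zm.csv --out model.json

# dynamic single-tone validation report
tremorkit validate --trial tone5.csv:5.0:1.0 --units m_per_s2 --out report.csv

# cohort aggregation (packaged tables by default)
tremorkit cohort --out-dir cohort_out/
```

Every subcommand writes a JSON manifest (config, version, input digests)
next to its outputs. Flat YAML config files can override preprocessing and
spectral settings via `--config`.

## Layout

- `src/tremorkit/signal_io.py` — logger CSV dialect, `AccelSeries`, unit
  conversion, cohort tables (`data/*.csv`)
- `src/tremorkit/synthetic_data.py` — recording and calibration simulators,
  clinical-scenario presets
- `src/tremorkit/calibration.py` — six-position estimator, model
  application, dynamic tone validation
- `src/tremorkit/preprocess.py` — gap filling, detrend, zero-phase
  Butterworth, normalization
- `src/tremorkit/spectral.py` — spectra, dominant frequency/axis, energy
  band, band amplitude, windowed energy
- `src/tremorkit/cohort.py` — test records, grouped aggregation, control
  comparison
- `src/tremorkit/cli.py` — the `tremorkit` entry point
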