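# duetgamma

Analysis pipeline for synchronized vocal and neural recordings of freely
behaving songbirds:

- **Turn-taking metrics** on time-stamped call-event tables: answer
  detection within a 500 ms window, reply latency, and reply strength
  `RS = (Nresponse − Nbaseline) / (Nresponse + Nbaseline)`.
- **LFP Auditory Response Strength (ARS)**: a 1st-order Butterworth
  filter bank (10–200 Hz in 10 Hz bands) applied zero-phase to the
  neural trace; per call and band, the RMS of the stimulus window minus
  the RMS of the equal-length immediately preceding baseline window;
  per-bird [−1, 1] normalization; band-of-interest selection by mean
  `log(ARS²)` (recovering the low-gamma bands labeled 30, 40, 50 Hz on
  burst-bearing data).
- **Night-playback support**: −5 dB peak normalization, pseudorandomized
  schedules (every stimulus exactly 30 times, no immediate repeats), and
  per-stimulus ARS aggregation across repetitions.
- **Posterior-draw inference**: REML fits (mixed model or OLS), 10,000
  flat-prior posterior draws, 95% credible intervals, and the
  "posterior probability of difference > 95%" decision rule.
- **Synthetic data**: Poisson call streams with context-dependent
  answers, and LFP traces with stimulus-locked narrowband bursts, so the
  whole pipeline is testable end to end with no recordings.

## Command line

```sh
duetgamma validate events.csv trace.wav config.yaml
duetgamma simulate --config sim.yaml --out data/
duetgamma interactions --events events.csv --config cfg.yaml --out metrics.csv
duetgamma ars --trace bird.wav --events events.csv --out ars.csv
duetgamma playback score --trace night.wav --schedule sched.csv --out pb_ars.csv
duetgamma report --ars ars.csv --out report/
```

File formats: event tables and schedules are plain CSV, traces are mono
WAV, configs are YAML. All times are session-relative seconds on one
shared clock (traces and events are assumed pre-aligned); intervals are
half-open `[start, end)` and answer windows are onset-exclusive
`(onset, onset + w]`.

## Layout

```
src/duetgamma/
  datamodel_io.py      domain types; CSV/WAV/YAML readers and writers
  synthetic_data.py    call-stream and LFP simulators, experiment writer
  vocal_interactions.py answers, reply latency/strength, call contexts
  lfp_ars.py           filter bank, fragment RMS, ARS, band selection
  playback.py          stimulus normalization, schedules, playback scoring
  inference.py         REML fits, posterior draws, decision rule
  cli.py               click-based command line
tests/                 pytest suite (unit, property, acceptance)
scripts/acceptance.py  standalone acceptance report
```
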