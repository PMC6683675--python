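# spikelick

Analysis pipeline for single-unit taste responses recorded while an animal
licks freely: sliding-window response detection at two timescales,
spike–lick coherence with firing-pattern cell classification, licking
microstructure metrics, and metric-space (spike-train distance) information
analysis with shuffle and exchange controls.  A seeded synthetic session
generator with `lean` and `DIO` group presets drives every stage, so the
whole pipeline runs with no external data.

## Layout

| module | contents |
| --- | --- |
| `spikelick.synth` | lick-train/bout generator, VR5 trial scheduler, inhomogeneous-Poisson spike generator (2 ms refractoriness), group presets |
| `spikelick.session_io` | session file dialect (`header.json` + `events.csv`, 25 µs timestamps), structural validation, duplicate-unit screen (zero-lag CCF) |
| `spikelick.detect` | spontaneous/baseline rate estimators; 5-lick (100 ms/20 ms over 4 s) and lick-by-lick (10 ms/2 ms over 170 ms) response detectors |
| `spikelick.lick` | Welch magnitude-squared spike–lick coherence with 4–9 Hz peak, circular-shift null, cell classification, behavior tables |
| `spikelick.metric` | spike-train edit distance (cost `q` per second of shift), classifier confusion, mutual information, shuffle/exchange controls, window sweep |
| `spikelick.stats` / `spikelick.pipeline` | group summaries, two-sample contrasts, end-to-end orchestration |

## CLI

```bash
spikelick synth --preset lean --n-cells 20 --seed 1 --out runs/lean01
spikelick validate runs/lean01
spikelick dedupe runs/lean01
spikelick detect runs/lean01 --out detection.csv
spikelick coherence runs/lean01 --out coherence.csv
spikelick behavior runs/lean01 --out behavior.csv
spikelick msa runs/lean01 --window 2.0 --seed 1 --out msa.csv
spikelick run --seed 0 --out runs/full   # lean + DIO, full pipeline
```

`spikelick run` accepts `--config <json|toml>` with keys `presets`,
`n_cells`, `trials_per_stimulus`, `seed`, `windows`, `msa_panel`,
`n_shuffle`, `n_exchange`, `coherence_null_shifts`, `stages`.

## Notes

- All randomness flows through `numpy.random.Generator` seeds; identical
  seeds give bit-identical sessions and byte-identical output tables.
- Preset rate parameters and lick-modulation depths are calibration
  fixtures chosen so that group-level contrasts run in the documented
  directions at desk scale; they are not measurements.
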