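# File formats

All artifacts are plain text (CSV / JSON).

## Spike raster CSV (`*.csv` + `*.csv.json` sidecar)

| column | meaning |
| --- | --- |
| `neuron_id` | 0-based index on the ring |
| `spike_time_s` | spike time in seconds, microsecond precision |

Sidecar JSON: `population_id`, `duration_s`, `bin_width_s`, and optionally the
full `population_spec` (size, freq_hz, gamma, intensity model, sigma).

## Intensity trace CSV

| column | meaning |
| --- | --- |
| `t_s` | refresh instant (s); values are piecewise constant until the next row |
| `D1_hz`, `D2_hz`, … | intensity of population 1, 2, … in Hz |

## Order-parameter trajectory CSV (long format)

| column | meaning |
| --- | --- |
| `t_s` | sample time (s) |
| `pop` | population index (0-based) |
| `w_bar` | mean synaptic weight |
| `w_tilde` | first-Fourier magnitude of the weight profile (half-amplitude convention) |
| `psi` | profile phase in [0, 2π); carried forward while `w_tilde` is unresolvably small |

## Phase-diagram grid CSV

Columns: the two axis parameters (e.g. `mu`, `alpha`), `lambda_wta`,
`lambda_r1`, `lambda_r2`, …, and `label` (`NR`, `R`, `WTA`, `partial_R`, or
`degenerate`).

## Run manifest JSON

`config` (echo of the input config), `seed`, `runtime_s`, `versions`
(package, numpy, python), plus subcommand-specific fields (e.g. `regime` and
its `evidence` for mean-field runs).

## Acceptance report JSON

`{"<target id>": {"value": <number>, "n": <problem size>}, ...}`.
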