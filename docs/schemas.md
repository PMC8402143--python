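# File formats

All CSV files are comma-separated UTF-8 with a mandatory header row.
Times are minutes, concentrations µg/mL, amounts µg, volumes mL, body
weights kg, unless a column name says otherwise.

## Plasma profile CSV (`nca --profile`, `synth` output `plasma.csv`)

| column       | type  | meaning                              |
|--------------|-------|--------------------------------------|
| `animal`     | int   | animal index (optional for `nca`)    |
| `drug`       | str   | `PA` or `NAPA` (optional for `nca`)  |
| `time_min`   | float | sampling time after dosing           |
| `conc_ug_ml` | float | plasma concentration                 |

Times must be strictly increasing per animal/drug; at least three positive
terminal concentrations are required for NCA.

## Urine CSV (`nca --urine`, `synth` output `urine.csv`)

| column      | type  | meaning                         |
|-------------|-------|---------------------------------|
| `animal`    | int   | animal index (optional)         |
| `drug`      | str   | `PA` or `NAPA` (optional)       |
| `start_h`   | float | collection interval start, h    |
| `end_h`     | float | collection interval end, h      |
| `amount_ug` | float | amount excreted in the interval |

Intervals must be contiguous and non-overlapping.  Dilution correction
(e.g. 100-fold for 0–8 h samples) is applied before writing this file.

## Observation CSV (`fit --obs`)

| column     | type  | meaning                                       |
|------------|-------|-----------------------------------------------|
| `kind`     | str   | `plasma` or `urine_cumulative`                |
| `drug`     | str   | `PA` or `NAPA`                                |
| `time_min` | float | sampling time / interval end (in minutes)     |
| `value`    | float | concentration (µg/mL) or cumulative amount µg |

## Parameter-table CSV (`simulate --pa-table/--napa-table`)

Tidy layout with columns `block, parameter, drug, arm, value, units,
provenance`; blocks are `physchem`, `distribution` (parameters named
`kp_<tissue>`), `hepatic` and `kidney`.  Round-trips losslessly through
`panapk.parameterization.parameter_table_to_frame/from_frame`.

## Simulation export (`simulate --out`)

Tidy columns `time, drug, compartment, amount, concentration`.
Compartments are the model states, including `kidney_vascular`,
`kidney_cell`, `kidney_lumen`, `urine` (cumulative, uncalibrated) and the
cumulative hepatic elimination states.

## Kp,ss table (`synth` output `kpss.csv`)

Columns `animal, drug, tissue, time_min` plus either
`concentration` (rows with `tissue = "plasma"`, serial samples) or
`c_tissue, c_plasma, kp_ss` (tissue rows at the sacrifice time).

## JSON outputs

`nca`/`fit` emit flat JSON objects of the result fields.  `synth` writes a
`truth.json` sidecar recording the seed, arm, generating `r_act`, and the
per-animal noiseless plasma and cumulative-urine series.  `reproduce
--out` writes `{check id: {computed, published, passed}}` plus the
treated-arm kidney-Kp comparison.

## Physiology TOML

Top-level keys mirror `panapk.physiology.REFERENCE_PHYSIOLOGY`:
`volumes_ml_per_kg.<tissue>`, `cardiac_output_ml_min_kg`,
`flow_fractions.<tissue>` (must sum to 1), `gfr_ml_min_kg`,
`urine_flow_ml_min_kg`, `kidney_subvolume_fractions.{vascular,cell,lumen}`
(must sum to 1).  Partial files are merged over the built-in reference.

Exit codes for all subcommands: 0 ok, 1 validation error, 2 runtime error.
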