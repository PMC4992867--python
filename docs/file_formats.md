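# File formats

## Plate CSV

Time is stored in minutes as floats; readers accept seconds via
`time_unit="s"` (CLI: not exposed; convert upstream) and convert on read.
Missing single readings are NaN gaps and are propagated to downstream
masks, never interpolated.

### long dialect

Columns `well_id, time_min, channel, value`; `channel` is `OD` or `F`; one
row per reading. Row order is irrelevant. Every well must carry both
channels at every time point it appears.

### wide dialect

One `time_min` column plus, per well, the pair `<well_id>_OD` and
`<well_id>_F` (e.g. `B3_OD`, `B3_F`). The time column must be strictly
increasing; all wells share the single grid.

## Layout TSV

Tab-separated with header
`well_id  role  genotype  module  position  medium  replicate`.

- `role`: `blank` (medium only), `background` (non-fluorescent reference
  strain), `sample`.
- `genotype`: `wildtype`, `hupAB`, `hns`, `none`.
- `module`: `Pdps`, `Phns`, `Pfis`, `none` (samples must not be `none`).
- `position`: `OL OR ML MR TL TR MLup ara native none`.
- `medium`: free text; `replicate`: integer ≥ 1.

A correctable plate needs at least one blank and one background well.
Duplicate `well_id` rows and unknown enum tokens are rejected with the
allowed tokens listed.

## Result tables and manifest

`write_results` emits one TSV per result kind — `expression` (well_id,
time_min, od_corr, f_corr, fod, mask), `activity` (well_id, time_min,
d_fod_raw, d_fod_clipped, mask), `synthesis` (well_id, time_min, q),
`response` (well_id, genotype, position, delta_fod, fraction_pct,
floored_flag) — plus `manifest.json` echoing the run configuration,
warnings and package version. Floats are written with 17 significant
digits so re-reading reproduces in-memory values.

## Scenario YAML

`nucleoflux simulate --scenario <file.yaml>` accepts a YAML rendering of
`ScenarioConfig` (see `nucleoflux.simulate.scenario_to_dict` for the exact
shape); packaged scenario names are accepted in place of a file.
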