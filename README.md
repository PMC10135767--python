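# caflow

Quantification of integrin-triggered calcium transients in cells firmly
adhering inside a parallel-plate flow chamber.

When a circulating lymphoid cell arrests on an adhesive substrate (for
example, integrin α4β7 engaging immobilized MAdCAM-1) under shear flow, a
calcium-sensitive dye such as Fluo-4 reports a stereotyped cytosolic
calcium burst: the fluorescence sits at a low plateau for a latent period,
rises swiftly to a peak, then relaxes back toward its original level.
`caflow` turns time-lapse recordings of such assays — or per-cell
fluorescence traces — into per-cell transient characteristics and group
statistics. It is aimed at quantitative cell-adhesion and
mechano-signaling labs that today do this by hand in vendor software and
spreadsheets.

## What it computes

Per frame, for each firmly adhered cell, the normalized fluorescence

```
F_IN = (F_IC − F_IB) / F_IB
```

where `F_IC` is the mean cell fluorescence over the cell mask and `F_IB`
is the local background: the mean of four round domains of area 36π µm²
(radius 6 µm) placed 24 µm from the cell centroid at 0°, 90°, 180° and
270°. Firm adhesion follows the standard operational criterion — travel
displacement strictly below 10 µm over some 1-minute window — and the
start of the earliest qualifying window defines t = 0 for the trace.

Per cell, three transient characteristics:

* **T_D** (delay time, s) — from arrest to the onset of the sharp rise;
* **T_P** (peak time, s) — from onset to the trace maximum;
* **I_P** (peak calcium intensity, dimensionless) — peak-to-plateau
  fluorescence ratio; cells with no detected rise, or I_P below the
  activation threshold (default 1.5), are non-activated.

Per condition, Student's t-test (two groups) or one-way ANOVA with
Tukey's HSD (three or more), boxplot five-number summaries and mean ± SEM,
with the usual star notation.

Because assays of this kind rarely ship public raw recordings, the
package includes a fully ground-truthed synthetic generator: seeded
multi-page 16-bit TIFF scenes of arresting and sliding cells (or bare
traces), with condition labels (ligand density, wall shear stress,
inhibitor/knockdown) that shift the transient-parameter distributions in
the directions such experiments report.

## Worked example

Run the bundled demo — a rendered two-condition ligand-density cohort of
8 cells — end to end:

```
$ caflow run-all --out-dir demo
{"n_tracks": 8, "n_firm": 8, "n_traces": 8, "n_features": 8, "n_activated": 8}
artifacts written to demo

$ caflow stats --features demo/features.csv --feature T_D_s
2 ug/mL: n=4 median=34.5 [32.7, 39.5] mean=37.6±4.86
20 ug/mL: n=4 median=15.8 [14.7, 19.5] mean=18.3±2.99
t-test: statistic=3.391 p=0.0147 (*)
```

All 8 simulated cells are detected, tracked, classified as firmly
adherent and labeled activated. The delay-time comparison shows what the
generator encoded: cells on the denser 20 µg/mL substrate fire their
calcium burst roughly twice as fast as on 2 µg/mL (median 15.8 s vs
34.5 s), significant at p ≈ 0.015 despite only four cells per group
(groups below the usual ≥ 15-events collection rule are flagged in the
output tables). The same pipeline is scriptable from Python:

```python
import caflow as cf

cohort = cf.generate_cohort(cf.shear_series_design(), 20, seed=11,
                            mode="traces", noise_sd=10.0)
features = cf.features_from_traces(cohort.traces)
```

CLI verbs `simulate`, `track`, `adhere`, `quantify`, `stats` and
`run-all` expose the individual stages on files (TIFF + JSON sidecar in,
CSV tables and a provenance JSON out); see `examples/demo_config.yaml`
for a complete configuration.

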