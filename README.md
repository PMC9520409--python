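# avnode

A network model of atrioventricular (AV) nodal conduction during atrial
fibrillation, extended with autonomic-tone scaling, plus the surrounding
analysis machinery:

- **`avnode.av_network`** — discrete-event simulation of impulse
  propagation through a 21-node dual-pathway network (slow/fast pathway
  chains joined at a coupling node) with history-dependent refractory
  periods and conduction delays, and multiplicative tone scales
  `a_r`/`a_d` that may follow a piecewise-constant schedule.
- **`avnode.atrial_generator`** — atrial-activation point process with
  Pearson Type IV inter-arrival times parameterized by moments
  (mean, std, skewness, kurtosis), stationary or with time-varying
  mean/std trends.
- **`avnode.rr_metrics`** — RR-series characteristics: mean, RMSSD and
  sample entropy (m = 2, r = 0.2 by default), with ectopic-interval
  exclusion masks and sliding-window trends.
- **`avnode.sensitivity`** — distribution-based global sensitivity
  analysis (conditional-vs-bootstrap empirical CDFs compared by
  Kolmogorov–Smirnov distance, with a dummy-parameter significance
  threshold) over the 14-dimensional model/input parameter space, with
  physiological screening of parameter sets.
- **`avnode.tilt_pipeline`** — desk-scale tilt-test protocol: synthetic
  atrial-fibrillatory-rate (AFR) trends, AA-parameter estimation from
  1/AFR, ensembles of parameter sets × AA realizations under per-position
  tone scales, and population-averaged characteristic trends.
- **`avnode.io` / `avnode.cli`** — plain-text readers/writers (CSV, JSON,
  YAML), run manifests, and the `avnode` command-line interface.

All times are in milliseconds except trend timestamps (seconds); units
are embedded in file column names.

## CLI

```sh
# generate a stationary AA series and run it through the model
avnode generate-aa --mu 150 --sigma 20 --n 5000 --seed 1 --out aa.csv
avnode simulate --params params.json --aa aa.csv --out v.csv

# RR characteristics of an RR series with validity mask
avnode metrics --rr rr.csv --m 2 --r 0.2 --out metrics.json

# scaled-down sensitivity study
avnode sensitivity --k 10000 --seed 1 --out sens/

# tilt protocol on a synthetic AFR trend (24 sets x 3 realizations)
avnode tilt --synth --seed 1 --out tilt/
```

`params.json` holds `sp`/`fp`/`cn` blocks (each with `r_min`, `delta_r`,
`tau_r`, `d_min`, `delta_d`, `tau_d`, in ms) and top-level `a_r`, `a_d`.
Every stochastic subcommand requires `--seed` and writes a JSON manifest
recording the configuration and seeds.

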