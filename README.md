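# episeg

Epidemic changepoint detection with online background estimation and
nuisance-segment modelling.

An *epidemic* changepoint is a pair (s, e): the series departs from its
background distribution at s and returns to it after e. `episeg`
implements two penalised-likelihood detectors for univariate series:

* **Algorithm 1** (`episeg.alg1`): optimal-partitioning detection of
  epidemic segments when the background parameter is unknown. The
  background estimate is updated online, in O(1) per point, from the
  background points of the incumbent optimal path; an optional second pass
  re-segments at the final estimate. PELT-style pruning keeps the
  candidate set small.
* **Algorithm 2** (`episeg.alg2`): additionally models long *nuisance*
  background shifts that affect the same parameter as the signal and are
  distinguished only by duration (> l vs <= l). The nuisance cost of a
  window is itself an inner Algorithm-1 problem with its own unknown local
  background, maintained incrementally per candidate start, so signal
  segments are recovered even when they overlap a nuisance stretch and
  their *signal-specific* effect (level minus local background) is
  reported. Local and global pruning variants are provided.

Costs are Gaussian (change in mean with known variance, or change in
variance with known mean); the solvers minimise a deviance-scale objective
`2*NLL + beta*k (+ beta'*m)` with the strengthened-SIC penalty
`beta = alpha*(ln n)^(1+delta)` (defaults alpha=3, delta=0.1).

Supporting modules: `episeg.costs` (sufficient statistics, segment costs,
penalties), `episeg.simulate` (six built-in simulation scenarios and a
Monte-Carlo study driver), `episeg.evaluate` (TPR/PPV/segment-count
metrics, signal-effect recovery, SIC), `episeg.io_cli` (CSV/TSV/bedGraph
input, BED-like output, CLI).

## Command line

```sh
# detect epidemic segments in a one-column CSV (unknown background)
episeg detect series.csv --detector alg1 --l 100 -o segments.tsv

# nuisance-robust detection on bedGraph coverage (known background 0)
episeg detect coverage.bedgraph --detector alg2 --l 100 --theta0 0 \
    -o segments.tsv

# emit a simulation scenario replicate / reproduce a study grid
episeg simulate --scenario overlap1 --n 220 --seed 1 -o x.csv --truth-out t.json
episeg study --scenario one_segment --n 750 --reps 50 --seed 1 -o study.csv
```

`detect` accepts a YAML/JSON `--config` file with the same keys as the
flags; identical config + seed gives byte-identical outputs. Segment
output is 0-based half-open BED-like TSV (genomic coordinates are mapped
back for bedGraph input) with one row per signal/nuisance segment.

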