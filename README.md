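# midflux

Non-targeted mass-isotopolome analysis of stable isotope labeling
experiments. Given per-compound, per-fragment mass isotopomer distributions
(MIDs) measured under several experimental conditions and tracers, the
package provides:

- **QC filtering** (`midflux.qc`) — fragment acceptance thresholds
  (MID-determination R², absolute-sum artifact check, M0 window, minimal
  enrichment), trailing-noise removal, contaminant exclusion lists, and a
  two-passing-fragments compound rule.
- **Flux-change ranking** (`midflux.variation`) — per compound, the maximal
  cross-condition population standard deviation of relative mass-isotopomer
  abundance ("variation score") on the heaviest fragment common to all
  conditions, with unlabeled-compound and one-derivative-per-metabolite
  rules.
- **MID similarity networks** (`midflux.similarity`) — Needleman–Wunsch
  alignment of MID vectors (gap penalty 0.4) followed by a
  dimension-normalized Canberra distance, pairwise distance matrices per
  condition, cutoff-based network construction with cross-condition edge
  overlay, GraphML/TSV export, and nearest-neighbor queries.
- **Moiety deconvolution** (`midflux.deconvolution`) — recovery of an
  unknown moiety MID from a parent fragment and a sub-fragment differing by
  that moiety, via a shifted-column convolution system solved by weighted
  nonnegative least squares, with optional natural-abundance correction.
- **Isotope math** (`midflux.isotopes`) — MID convolution (Cauchy product),
  theoretical natural-abundance envelopes from elemental formulas
  (including Si for TMS derivatives), and correction-matrix-based removal
  of natural isotope abundance.
- **Label simulator** (`midflux.simulate`) — exact positional-isotopomer
  propagation of tracers through small user-defined metabolic networks
  (transfer/condensation/cleavage reactions with explicit atom maps and
  mixing fractions), emitting ground-truth fragment MIDs with optional
  natural-abundance background and measurement noise. A toy
  glycolysis/TCA-like model ships with the package
  (`midflux.toy_model_path()`).

The canonical interchange format is a TSV table
(`condition  tracer  replicate  compound_id ... M0..Mk  I0..Ik`); see
`midflux.core.read_mid_table` / `write_mid_table`.

## CLI

One executable with five subcommands:

```bash
# generate a synthetic dataset from the packaged toy network
midflux simulate --model src/midflux/data/toy_network.yaml \
    --noise 0.005 --replicates 3 --seed 1 --out sim.tsv --truth-out truth.json

# QC-filter it (paper-style defaults shown)
midflux qc --in sim.tsv --out filtered.tsv --min-r2 0.98 --max-abs-sum 1.05 \
    --m0-lower 0.45 --min-enrichment 0.05 --trailing 0.01

# rank putative flux changes
midflux variation --in filtered.tsv --out ranked.tsv --tracer glc \
    --min-conditions 3 --top-k 5

# build a similarity network (cutoff is data-dependent; --top-edges N works too)
midflux similarity --in filtered.tsv --tracer glc --cutoff 0.05 \
    --out-graphml net.graphml --out-edges edges.tsv

# deconvolve a moiety MID from a parent/sub-fragment pair
midflux deconvolve --in sim.tsv --out moiety.tsv --compound naa \
    --condition A --tracer glc --parent-mz 304 --sub-mz 245 \
    --moiety-formula C2H3NO --moiety-tracer-atoms 2
```

Exit code 2 signals a schema or data error in the input.

## Simulator model files

Network models are YAML with `compounds` (name → tracer atom count),
`reactions` (atom maps as substrate-position → product-position dicts),
`mixing` (flux fractions over producing reactions), `sources`/`tracers`
(positional labeling patterns as bitstrings), and optional `fragments`
(observed m/z, atom subsets, elemental formulas). See
`src/midflux/data/toy_network.yaml` for a complete example.
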