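# transectne

Recent effective population size (Ne) trajectories from identity-by-descent
(IBD) segments in time-series data.

Ancient-DNA studies increasingly assemble *time transects* — samples from
one population at several past time points. Long IBD segments (≥8 cM in
imputed aDNA) coalesce almost exclusively within the last ~50–100
generations, making them the signal of choice for recent demography, but
standard IBD-based estimators assume all samples are contemporaneous.
`transectne` models the sharing between haplotypes sampled `Δt` generations
apart explicitly and turns within- and cross-epoch sharing into a
per-generation Ne trajectory. It is aimed at population geneticists working
with aDNA IBD calls (or any time-stratified IBD table) and at
methods-oriented users who want a fully simulable test bed.

## Model

For haplotypes sampled at generations `ti, tj` coalescing at generation
`g`, the total branch length is `t* = (g − ti) + (g − tj)`. The expected
density of IBD segments of length `l` on a chromosome of length `L`
Morgans is

    fN(l) = Σ_g  [ 2 t* e^{−t* l} + (L − l) t*² e^{−t* l} ] · φ(g),
    φ(g) = (1 / 2Ne[g]) · Π_{i<g} (1 − 1 / 2Ne[i]),

summed over `g = max(ti,tj) … G + max(ti,tj)` and over chromosomes.
Observed segment counts in 0.25 cM bins are Poisson with mean
`nhap · fN(mid) · Δl`, and the composite log-likelihood over all sample-set
pairs is maximized over `log Ne` with L-BFGS-B under two penalties: a
curvature (squared second difference) term weighted by a cross-validated
`α`, and a depth-weighted first-difference term (`β = 250`) that pins the
trajectory where IBD carries no signal. Confidence intervals come from
bootstrapping chromosomes. IBD detection errors — false positives, partial
recall, Gaussian length noise — can be folded into the expected rates by a
windowed convolution, and the same error model can be applied generatively
to simulated ground truth. A TMRCA posterior (Erlang-2 length likelihood ×
coalescent prior) reports how old the informative segments are.

## Worked example

`examples/infer_bottleneck.py` simulates the bottleneck study design —
three sets of 30 diploids at 0, 25 and 35 generations before present, a
population that crashed 10-fold (50,000 → 5,000) at generation 30 and
regrew exponentially to 100,000 — and refits the trajectory:

```
$ python examples/infer_bottleneck.py
simulated 486 IBD segments in [8, 20) cM
constant-Ne initialization: 26,228
converged: True after 1587 iterations

 gen   truth      inferred
   0    100,000    124,418
  10     36,840     40,449
  20     13,572     12,110
  25      8,238      8,635
  30      5,000     10,811
  35     50,000     21,583
  40     50,000     41,315
  50     50,000     67,843

inferred crash depth around generation 30: 7.9-fold (truth: 10-fold); the
smooth penalty spreads the instantaneous jump over a few generations.
```

The fit tracks the regrowth branch and the pre-crash plateau within a
factor of ~1.3 and recovers an ~8-fold crash; the instantaneous jump itself
is smoothed over a few generations, which is inherent to any curvature-
penalized estimator. The other scripts in `examples/` demonstrate expected
sharing across sampling gaps, TMRCA posteriors, the detection-error round
trip, and metadata preprocessing (relatedness filter, 5-generation
grouping at 29 years/generation).

A thin CLI mirrors the library for shell use:

```bash
transectne infer --ibd calls.tsv --meta meta.tsv --out trajectory.tsv
transectne bootstrap --ibd calls.tsv --meta meta.tsv --reps 200 --out traj_ci.tsv
transectne simulate-ibd --scenario bottleneck --times 0,25,35 --sizes 30,30,30 --out sim.tsv
```

Inputs are tab-separated: IBD calls (`id1, id2, chrom, length_cm`), sample
metadata (`id, date, unit[BP|CE], coverage`), an optional genetic map
(`chrom, length_morgan`; 22 built-in autosomes by default) and an optional
3-column error-model table.

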