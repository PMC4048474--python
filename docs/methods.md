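# Methods

## The model

`telosim` simulates replicative senescence driven by the end-replication
problem. The only state variable is telomere length: each chromosome is
reduced to the four telomere lengths at its ends (two antiparallel strands
× two ends), written as a 2×2 quartet

```
( m  n )          top strand
( m  n-y )        bottom strand
```

in the *canonical presentation*, in which the strand written on top loses
telomere from its complement at the right end and the bottom strand from
its complement at the left end. Replication of a non-senescent chromosome
produces one daughter identical to the parent (the top strand plus a fresh
complement) and one *shorter* daughter (the bottom strand plus a
complement missing `y` basepairs at one end):

```
( m  n )      →   ( m  n )    +    ( n-y  m )
( m  n-y )        ( m  n-y )       ( n-y  m-y' )
```

The shorter daughter is returned re-oriented (ends and strands swapped)
back into the canonical presentation. This re-orientation is load-bearing:
a chromosome has no intrinsic left/right, and keeping a fixed orientation
would leave the shorter daughter's template strand permanently un-eroded,
creating non-senescent states that copy themselves forever. With the
canonical form, repeated replication erodes both ends alternately and
whole populations reach senescence, as observed experimentally and in the
modelling literature this package follows.

Loss and division are parametric:

* loss per replication `y(n) = y0 + y1·n`, evaluated at the current
  length of the telomere being eroded;
* division probability `P_div(n) = (a + b·n)^α`, `0 ≤ α ≤ 1`, with the
  base clamped at 0 before exponentiation and the result clamped to
  [0, 1]; `α = 0` means every non-senescent individual divides (Case A).

The named presets (A1, A2, B1.1–B1.4, B2.1–B2.4) all share
`P_div = ((n − 200)/5750)^α`, which is 1 at the initial mean length
5,950 bp and 0 at the 200 bp threshold, and are calibrated so the expected
loss `P_div(n)·y(n)` is ≈200 bp at the half-way length `n = 2975`
(property-tested: all presets fall in [195, 206]). The `zhang_fit` preset
carries the fitted cultured-fibroblast rates `Y(n) = 10 + 0.043·n` and
`P_div = (n/12200 − 0.03)^0.25`, meant for a 12,200 bp initial length.

**Senescence.** A chromosome is senescent once any of its four telomeres
*reaches* the critical length (`min ≤ threshold`, default 200 bp), and
senescence is permanent. With the canonical 200 bp loss, lengths step
through exact multiples of 200 and hit the threshold exactly; the
reaches-the-threshold rule (rather than strictly-below) is what reproduces
the published senescence timing (first senescent chromosomes near pd
85–95, full senescence near pd 150, cell-model lengths at senescence in
the 1150–1500 bp bracket). A cell of N chromosomes is senescent as soon as any
one chromosome is: the shortest telomere governs replicative potential.

**Werner's syndrome.** With probability `p_w` per chromosome replication,
an extra deletion of `x` bp strikes both strands at one of the four
daughter/end positions, chosen uniformly (probability 1/4 each). A
deletion that would take any telomere of the modified daughter below the
senescence threshold is physically unrealistic: that replication attempt
fails, the parent is retained, and the cell may try again next generation
— the infeasible variants' probability mass is *not* redistributed. The
feasibility floor equals the senescence threshold (the published boundary
rules are the same statement in threshold-subtracted units, where two of
the four variants are infeasible and division fails with probability 1/2
— asserted in the test suite). `x = 0` is exempt (nothing is deleted), so
the Werner rule with `x = 0` is bitwise identical to normal replication.
The tabulated pairs `(p_w, x)` ∈ {(0.2, 1000), (0.4, 500), (0.6, 333),
(0.8, 250), (1, 200)} hold the expected extra loss at `p_w·x = 200` bp.

## The generation loop

Each generation every tracked individual is classified senescent /
potential / divided, in that order: senescence check first; then a uniform
draw `u < P_div(n̄)` with `n̄` the mean telomere length over the cell
(chromosome model: over the quartet); then per-chromosome replication
events. If any chromosome of a cell draws an infeasible Werner deletion
the whole cell does not divide that generation (classified potential).
Daughter chromosome pairs are allocated to the two daughter cells
independently and uniformly at random (2^N allocations).

Tracking follows experimental passaging: when the tracked sample exceeds
the cap (default 200 cells) a uniform without-replacement subsample of
200 is retained (unbiasedness is Monte-Carlo-tested). Growth beyond the
cap is carried by the notional population size
`N(g+1) = (1 + φ_div(g))·N(g)` with `φ_div` the dividing fraction of the
tracked sample, and `pd = log2(N(g)/N(0))`. While every cell divides,
`pd = g` exactly, and a single founder cell reaches the 200-cell cap in
eight generations (2^8 = 256).

Default initial condition: one individual whose chromosomes all start at
(6000, 6000 / 6000, 5800) — three telomeres of 6,000 bp and one of
5,800 bp, i.e. mean 5,950; the all-6000 variant is configurable. Cell
model: N = 46; chromosome model: N = 1 (the cell engine with N = 1 *is*
the chromosome model — there is one engine).

The per-generation random-draw protocol (one `u` per non-senescent cell in
index order; one `r` and one variant index per chromosome of each division
candidate, variants drawn even where `r ≥ p_w`; one allocation bit per
chromosome of each divider; then the passaging subsample) is fixed and
documented, making runs bit-reproducible for a given seed. Replicate `i`
of an ensemble uses seed `base_seed + i`. The engine is array-based
(numpy, shape `(cells, chromosomes, 4)`); a pure-scalar reference
implementation of one generation, built from the single-chromosome
operations, is kept in the test suite and must match the engine
draw-for-draw.

## Stopping, tails and censoring

A run records every generation (including generation 0) and stops when the
tracked sample is entirely senescent or the generation budget is
exhausted. Because the "identical" daughter of a division is a true copy
of its parent, a last non-senescent lineage can persist for a long time
under Case A1, dying only through passaging pressure; these tails carry
almost no population growth (φ_div ≈ 1/200), so pd is insensitive to them,
but full-senescence *generation* numbers are heavy-tailed. The default
budget is 500 generations; the ensemble drivers used for the headline
numbers raise it (3,000–5,000) so that replicates complete. A trajectory
that never reaches full senescence is flagged censored — summary fields
that need full senescence are NaN, never silent zeros — and censored
replicates are excluded from (and counted alongside) ensemble senescence
summaries.

## Ensembles and summaries

Ensembles align trajectories on the generation axis, extending finished
(frozen) runs by their last record, and report per-generation
across-replicate means and standard deviations. The senescence summary
gives, per replicate, the pd at first senescence, the pd at full
senescence and the population mean telomere length at that generation.
Two first-appearance statistics are exposed: the per-replicate mean and
the ensemble-level minimum. The published "pd at which senescent cells
first appear" behaves like the pooled (minimum) statistic — for
`(p_w, x) = (0.2, 1000)` the printed value 11 equals the theoretical
earliest possible senescence (five same-end deletions plus four losses
from 6,000 bp), which a 200-cell sample only realises somewhere across a
large ensemble.

Histograms of per-cell mean or per-cell shortest telomere length use
100 bp bins from 0 (bin width configurable). The multimodality check
coalesces runs of bins holding fewer than 2 observations and counts
strict local maxima, plateaus once — a deliberate, simple
operationalization of "the distribution is bimodal".

The Gompertz growth law `N(t) = a·exp(−b·e^{−ct})` is fitted by nonlinear
least squares on log N (sizes span many orders of magnitude), with initial
guesses derived from the data and explicit failure on non-convergence or
non-positive parameters. Noiseless self-consistency is recovered to 1e−6
relative error; fits of Case B growth trajectories over their first 300
generations achieve R² > 0.98 on the log scale.

## Numerical choices

* Lengths are real-valued doubles; rounding happens only at
  serialization (6 significant digits). Length-dependent losses such as
  `n/30` are non-integer by design.
* Normal-aging losses clamp at 0; only Werner deletions can be
  infeasible.
* Ties and boundaries: senescence at `min ≤ threshold`; feasibility at
  `entry ≥ threshold` (a daughter may be born exactly at the threshold,
  hence senescent); division draw `u < P_div` with `u ∈ [0, 1)`, so
  `P_div = 1` always divides.
* Empty populations, non-positive budgets, invalid presets and negative
  parameters raise `ValueError` before any stepping.

## Known limitations

* No telomerase, recombination, cell death or continuous time; "one
  generation" is one synchronous division opportunity for every cell.
* The tracked sample is an unbiased but small (200-cell) window on the
  notional population; statistics that depend on extremes (first
  senescence) are sample-size dependent.
* Two published Werner rows with small, frequent deletions
  ((p_w, x) = (0.8, 250) and (1, 200)) report later final pds (92, 97)
  than this implementation produces (~67, ~64). Under the printed rules
  those deletions are essentially never infeasible for non-senescent
  chromosomes, so the population loses telomere at twice the normal rate
  to the very end; reproducing the published values would require
  late-stage cells to escape deletions in some unstated way. The
  disagreement is documented rather than patched; the large- and
  intermediate-deletion rows (p_w ≤ 0.6) and all normal-aging results are
  reproduced.
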