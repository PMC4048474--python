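# telosim

Stochastic (Monte-Carlo) simulation of telomere shortening and
replicative senescence, at the level of independently dividing
chromosomes and of cells carrying 46 chromosomes, for normal aging and
for Werner's syndrome.

## The problem

Telomeres — repetitive DNA at chromosome ends — shorten at each cell
division because DNA replication cannot complete the 5' end of the newly
synthesised strand (the end-replication problem). When a telomere reaches
a critical length the chromosome stops replicating and the cell becomes
senescent: this is the cellular basis of the Hayflick limit. `telosim`
lets you compare hypotheses about *how* shortening happens — constant
versus length-dependent loss per division, certain versus
length-dependent division probability — and extends the same machinery to
Werner's syndrome, a premature-aging condition modelled as random large
telomeric deletions during replication.

A chromosome is represented by the four telomere lengths at its ends
(two strands × two ends), written as a quartet `(m, n / m, n−y)`.
Replication maps

```
(m, n / m, n−y)  →  (m, n / m, n−y)   +   (n−y, m / n−y, m−y′)
     parent          identical daughter      shorter daughter
```

with per-event loss and division probability

```
y(n)     = y0 + y1·n
P_div(n) = (a + b·n)^α ,   0 ≤ α ≤ 1
```

Named presets cover the four model families (A1: constant loss, always
divide; A2: length-dependent loss; B1: constant loss, length-dependent
division; B2: both length-dependent), ten calibrated parameter sets that
all lose ≈200 bp per replication half-way to senescence, and a fitted
preset (`zhang_fit`) for cultured-fibroblast data. Werner's syndrome adds
a probability `p_w` of an extra deletion of `x` bp per chromosome
replication, with tabulated pairs holding `p_w·x = 200`.

Populations are tracked like a cell culture: 200 cells are kept by random
passaging, a notional population size grows as
`N(g+1) = (1 + φ_div)·N(g)`, and results are reported against population
doublings `pd = log2(N/N0)`. See `docs/methods.md` for the full model
description and design choices.

## Worked example

Run one chromosome-level simulation of Case A1 (constant 200 bp loss,
certain division) to full senescence:

```
$ telosim simulate --case A1 --model chromosome --seed 1 \
      --max-generations 3000 --out a1.csv
telosim 0.1.0: case=A1 model=chromosome pw=0.0 seed=1
finished at generation 320: pd=155.19 phi_sen=1.000 mean_length=350.0
```

The population mean telomere length starts at 5,950 bp and falls by
y0/4 = 50 bp per generation while every chromosome divides; the first
senescent chromosomes appear near pd 85–95, and by the end the whole
tracked sample is senescent at about pd 150 with mean length a few
hundred bp above zero. The CSV holds one row per generation
(`g, pd, notional_N, mean_length, sd_length, mean_shortest, phi_div,
phi_pot, phi_sen`) with the resolved configuration in `#` header lines.

A Werner's-syndrome ensemble (deletion probability 0.6, deletion size
333 bp) over 40 replicates:

```
$ telosim ensemble --case A1 --model chromosome --pw 0.6 --seed 42 \
      -R 40 --max-generations 5000 --out w06.json
telosim 0.1.0: ensemble R=40 case=A1 model=chromosome pw=0.6 base seed=42
final pd 83.24, first senescence at pd 38.97, mean length at senescence 188.7 bp (0 censored)
```

Werner populations senesce far earlier than normal aging (pd ≈ 83–91
versus ≈150 here) — the model's analogue of the ~20 versus ~60 population
doublings observed for Werner versus normal fibroblasts.

The same things are available as a library:

```python
from telosim import preset_case, run_simulation, senescence_summary

result = run_simulation(preset_case("A1"), n_chromosomes=46, seed=1,
                        max_generations=3000)
print(senescence_summary(result.records))
```

Other subcommands: `telosim presets` (the parameter tables),
`telosim histogram` (telomere-length distributions of the tracked sample
at chosen generations, per-cell mean or shortest).

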