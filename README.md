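# connectogenesis

Tools for analyzing how the *Caenorhabditis elegans* connectome assembles:
a first-mover (Stackelberg leader–follower) view of synaptogenesis, in
which the order in which neurons are born constrains the pre→post
direction of the chemical connections they form.

## The problem and the model

During embryogenesis, neurons terminally differentiate at stereotyped times
(the first at 265 min post-fertilization, the last wave around 400 min,
hatch at 800 min). During larval development each cell establishes chemical
synapses whose stability falls into three classes — *transient* (variable
across individuals), *developmental* (formed or pruned during development)
and *stable* (stereotyped from hatch through L4). For a connection with
presynaptic cell *i* and postsynaptic cell *j*, the **birth time
difference** is

```
delta(i, j) = birth(i) − birth(j)        (minutes, signed)
```

negative when the presynaptic cell was born first. Treating connection
formation as sequential competition — earlier-born cells are leaders whose
choices constrain later-born followers — each cell's incident deltas sort
it into one or more of five wiring strategies:

| strategy | definition over a cell's connections |
|---|---|
| N–P coupling | mean delta < 0 (presynaptic partners born earlier on average) |
| XOR First Mover | N–P, and *no* presynaptic partner born after the cell |
| XOR Second Mover | N–P, and *no* postsynaptic partner born before the cell |
| XNOR | N–P, every presynaptic partner earlier *and* every postsynaptic partner later |
| P–N coupling | mean delta > 0; pure, never co-occurs with the others |

The base N–P/P–N label is a majority (mean-sign) judgement; the refinements
are universal (a single violating connection disqualifies). A partner born
the same minute counts as neither earlier nor later.

The package covers the full analysis surface: cell catalogs and staged
connectome snapshots (`cell_catalog`), stability-classified synapse tables
and pairwise birth-time-difference matrices (`synapse_table`), strategy
classification (`first_mover`), population summaries — frequencies,
overlaps, subnetwork splits, birth-time CDFs, synaptic densities
(`strategy_stats`) — the game-theoretic machinery and a sequential
network-growth simulator (`stackelberg`), and a synthetic-data generator
with planted ground truth (`synthetic_data`). The published reference data
(the five strategy cell lists, the example strategy profile, the
300→400 min family cohort, the NSY-5 subnetwork classes) ship as versioned
fixtures, so everything runs with no external download.

## Worked example

```python
>>> from connectogenesis import (fixtures, assignments_from_lists,
...                              frequency_table, overlap)
>>> fx = fixtures()
>>> assignments = assignments_from_lists(fx.strategies)
>>> ft = frequency_table(assignments)
>>> ft.denominator
53
>>> {s: round(100 * f, 1) for s, f in ft.fractions.items()}
{'NP': 41.5, 'XOR_FIRST': 7.5, 'XOR_SECOND': 18.9, 'XNOR': 15.1, 'PN': 45.3}
>>> overlap(assignments, "NP", "XNOR")
(5, 8)
```

The 53 cell classes carrying at least one strategy label form the
population; 41.5% of them (22/53) follow N–P coupling, and the N–P and
XNOR strategies are co-employed by 5 of the 8 possible cells. Classifying
a synthetic network grown at 75% conformity recovers the planted base
labels for ~98% of well-connected cells:

```
$ python analysis/03_classify_strategies.py
60 cells classified from 292 connections at 75% conformity
base-label recovery: 93.3% overall, 97.6% among 42 cells with >= 8 connections
full-conformity recovery over 20 seeds: 100.0% of planted labels exact
```

## Analysis pipeline

Numbered drivers under `analysis/` write their tables to `results/`:

1. `01_verify_published_tables.py` — recompute the published frequency,
   overlap, subnetwork and family tables from the bundled cell lists.
2. `02_generate_synthetic.py` — generate the synthetic study-condition
   dataset (bursty births, planted strategies, 75% conformity).
3. `03_classify_strategies.py` — classify and score planted-label recovery.
4. `04_population_summaries.py` — burst histogram, delta distributions,
   per-strategy birth-time CDFs, synaptic densities, figures.

A `connectogenesis` CLI exposes the same steps
(`snapshot` / `classify` / `stats` / `simulate` / `generate` /
`verify-fixtures`).

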