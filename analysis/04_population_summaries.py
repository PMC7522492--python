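#!/usr/bin/env python
"""Population summaries and figures for the synthetic dataset.

Birth-burst histogram, per-stability-class birth-time-difference
distributions, per-strategy birth-time CDFs, and pre/postsynaptic density
by birth time. Writes tables to results/summaries/ and figures to
results/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from connectogenesis import (
    GeneratorSpec,
    assign_all,
    birth_time_cdf,
    burst_histogram,
    difference_histogram,
    frequency_table,
    generate,
    load_catalog,
    load_synapses,
    synaptic_density,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "summaries"
FIG = ROOT / "figures"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    FIG.mkdir(parents=True, exist_ok=True)
    syn_dir = ROOT / "synthetic"
    if not (syn_dir / "catalog.csv").exists():
        generate(GeneratorSpec(seed=SEED)).write(syn_dir)
    catalog = load_catalog(syn_dir / "catalog.csv")
    records = load_synapses(syn_dir / "synapses.csv", catalog)
    assignments = assign_all(records, catalog)

    # strategy frequencies with stability-class composition
    ft = frequency_table(assignments, records)
    ft.to_frame().to_csv(OUT / "strategy_frequencies.csv")
    print("strategy counts:", ft.counts)

    # birth bursts
    births = [r.birth_time for r in catalog]
    h = burst_histogram(births, bin_width=8)
    pd.DataFrame(
        {"bin_start": h.bin_edges[:-1], "count": h.counts}
    ).to_csv(OUT / "birth_histogram.csv", index=False)
    print(f"birth bursts: {h.bursts}")
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.bar(h.bin_edges[:-1], h.counts, width=8, align="edge",
           edgecolor="k")
    ax.set_xlabel("birth time (min post-fertilization)")
    ax.set_ylabel("cells born")
    fig.tight_layout()
    fig.savefig(FIG / "birth_bursts.png", dpi=150)

    # birth-time-difference distributions per stability class
    hist = difference_histogram(records, catalog)
    fig, ax = plt.subplots(figsize=(7, 3))
    for cls, (edges, counts) in hist.items():
        ax.step(edges[:-1], counts, where="post", label=cls)
    ax.set_xlabel("birth time difference (min, pre - post)")
    ax.set_ylabel("connections")
    ax.legend()
    fig.tight_layout()
    fig.savefig(FIG / "difference_histogram.png", dpi=150)

    # per-strategy birth-time CDFs
    cdfs = birth_time_cdf(assignments, catalog)
    rows = [
        (s, t, c) for s, (ts, cs) in cdfs.items() for t, c in zip(ts, cs)
    ]
    pd.DataFrame(rows, columns=["strategy", "birth_time", "cdf"]).to_csv(
        OUT / "birth_time_cdf.csv", index=False
    )
    fig, ax = plt.subplots(figsize=(5, 4))
    for s, (ts, cs) in cdfs.items():
        ax.step(ts, cs, where="post", label=s)
    ax.set_xlabel("birth time (min)")
    ax.set_ylabel("cumulative fraction of cells")
    ax.legend()
    fig.tight_layout()
    fig.savefig(FIG / "birth_time_cdf.png", dpi=150)

    # synaptic density by birth time
    for role in ("pre", "post"):
        d = synaptic_density(records, catalog, role)
        d.to_csv(OUT / f"density_{role}.csv")
        fig, ax = plt.subplots(figsize=(7, 3))
        d.plot.bar(ax=ax, stacked=False, width=0.9)
        ax.set_xlabel("birth time (min)")
        ax.set_ylabel(f"mean {role}synaptic connections per cell")
        fig.tight_layout()
        fig.savefig(FIG / f"density_{role}.png", dpi=150)
    print(f"wrote tables to {OUT} and figures to {FIG}")


if __name__ == "__main__":
    main()
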