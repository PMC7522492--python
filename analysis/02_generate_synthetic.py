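#!/usr/bin/env python
"""Generate the synthetic connectogenesis dataset used downstream.

Study conditions: 60 cells born in three bursts (quiescent 345-365 min),
half as equal-birth L/R pairs, planted strategies at the published
population mix, 75% conformity, 43/14/43% stability mix. Writes
results/synthetic/ (catalog.csv, synapses.csv, truth.json).
"""

from pathlib import Path

from connectogenesis import GeneratorSpec, generate

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 1


def main() -> None:
    spec = GeneratorSpec(seed=SEED)
    ds = generate(spec)
    paths = ds.write(OUT)
    n_violating = len(ds.truth["violating_edges"])
    n_edges = len(ds.records)
    print(
        f"generated {len(ds.catalog)} cells, {n_edges} connections "
        f"({n_violating} strategy-violating, "
        f"{1 - n_violating / n_edges:.0%} conforming)"
    )
    for name, path in paths.items():
        print(f"  {name}: {path.relative_to(OUT.parent.parent)}")


if __name__ == "__main__":
    main()
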