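#!/usr/bin/env python
"""Recompute the published strategy tables from the bundled cell lists.

The five printed strategy membership lists are the primary data: their
union (53 cell classes) is the analyzed population, and every headline
number - per-strategy frequencies, refinement overlaps, the NSY-5
subnetwork split, the 300-to-400-minute family cohort, the profile
conformity, and the pairwise-matrix scale - follows from them by counting.
Writes results/published_tables/.
"""

from pathlib import Path

import pandas as pd

from connectogenesis import (
    StrategyProfile,
    assignments_from_lists,
    conformity,
    fixtures,
    frequency_table,
    load_catalog,
    overlap,
    pairwise_matrix,
    subnetwork_strategy_split,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "published_tables"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fx = fixtures()
    assignments = assignments_from_lists(fx.strategies)

    ft = frequency_table(assignments)
    freq = ft.to_frame()
    freq["percent"] = (100 * freq["fraction"]).round(1)
    freq["published_percent"] = pd.Series(fx.strategy_frequencies_pct)
    freq.to_csv(OUT / "strategy_frequencies.csv")
    print(f"strategy population: {ft.denominator} cell classes")
    print(freq[["count", "percent", "published_percent"]], "\n")

    rows = []
    for s2 in ("XNOR", "XOR_FIRST", "XOR_SECOND"):
        shared, possible = overlap(assignments, "NP", s2)
        rows.append(("NP", s2, shared, possible))
    overlaps = pd.DataFrame(
        rows, columns=["strategy_a", "strategy_b", "shared", "possible"]
    )
    overlaps.to_csv(OUT / "strategy_overlaps.csv", index=False)
    print("N-P refinement overlaps (shared/possible):")
    print(overlaps, "\n")

    split = subnetwork_strategy_split(assignments, fx.nsy5_pn_classes)
    pd.Series(split, name="cells").to_csv(OUT / "nsy5_split.csv")
    print(
        f"NSY-5 P-N classes expand to {split['PN']} cells, "
        f"all P-N strategists\n"
    )

    fam = pd.Series(fx.family_counts_300_400, name="new_cells")
    fam.to_csv(OUT / "family_counts_300_400.csv")
    print(
        f"{fam.sum()} neurons differentiate between 300 and 400 min; "
        f"largest family {fam.idxmax()} with {fam.max()} cells\n"
    )

    profile = StrategyProfile.from_nested(fx.strategy_profile)
    print(f"example profile conformity: {conformity(profile):.2f}")

    classes = sorted(fx.all_strategy_cells)
    catalog = load_catalog(
        pd.DataFrame(
            {"name": classes,
             "birth_time": [265.0 + i for i in range(len(classes))]}
        )
    )
    m = pairwise_matrix(catalog, classes)
    print(f"pairwise matrix over {len(classes)} classes: {m.size} entries")


if __name__ == "__main__":
    main()
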