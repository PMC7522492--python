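"""Synthetic catalogs and synapse tables with planted structure.

The generator emulates the statistical shape of the real developmental
dataset: bursty birth-time schedules with a quiescent window, left/right
cell pairs sharing a birth time, per-cell planted wiring strategies at a
stated conformity, and the transient/developmental/stable synapse mix. It
exists so that every pipeline stage - loading, snapshotting, classification,
population summaries - is testable end to end against known ground truth
without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stackelberg
from .cell_catalog import CellCatalog, load_catalog
from .first_mover import NP, PN, XNOR, XOR_FIRST, XOR_SECOND
from .fixtures import fixtures  # re-exported: bundled in-text datasets
from .synapse_table import SynapseRecord, to_frame

__all__ = ["GeneratorSpec", "SyntheticDataset", "generate", "fixtures"]

#: default burst windows (start, end, weight): the three developmental
#: birth bursts, weighted by window length, with the 345-365 min window
#: quiescent by construction
DEFAULT_BURSTS: tuple[tuple[float, float, float], ...] = (
    (210.0, 285.0, 75 / 170),
    (285.0, 345.0, 60 / 170),
    (365.0, 400.0, 35 / 170),
)

#: exclusive planted-label weights from the published strategy lists
#: (plain N-P 7, XOR-First 4, XOR-Second 10, XNOR 8, P-N 24 of 53 classes)
DEFAULT_STRATEGY_WEIGHTS: dict[str, float] = {
    NP: 7 / 53,
    XOR_FIRST: 4 / 53,
    XOR_SECOND: 10 / 53,
    XNOR: 8 / 53,
    PN: 24 / 53,
}


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic connectogenesis dataset.

    Defaults reproduce the study conditions: three birth bursts between 210
    and 400 minutes post-fertilization separated by a 345-365 min quiescent
    window, roughly half the cells created as equal-birth L/R pairs,
    planted strategies at the published population mix, 75% conformity, and
    a 43/14/43% transient/developmental/stable synapse mix.
    """

    n_cells: int = 60
    burst_windows: tuple[tuple[float, float, float], ...] = DEFAULT_BURSTS
    pair_fraction: float = 0.5
    planted_strategies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRATEGY_WEIGHTS)
    )
    conformity: float = 0.75
    class_mix: tuple[float, float, float] = (0.43, 0.14, 0.43)
    attach_rate: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise GeneratorError("n_cells must be >= 1")
        if not 0.0 <= self.pair_fraction <= 1.0:
            raise GeneratorError("pair_fraction must be in [0, 1]")
        if not 0.0 <= self.conformity <= 1.0:
            raise GeneratorError("conformity must be in [0, 1]")
        if self.attach_rate < 0:
            raise GeneratorError("attach_rate must be >= 0")
        if self.attach_rate > 0 and self.n_cells == 1:
            raise GeneratorError("cannot attach edges with a single cell")
        w = sum(weight for _, _, weight in self.burst_windows)
        if abs(w - 1.0) > 1e-9:
            raise GeneratorError(f"burst weights sum to {w}, not 1")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise GeneratorError("class_mix must sum to 1")
        p = sum(self.planted_strategies.values())
        if abs(p - 1.0) > 1e-9:
            raise GeneratorError(f"strategy weights sum to {p}, not 1")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated catalog + synapse table + complete ground truth."""

    catalog: CellCatalog
    records: tuple[SynapseRecord, ...]
    truth: dict

    def catalog_frame(self) -> pd.DataFrame:
        return self.catalog.to_frame()

    def synapse_frame(self) -> pd.DataFrame:
        return to_frame(self.records)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write catalog CSV, synapse CSV and ground-truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "catalog": outdir / "catalog.csv",
            "synapses": outdir / "synapses.csv",
            "truth": outdir / "truth.json",
        }
        self.catalog_frame().to_csv(paths["catalog"], index=False)
        self.synapse_frame().to_csv(paths["synapses"], index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


def _draw_birth_time(
    rng: np.random.Generator, windows: Sequence[tuple[float, float, float]]
) -> float:
    weights = np.array([w for _, _, w in windows])
    i = rng.choice(len(windows), p=weights / weights.sum())
    lo, hi, _ = windows[i]
    # whole minutes, as in the source tables; creates natural birth ties
    return float(np.floor(rng.uniform(lo, hi)))


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Generate a synthetic dataset per ``spec``.

    Cells are created as equal-birth L/R pairs (sharing a planted strategy,
    like real bilateral classes) or single cells, with birth times drawn
    uniformly within weighted burst windows. Edges come from
    :func:`connectogenesis.stackelberg.simulate_growth` with the planted
    labels; the truth dict records every planted label, every edge's
    initiator and conformity, and the generator spec.
    """
    rng = np.random.default_rng(spec.seed)

    births: dict[str, float] = {}
    planted: dict[str, str] = {}
    strat_names = sorted(spec.planted_strategies)
    strat_p = np.array([spec.planted_strategies[s] for s in strat_names])
    strat_p = strat_p / strat_p.sum()

    i = 0
    serial = 0
    while i < spec.n_cells:
        t = _draw_birth_time(rng, spec.burst_windows)
        label = strat_names[rng.choice(len(strat_names), p=strat_p)]
        paired = spec.n_cells - i >= 2 and rng.random() < spec.pair_fraction
        stem = f"SC{serial:03d}"
        serial += 1
        if paired:
            for side in ("L", "R"):
                births[stem + side] = t
                planted[stem + side] = label
            i += 2
        else:
            births[stem] = t
            planted[stem] = label
            i += 1

    if spec.n_cells == 1 or spec.attach_rate == 0:
        records: list[SynapseRecord] = []
        truth_growth = stackelberg.GrowthTruth(labels=dict(planted))
    else:
        records, truth_growth = stackelberg.simulate_growth(
            births,
            planted,
            conformity=spec.conformity,
            attach_rate=spec.attach_rate,
            seed=rng,
            class_mix=spec.class_mix,
        )

    catalog = load_catalog(
        pd.DataFrame(
            {
                "name": sorted(births),
                "birth_time": [births[c] for c in sorted(births)],
            }
        )
    )
    truth = {
        "planted_labels": truth_growth.labels,
        "edges": truth_growth.edges,
        "violating_edges": [
            e for e in truth_growth.edges if not e["conforming"]
        ],
        "spec": {
            "n_cells": spec.n_cells,
            "pair_fraction": spec.pair_fraction,
            "conformity": spec.conformity,
            "attach_rate": spec.attach_rate,
            "class_mix": list(spec.class_mix),
            "seed": spec.seed,
        },
    }
    return SyntheticDataset(
        catalog=catalog, records=tuple(records), truth=truth
    )
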