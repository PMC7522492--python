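"""Population-level summaries of strategy assignments.

Frequencies (share of assigned cells carrying each label), pairwise label
overlaps, stability-class composition per strategy, per-strategy birth-time
CDFs, and synaptic density by birth time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cell_catalog import CellCatalog, expand_pairs
from .fixtures import STABILITY_CLASSES, STRATEGIES
from .first_mover import StrategyAssignment
from .synapse_table import SynapseRecord


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class FrequencyTable:
    """Per-strategy counts and population fractions.

    The denominator is the number of distinct strategy-assigned cells; label
    counts may sum to more than that because NP refinements overlap NP.
    ``stability`` holds, per strategy, the proportion of each stability
    class among connections incident to that strategy's cells (each row sums
    to 1), when connection data were supplied.
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    denominator: int
    stability: dict[str, dict[str, float]] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "count": pd.Series(self.counts),
                "fraction": pd.Series(self.fractions),
            }
        )
        if self.stability is not None:
            for cls in STABILITY_CLASSES:
                df[cls] = pd.Series(
                    {s: p.get(cls, 0.0) for s, p in self.stability.items()}
                )
        df.index.name = "strategy"
        return df


def frequency_table(
    assignments: Mapping[str, StrategyAssignment],
    records: Iterable[SynapseRecord] | None = None,
) -> FrequencyTable:
    """Tabulate label frequencies over the assigned-cell population.

    ``fraction(s) = |cells with label s| / |cells with any label|``. With
    ``records``, the stability-class composition of each strategy's incident
    connections is added.
    """
    if not assignments:
        raise StatsError("no assignments supplied")
    denom = len(assignments)
    counts = {
        s: sum(1 for a in assignments.values() if s in a.labels)
        for s in STRATEGIES
    }
    fractions = {s: counts[s] / denom for s in STRATEGIES}

    stability = None
    if records is not None:
        records = list(records)
        stability = {}
        for s in STRATEGIES:
            members = {c for c, a in assignments.items() if s in a.labels}
            incident = [
                r for r in records if r.pre in members or r.post in members
            ]
            if incident:
                n = len(incident)
                stability[s] = {
                    cls: sum(1 for r in incident if r.stability == cls) / n
                    for cls in STABILITY_CLASSES
                }
            else:
                stability[s] = {cls: float("nan") for cls in STABILITY_CLASSES}
    return FrequencyTable(
        counts=counts, fractions=fractions, denominator=denom,
        stability=stability,
    )


def overlap(
    assignments: Mapping[str, StrategyAssignment], s1: str, s2: str
) -> tuple[int, int]:
    """Co-employment of two strategies: (shared cells, possible cells).

    ``possible`` is the size of the rarer label's member set - the maximum
    number of cells the two labels could share.
    """
    for s in (s1, s2):
        if s not in STRATEGIES:
            raise StatsError(f"unknown strategy {s!r}")
    m1 = {c for c, a in assignments.items() if s1 in a.labels}
    m2 = {c for c, a in assignments.items() if s2 in a.labels}
    return len(m1 & m2), min(len(m1), len(m2))


def subnetwork_strategy_split(
    assignments: Mapping[str, StrategyAssignment],
    member_classes: Iterable[str],
    *,
    unpaired: Iterable[str] = (),
) -> dict[str, int]:
    """Per-strategy cell counts within a subnetwork, after L/R expansion.

    Each member class expands to its left/right cells (unless flagged
    unpaired) and inherits the class-level assignment. Expanded cells whose
    class carries no assignment are tallied under ``"unassigned"``.
    """
    member_classes = list(member_classes)
    counts: dict[str, int] = {s: 0 for s in STRATEGIES}
    counts["unassigned"] = 0
    unpaired_set = set(unpaired)
    for cls_name in member_classes:
        expanded = expand_pairs([cls_name], unpaired=unpaired_set)
        assignment = assignments.get(cls_name)
        for _cell in expanded:
            if assignment is None:
                counts["unassigned"] += 1
            else:
                for label in assignment.labels:
                    counts[label] += 1
    return counts


def birth_time_cdf(
    assignments: Mapping[str, StrategyAssignment],
    catalog: CellCatalog,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Empirical CDF of member birth times, per strategy.

    Returns ``{strategy: (times, cumulative_fraction)}`` where ``times`` are
    the sorted member birth times and the CDF steps from 0 up to exactly 1
    at the latest member birth (right-continuous step function).
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in STRATEGIES:
        births = sorted(
            catalog.birth_time(c)
            for c, a in assignments.items()
            if s in a.labels
        )
        if not births:
            continue
        times = np.asarray(births, dtype=float)
        cum = np.arange(1, len(births) + 1) / len(births)
        out[s] = (times, cum)
    return out


def evaluate_cdf(times: np.ndarray, cum: np.ndarray, t: float) -> float:
    """Right-continuous evaluation of an empirical CDF at ``t``."""
    idx = np.searchsorted(times, t, side="right")
    return 0.0 if idx == 0 else float(cum[idx - 1])


def synaptic_density(
    records: Iterable[SynapseRecord],
    catalog: CellCatalog,
    role: str,
) -> pd.DataFrame:
    """Mean connection count per cell by birth time and stability class.

    For each birth time ``t`` present in the catalog and each stability
    class, the number of connections whose ``role`` endpoint (presynaptic or
    postsynaptic cell) was born at ``t``, divided by the number of catalog
    cells born at ``t``. Indexed by birth time with one column per class.
    """
    if role not in ("pre", "post"):
        raise StatsError(f"role must be 'pre' or 'post', got {role!r}")
    records = list(records)
    births = pd.Series(
        {r.name: r.birth_time for r in catalog}, name="birth_time"
    )
    cells_per_time = births.value_counts().sort_index()

    rows = []
    for rec in records:
        endpoint = rec.pre if role == "pre" else rec.post
        rows.append((births[endpoint], rec.stability))
    counts = (
        pd.DataFrame(rows, columns=["birth_time", "stability"])
        .groupby(["birth_time", "stability"])
        .size()
        .unstack(fill_value=0)
        if rows
        else pd.DataFrame()
    )
    out = counts.reindex(
        index=cells_per_time.index, columns=list(STABILITY_CLASSES),
        fill_value=0,
    ).fillna(0)
    return out.div(cells_per_time, axis=0)
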