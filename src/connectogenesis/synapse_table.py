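"""Stability-classified directed chemical synaptic connections.

Each record is a presynaptic-to-postsynaptic cell-cell relationship carrying
one of three larval stability classes: *transient* (variable across
individuals), *developmental* (formed or eliminated during development), or
*stable* (stereotyped from hatch through L4). Gap junctions are outside this
schema; only chemical connections enter the first-mover analysis.

The central derived quantity is the signed *birth time difference*
``delta = birth(pre) - birth(post)``: negative when the presynaptic cell was
born first, positive when it was born second.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cell_catalog import CellCatalog
from .fixtures import STABILITY_CLASSES


class SynapseError(ValueError):
    """Raised for malformed synapse tables."""


@dataclass(frozen=True)
class SynapseRecord:
    """Directed chemical connection ``pre -> post`` with a stability class."""

    pre: str
    post: str
    stability: str

    def __post_init__(self) -> None:
        if self.stability not in STABILITY_CLASSES:
            raise SynapseError(
                f"unknown stability {self.stability!r} for {self.pre}->"
                f"{self.post}; expected one of {STABILITY_CLASSES}"
            )


def load_synapses(
    source: str | Path | pd.DataFrame,
    catalog: CellCatalog | None = None,
    *,
    allow_autapses: bool = False,
    collapse_duplicates: bool = True,
) -> list[SynapseRecord]:
    """Read and validate an edge table with columns ``pre, post, stability``.

    With a catalog, every endpoint must resolve to a known cell; unknown
    names are collected and reported in one error. Duplicate
    ``(pre, post, stability)`` rows are collapsed to a single relationship
    by default (the analysis concerns pairwise relationships, not synapse
    counts); pass ``collapse_duplicates=False`` to keep multiplicity.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        sep = "\t" if str(source).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(source, sep=sep)
    missing = {"pre", "post", "stability"} - set(df.columns)
    if missing:
        raise SynapseError(f"synapse table lacks columns: {sorted(missing)}")

    if collapse_duplicates:
        df = df.drop_duplicates(subset=["pre", "post", "stability"])

    records: list[SynapseRecord] = []
    unknown: set[str] = set()
    for _, row in df.iterrows():
        pre, post = str(row["pre"]).strip(), str(row["post"]).strip()
        if pre == post and not allow_autapses:
            raise SynapseError(f"autapse {pre}->{post} not allowed")
        if catalog is not None:
            if pre not in catalog:
                unknown.add(pre)
            if post not in catalog:
                unknown.add(post)
        records.append(
            SynapseRecord(pre=pre, post=post, stability=str(row["stability"]))
        )
    if unknown:
        raise SynapseError(
            f"cells absent from catalog: {sorted(unknown)}"
        )
    return records


def to_frame(records: Iterable[SynapseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.pre, r.post, r.stability) for r in records],
        columns=["pre", "post", "stability"],
    )


def birth_time_difference(record: SynapseRecord, catalog: CellCatalog) -> float:
    """Signed minutes ``birth(pre) - birth(post)`` for one connection."""
    return catalog.birth_time(record.pre) - catalog.birth_time(record.post)


def pairwise_matrix(
    catalog: CellCatalog, cells: Sequence[str]
) -> pd.DataFrame:
    """All-pairs signed birth-time differences over an ordered cell list.

    Entry ``(i, j)`` is ``birth(i) - birth(j)``; the matrix is antisymmetric
    with a zero diagonal, and includes the diagonal in its entry count (53
    classes give a 53 x 53 = 2,809-entry matrix).
    """
    births = np.array([catalog.birth_time(c) for c in cells], dtype=float)
    mat = births[:, None] - births[None, :]
    return pd.DataFrame(mat, index=list(cells), columns=list(cells))


def difference_histogram(
    records: Iterable[SynapseRecord],
    catalog: CellCatalog,
    *,
    by_stability: bool = True,
    bin_width: float = 10.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Histogram of birth-time differences, optionally split by stability.

    Returns ``{class: (bin_edges, counts)}`` (a single ``"all"`` entry when
    ``by_stability`` is false). All classes share one set of half-open bins
    spanning the observed delta range, so per-class counts are comparable;
    each class's counts sum to its record count.
    """
    records = list(records)
    deltas = np.array(
        [birth_time_difference(r, catalog) for r in records], dtype=float
    )
    if deltas.size == 0:
        return {}
    lo = np.floor(deltas.min() / bin_width) * bin_width
    hi = np.floor(deltas.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)

    def _hist(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.floor((values - lo) / bin_width).astype(int)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        return edges.copy(), counts

    if not by_stability:
        return {"all": _hist(deltas)}
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cls in STABILITY_CLASSES:
        vals = np.array(
            [d for r, d in zip(records, deltas) if r.stability == cls]
        )
        if vals.size:
            out[cls] = _hist(vals)
    return out


def to_graphml(
    records: Iterable[SynapseRecord],
    catalog: CellCatalog,
    path: str | Path,
) -> None:
    """Export the connection table as GraphML with ``stability`` edge and
    ``birth_time`` node attributes."""
    g = nx.MultiDiGraph()
    for rec in records:
        g.add_edge(rec.pre, rec.post, stability=rec.stability)
    for node in g.nodes:
        g.nodes[node]["birth_time"] = catalog.birth_time(node)
    nx.write_graphml(g, path)
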