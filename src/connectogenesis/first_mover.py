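"""Wiring-strategy classification from birth-order statistics.

Each connected cell is assigned one or more of five strategies from the
signs of the birth-time differences over its incident chemical connections
(delta = birth(pre) - birth(post), so negative means the presynaptic cell
was born first):

* **N-P coupling (NP)** - on average over a cell's connections the
  presynaptic partner is born before the postsynaptic partner (mean incident
  delta < 0).
* **XOR First Mover (XOR_FIRST)** - an NP refinement that additionally
  excludes *any* presynaptic partner born after the cell.
* **XOR Second Mover (XOR_SECOND)** - an NP refinement that additionally
  excludes *any* postsynaptic partner born before the cell.
* **XNOR** - the strictest refinement: every presynaptic partner born
  strictly before the cell and every postsynaptic partner strictly after.
* **P-N coupling (PN)** - the mirror tendency (mean incident delta > 0); a
  pure strategy that never co-occurs with the others.

The base NP/PN label is a *majority* (mean-sign) judgement; the refinements
are universal (zero violating connections). Partners born at exactly the
cell's birth time (bilateral pairs) count as neither earlier nor later: such
edges are excluded from the universal tests and enter the mean as delta 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .cell_catalog import CellCatalog
from .synapse_table import SynapseRecord

logger = logging.getLogger(__name__)

NP = "NP"
XOR_FIRST = "XOR_FIRST"
XOR_SECOND = "XOR_SECOND"
XNOR = "XNOR"
PN = "PN"


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class RoleSummary:
    """Per-cell decomposition of incident birth-time differences by role.

    ``pre_role_deltas`` are deltas of connections where the cell is
    presynaptic (delta = birth(cell) - birth(post)); ``post_role_deltas``
    where it is postsynaptic (delta = birth(pre) - birth(cell)). The two
    lists partition the cell's incident connections.
    """

    cell: str
    pre_role_deltas: tuple[float, ...]
    post_role_deltas: tuple[float, ...]

    @property
    def all_deltas(self) -> tuple[float, ...]:
        return self.pre_role_deltas + self.post_role_deltas

    @property
    def mean_delta_all(self) -> float:
        deltas = self.all_deltas
        return sum(deltas) / len(deltas)

    @property
    def neg_component(self) -> float | None:
        neg = [d for d in self.all_deltas if d < 0]
        return sum(neg) / len(neg) if neg else None

    @property
    def pos_component(self) -> float | None:
        pos = [d for d in self.all_deltas if d > 0]
        return sum(pos) / len(pos) if pos else None

    @property
    def n_connections(self) -> int:
        return len(self.pre_role_deltas) + len(self.post_role_deltas)


@dataclass(frozen=True)
class StrategyAssignment:
    """Non-empty strategy label set for one cell.

    PN never co-occurs with other labels; at most one of the NP refinements
    (XOR_FIRST, XOR_SECOND, XNOR) is attached alongside NP.
    """

    cell: str
    labels: frozenset[str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ClassificationError(f"{self.cell}: empty label set")
        if PN in self.labels and len(self.labels) > 1:
            raise ClassificationError(f"{self.cell}: PN is a pure strategy")
        if len(self.labels & {XOR_FIRST, XOR_SECOND, XNOR}) > 1:
            raise ClassificationError(
                f"{self.cell}: refinements are mutually exclusive"
            )


@dataclass(frozen=True)
class Policy:
    """Tunable readings of the strategy definitions.

    tie_label
        Base label when the mean incident delta is exactly 0 (bilateral
        pairs can produce exact ties); default NP, logged.
    strict_refinements
        When true (default) the XOR/XNOR tests are universal: a single
        violating connection disqualifies. When false, a tolerated violation
        fraction applies instead.
    refinement_tolerance
        Max fraction of violating connections permitted per universal test
        when ``strict_refinements`` is false.
    """

    tie_label: str = NP
    strict_refinements: bool = True
    refinement_tolerance: float = 0.0


def role_summary(
    cell: str,
    records: Iterable[SynapseRecord],
    catalog: CellCatalog,
) -> RoleSummary:
    """Partition a cell's incident connections into pre/post-role deltas."""
    pre_deltas: list[float] = []
    post_deltas: list[float] = []
    bt = catalog.birth_time
    for rec in records:
        if rec.pre == cell:
            pre_deltas.append(bt(cell) - bt(rec.post))
        elif rec.post == cell:
            post_deltas.append(bt(rec.pre) - bt(cell))
    if not pre_deltas and not post_deltas:
        raise ClassificationError(f"{cell}: no incident connections")
    return RoleSummary(
        cell=cell,
        pre_role_deltas=tuple(pre_deltas),
        post_role_deltas=tuple(post_deltas),
    )


def _universal(deltas: Iterable[float], policy: Policy) -> bool:
    """True when (almost) every nonzero delta is negative.

    A delta of 0 (partner born the same minute) is excluded from the test.
    Vacuously true over an empty set.
    """
    nonzero = [d for d in deltas if d != 0]
    if not nonzero:
        return True
    violations = sum(1 for d in nonzero if d > 0)
    if policy.strict_refinements:
        return violations == 0
    return violations / len(nonzero) <= policy.refinement_tolerance


def classify_strategy(
    summary: RoleSummary, policy: Policy = Policy()
) -> StrategyAssignment:
    """Assign strategy labels to one cell from its role summary.

    The base label follows the sign of the mean delta over all incident
    connections (negative -> NP, positive -> PN; exact zero resolved by
    ``policy.tie_label``). For NP cells, refinements are tested in order of
    strictness: XNOR (every presynaptic partner strictly earlier *and* every
    postsynaptic partner strictly later), then XOR_FIRST (presynaptic
    condition alone), then XOR_SECOND (postsynaptic condition alone); the
    first that holds is attached alongside NP.
    """
    mean = summary.mean_delta_all
    if mean > 0:
        base = PN
    elif mean < 0:
        base = NP
    else:
        base = policy.tie_label
        logger.info("cell %s: mean delta tie, labeled %s", summary.cell, base)
    if base == PN:
        return StrategyAssignment(cell=summary.cell, labels=frozenset({PN}))

    # negative post-role delta <=> presynaptic partner born before the cell;
    # negative pre-role delta <=> postsynaptic partner born after the cell
    pre_partners_earlier = _universal(summary.post_role_deltas, policy)
    post_partners_later = _universal(summary.pre_role_deltas, policy)

    labels = {NP}
    if pre_partners_earlier and post_partners_later:
        labels.add(XNOR)
    elif pre_partners_earlier:
        labels.add(XOR_FIRST)
    elif post_partners_later:
        labels.add(XOR_SECOND)
    return StrategyAssignment(cell=summary.cell, labels=frozenset(labels))


def assign_all(
    records: Iterable[SynapseRecord],
    catalog: CellCatalog,
    policy: Policy = Policy(),
) -> dict[str, StrategyAssignment]:
    """Classify every cell incident to at least one connection.

    Deterministic given inputs and policy, and independent of record order.
    Per-cell failures are logged and the cell skipped.
    """
    records = list(records)
    cells = sorted({r.pre for r in records} | {r.post for r in records})
    out: dict[str, StrategyAssignment] = {}
    for cell in cells:
        try:
            out[cell] = classify_strategy(
                role_summary(cell, records, catalog), policy
            )
        except ClassificationError as exc:  # pragma: no cover - defensive
            logger.warning("skipping %s: %s", cell, exc)
    return out


def assignments_from_lists(
    lists: Mapping[str, Iterable[str]]
) -> dict[str, StrategyAssignment]:
    """Build assignments from per-strategy membership lists.

    Used to load printed strategy lists as ground-truth assignments: each
    cell's label set is the union of the lists containing it.
    """
    by_cell: dict[str, set[str]] = {}
    for label, cells in lists.items():
        for cell in cells:
            by_cell.setdefault(cell, set()).add(label)
    return {
        cell: StrategyAssignment(cell=cell, labels=frozenset(labels))
        for cell, labels in sorted(by_cell.items())
    }


def assignments_to_frame(
    assignments: Mapping[str, StrategyAssignment]
) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {
            "cell": list(assignments),
            "labels": [
                ";".join(sorted(a.labels)) for a in assignments.values()
            ],
        }
    )
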