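"""Leader-follower (Stackelberg) machinery: profiles, payoffs, growth model.

A *strategy profile* is a joint probability over (synaptic role x birth
order) for a single cell; its *conformity* is the probability mass on the
leader-follower-consistent cells (presynaptic partner born first,
postsynaptic partner born second).

The *payoff matrix* gives the utility to a presynaptic cell of being a
first mover, subsequent mover, or random mover against each opposing mover
type, parameterized by FREQ (empirically observed frequency), M (molecular
milieu estimate) and N (neurophysiological milieu estimate).

``simulate_growth`` grows a synthetic connectome sequentially: cells enter
in birth order and connect to already-born cells, with edge directions
conforming to each cell's planted wiring strategy with a given probability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .first_mover import NP, PN, XNOR, XOR_FIRST, XOR_SECOND
from .fixtures import STABILITY_CLASSES
from .synapse_table import SynapseRecord

logger = logging.getLogger(__name__)

ROLES = ("presynaptic", "postsynaptic")
ORDERS = ("born_first", "born_second")
MOVER_TYPES = ("first", "subsequent", "random")

#: strategies whose base tendency is negative mean delta (pre born first)
NP_FAMILY = frozenset({NP, XOR_FIRST, XOR_SECOND, XNOR})

_PROB_TOL = 1e-9


class GameError(ValueError):
    pass


@dataclass(frozen=True)
class StrategyProfile:
    """2x2 joint probability over (role, birth order), summing to 1."""

    p: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        total = 0.0
        for role in ROLES:
            for order in ORDERS:
                v = self.p[role][order]
                if v < 0:
                    raise GameError(f"negative probability p[{role}][{order}]")
                total += v
        if abs(total - 1.0) > _PROB_TOL:
            raise GameError(f"profile probabilities sum to {total}, not 1")

    @classmethod
    def from_nested(cls, nested: Mapping) -> "StrategyProfile":
        return cls(p={r: dict(nested[r]) for r in ROLES})


def conformity(profile: StrategyProfile) -> float:
    """Probability the cell behaves as a leader-follower conformist.

    The mass on (presynaptic partner born first) plus (postsynaptic partner
    born second) - the two cells of the profile consistent with earlier-born
    presynaptic cells driving connections.
    """
    return (
        profile.p["presynaptic"]["born_first"]
        + profile.p["postsynaptic"]["born_second"]
    )


@dataclass(frozen=True)
class PayoffMatrix:
    """Utilities for a presynaptic cell by (own mover type, opponent type).

    Off-diagonal entries follow the published formulation:

    ====================  ======================
    (first, subsequent)   FREQ * (M + N)
    (first, random)       FREQ * 0.5
    (subsequent, first)   1 - FREQ * (M + N)
    (subsequent, random)  FREQ / 0.5
    (random, first)       FREQ * 0.5
    (random, subsequent)  FREQ / 0.5
    ====================  ======================

    The (subsequent, random) entry is read literally as FREQ divided by 0.5
    (= 2 FREQ); set ``subsequent_random_literal=False`` to use FREQ * 0.5
    instead (the plausible intended reading). The diagonal (self-play) is
    undefined.
    """

    freq: float
    m: float
    n: float
    subsequent_random_literal: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq <= 1.0:
            raise GameError(f"FREQ must be in [0, 1], got {self.freq}")
        if self.m < 0 or self.n < 0:
            raise GameError("M and N must be non-negative")
        if self.freq * (self.m + self.n) > 1.0 + _PROB_TOL:
            warnings.warn(
                "FREQ * (M + N) > 1: utilities leave [0, 1]",
                stacklevel=2,
            )


def payoff(matrix: PayoffMatrix, row: str, col: str) -> float:
    """Utility of mover type ``row`` against opponent type ``col``."""
    for mover in (row, col):
        if mover not in MOVER_TYPES:
            raise GameError(f"unknown mover type {mover!r}")
    if row == col:
        raise GameError("diagonal undefined: no self-play")
    fq, m, n = matrix.freq, matrix.m, matrix.n
    sub_random = fq / 0.5 if matrix.subsequent_random_literal else fq * 0.5
    table = {
        ("first", "subsequent"): fq * (m + n),
        ("first", "random"): fq * 0.5,
        ("subsequent", "first"): 1.0 - fq * (m + n),
        ("subsequent", "random"): sub_random,
        ("random", "first"): fq * 0.5,
        ("random", "subsequent"): sub_random,
    }
    return table[(row, col)]


# ---------------------------------------------------------------------------
# sequential growth simulator
# ---------------------------------------------------------------------------

#: which strategies tolerate being the *older, postsynaptic* end of a
#: positive-delta edge (a younger presynaptic partner): excludes XOR_FIRST
#: and XNOR, whose definitions forbid presynaptic partners born later.
_TOLERATES_YOUNG_PRE = frozenset({PN, NP, XOR_SECOND})
#: which strategies tolerate being the *younger, presynaptic* end of a
#: positive-delta edge (an older postsynaptic partner): excludes XOR_SECOND
#: and XNOR, whose definitions forbid postsynaptic partners born earlier.
_TOLERATES_OLD_POST = frozenset({PN, NP, XOR_FIRST})


@dataclass
class GrowthTruth:
    """Provenance of every simulated edge and the planted labels."""

    labels: dict[str, str]
    edges: list[dict] = field(default_factory=list)


def _draw_stability(rng: np.random.Generator, mix: Sequence[float]) -> str:
    return STABILITY_CLASSES[rng.choice(len(STABILITY_CLASSES), p=list(mix))]


def feasible_labels(
    has_strict_elder: bool, has_strict_junior: bool
) -> frozenset[str]:
    """Strategy labels realizable at a birth-order position.

    Plain NP requires both an older postsynaptic partner and a younger
    presynaptic partner; XOR_FIRST requires an older postsynaptic partner;
    XOR_SECOND a younger presynaptic partner. Cells at the extremes of the
    birth order therefore cannot realize some labels.
    """
    labels = {XNOR, PN}
    if has_strict_elder:
        labels.add(XOR_FIRST)
    if has_strict_junior:
        labels.add(XOR_SECOND)
    if has_strict_elder and has_strict_junior:
        labels.add(NP)
    return frozenset(labels)


def repair_labels(
    order: Sequence[str],
    births: Mapping[str, float],
    labels: dict[str, str],
    rng: np.random.Generator,
) -> dict[str, str]:
    """Replant labels that are infeasible at their birth-order position.

    The cells tied at the earliest and latest birth times are anchored to
    PN: PN is feasible at both extremes, and a PN cell at each extreme
    guarantees every interior cell the older postsynaptic partner
    (NP, XOR_FIRST) or younger presynaptic partner (NP, XOR_SECOND) its
    planted definition requires.
    """
    del rng  # anchoring is deterministic
    labels = dict(labels)
    times = sorted({births[c] for c in order})
    lo, hi = times[0], times[-1]
    if lo == hi:
        return labels
    for cell in order:
        if births[cell] in (lo, hi) and labels[cell] != PN:
            logger.info(
                "cell %s: label %s replanted PN at birth extreme",
                cell, labels[cell],
            )
            labels[cell] = PN
    return labels


def simulate_growth(
    birth_schedule: Mapping[str, float],
    strategies: Mapping[str, str],
    conformity: float,
    attach_rate: float,
    seed: int | np.random.Generator,
    *,
    class_mix: Sequence[float] = (0.43, 0.14, 0.43),
    partner_kernel: Callable[[Sequence[str], np.random.Generator], str]
    | None = None,
    repair_infeasible: bool = True,
) -> tuple[list[SynapseRecord], GrowthTruth]:
    """Grow a synthetic chemical connectome by sequential competition.

    Cells enter the network in birth order. Each new cell draws on the
    order of ``attach_rate`` partners among strictly earlier-born cells; the
    edge direction conforms to the new cell's planted strategy with
    probability ``conformity`` and is inverted otherwise. Cells planted with
    the non-exclusive strategies additionally place the minority edges their
    definitions require (an older postsynaptic partner for NP and
    XOR_FIRST; a younger presynaptic partner for NP and XOR_SECOND). At
    ``conformity == 1.0`` the simulator guarantees that every cell's
    realized connection pattern satisfies its planted definition, so
    classification recovers the planted labels exactly.

    Returns the synapse records (stability classes drawn from ``class_mix``)
    and a :class:`GrowthTruth` with per-edge provenance.
    """
    if not birth_schedule:
        raise GameError("empty birth schedule")
    if not 0.0 <= conformity <= 1.0:
        raise GameError(f"conformity must be in [0, 1], got {conformity}")
    if attach_rate < 0:
        raise GameError(f"attach_rate must be >= 0, got {attach_rate}")
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise GameError("class_mix must sum to 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    order = sorted(birth_schedule, key=lambda c: (birth_schedule[c], c))
    births = dict(birth_schedule)
    labels = {c: strategies[c] for c in order}
    if repair_infeasible and len(order) > 1:
        labels = repair_labels(order, births, labels, rng)

    edges: set[tuple[str, str]] = set()
    truth = GrowthTruth(labels=dict(labels))
    records: list[SynapseRecord] = []

    def _add_edge(pre: str, post: str, initiator: str, kind: str,
                  conforming: bool) -> bool:
        if (pre, post) in edges or pre == post:
            return False
        edges.add((pre, post))
        stability = _draw_stability(rng, class_mix)
        records.append(SynapseRecord(pre=pre, post=post, stability=stability))
        truth.edges.append(
            {
                "pre": pre,
                "post": post,
                "stability": stability,
                "initiator": initiator,
                "conforming": conforming,
                "kind": kind,
            }
        )
        return True

    def _choose(pool: Sequence[str]) -> str:
        if partner_kernel is not None:
            return partner_kernel(pool, rng)
        return pool[rng.choice(len(pool))]

    def _needs_young_pre(cell: str) -> bool:
        return labels[cell] in (NP, XOR_SECOND) and not any(
            p == cell and births[q] > births[cell] for q, p in edges
        )

    for j in order:
        elders = [c for c in order if births[c] < births[j]]
        if not elders:
            continue
        n_draws = max(1, int(rng.poisson(attach_rate)))
        for _ in range(n_draws):
            conforming = bool(rng.random() < conformity)
            if labels[j] in NP_FAMILY:
                pool = [c for c in elders if labels[c] in NP_FAMILY]
                direction = "in"  # elder presynaptic, newcomer postsynaptic
            else:  # PN: newcomer presynaptic toward an older partner,
                # preferring PN elders (for whom the edge also conforms)
                pool = [c for c in elders if labels[c] == PN] or [
                    c for c in elders if labels[c] in _TOLERATES_YOUNG_PRE
                ]
                direction = "out"
            if not conforming:
                pool = elders
                direction = "out" if direction == "in" else "in"
            if not pool:
                continue  # no strategy-compatible elder for this draw
            partner = _choose(pool)
            if direction == "in":
                _add_edge(partner, j, j, "attachment", conforming)
            else:
                _add_edge(j, partner, j, "attachment", conforming)

        # definitional minority edges: NP/XOR_FIRST newcomers take one older
        # postsynaptic partner, preferring elders still owed a younger
        # presynaptic partner (which services NP/XOR_SECOND definitions).
        # Only placed at full conformity - below it, the random direction
        # flips already supply each cell's minority mass.
        if conformity >= 1.0 and labels[j] in _TOLERATES_OLD_POST \
                and labels[j] != PN:
            pool = [c for c in elders if labels[c] in _TOLERATES_YOUNG_PRE]
            needy = [c for c in pool if _needs_young_pre(c)]
            use = needy or pool
            if use:
                # nearest elder keeps the positive delta a minority in the mean
                use = sorted(use, key=lambda c: (births[j] - births[c], c))
                for candidate in use:
                    if _add_edge(j, candidate, j, "shaping", True):
                        break

    _connect_isolated(order, births, labels, edges, _add_edge)
    if conformity >= 1.0:
        _finalize_definitions(order, births, labels, edges, _add_edge)
        _balance_means(order, births, labels, edges, _add_edge, rng)

    return records, truth


def _connect_isolated(order, births, labels, edges, add_edge) -> None:
    """Give every cell at least one strategy-conforming connection.

    The earliest-born cells place no edges of their own (no elders exist
    yet) and may never be drawn as partners; they are wired here in the
    direction their planted strategy prescribes.
    """
    incident = {c: 0 for c in order}
    for pre, post in edges:
        incident[pre] += 1
        incident[post] += 1
    for c in order:
        if incident[c]:
            continue
        if labels[c] in NP_FAMILY:
            juniors = [
                x for x in order
                if births[x] > births[c] and labels[x] in NP_FAMILY
            ]
            elders = [
                x for x in order
                if births[x] < births[c] and labels[x] in NP_FAMILY
            ]
            if juniors:  # c presynaptic to a younger cell: conforms both
                x = min(juniors, key=lambda y: (births[y], y))
                add_edge(c, x, x, "isolated", True)
            elif elders:
                x = max(elders, key=lambda y: (births[y], y))
                add_edge(x, c, c, "isolated", True)
        else:  # PN: younger presynaptic partner or older postsynaptic one
            juniors = [
                x for x in order
                if births[x] > births[c]
                and labels[x] in _TOLERATES_OLD_POST
            ]
            elders = [
                x for x in order
                if births[x] < births[c]
                and labels[x] in _TOLERATES_YOUNG_PRE
            ]
            if juniors:
                x = min(juniors, key=lambda y: (births[y], y))
                add_edge(x, c, x, "isolated", True)
            elif elders:
                x = max(elders, key=lambda y: (births[y], y))
                add_edge(c, x, c, "isolated", True)


def _finalize_definitions(order, births, labels, edges, add_edge) -> None:
    """Place any definitional minority edges still missing after growth."""
    incoming = {c: [] for c in order}
    outgoing = {c: [] for c in order}
    for pre, post in edges:
        outgoing[pre].append(post)
        incoming[post].append(pre)

    for c in order:
        if labels[c] in (NP, XOR_SECOND):
            if not any(births[x] > births[c] for x in incoming[c]):
                pool = [
                    x
                    for x in order
                    if births[x] > births[c]
                    and labels[x] in _TOLERATES_OLD_POST
                    and (x, c) not in edges
                ]
                if pool:
                    x = min(pool, key=lambda y: (births[y], y))
                    if add_edge(x, c, x, "definitional", True):
                        incoming[c].append(x)
                        outgoing[x].append(c)
                else:
                    logger.warning(
                        "cell %s (%s): no feasible younger presynaptic "
                        "partner", c, labels[c],
                    )
        if labels[c] in (NP, XOR_FIRST):
            if not any(births[x] < births[c] for x in outgoing[c]):
                pool = [
                    x
                    for x in order
                    if births[x] < births[c]
                    and labels[x] in _TOLERATES_YOUNG_PRE
                    and (c, x) not in edges
                ]
                if pool:
                    x = max(pool, key=lambda y: (births[y], y))
                    if add_edge(c, x, c, "definitional", True):
                        outgoing[c].append(x)
                        incoming[x].append(c)
                else:
                    logger.warning(
                        "cell %s (%s): no feasible older postsynaptic "
                        "partner", c, labels[c],
                    )


def _balance_means(order, births, labels, edges, add_edge, rng) -> None:
    """At full conformity, top up conforming edges until every cell's mean
    incident delta has the sign its planted base strategy prescribes."""

    def mean_delta(c: str) -> float:
        deltas = [
            births[pre] - births[post]
            for pre, post in edges
            if pre == c or post == c
        ]
        return sum(deltas) / len(deltas) if deltas else 0.0

    for _ in range(20):  # outer passes; edge additions interact across cells
        changed = False
        for c in order:
            base_np = labels[c] in NP_FAMILY
            for _ in range(50):
                m = mean_delta(c)
                if (base_np and m < 0) or (not base_np and m > 0):
                    break
                if base_np:
                    # prefer an elder presynaptic partner (negative delta);
                    # fall back to a younger postsynaptic partner, which is
                    # equally conforming for both ends
                    pool = [
                        x for x in order
                        if births[x] < births[c]
                        and labels[x] in NP_FAMILY
                        and (x, c) not in edges
                    ]
                    if pool:
                        x = pool[rng.choice(len(pool))]
                        add_edge(x, c, c, "balance", True)
                    else:
                        pool = [
                            x for x in order
                            if births[x] > births[c]
                            and labels[x] in NP_FAMILY
                            and (c, x) not in edges
                        ]
                        if not pool:
                            break
                        x = pool[rng.choice(len(pool))]
                        add_edge(c, x, x, "balance", True)
                else:
                    # PN: add an elder postsynaptic partner (positive delta),
                    # preferring PN partners whose own mean it also helps
                    pn_pool = [
                        x for x in order
                        if births[x] < births[c]
                        and labels[x] == PN
                        and (c, x) not in edges
                    ]
                    pool = pn_pool or [
                        x for x in order
                        if births[x] < births[c]
                        and labels[x] in _TOLERATES_YOUNG_PRE
                        and (c, x) not in edges
                    ]
                    if not pool:
                        break
                    x = pool[rng.choice(len(pool))]
                    add_edge(c, x, c, "balance", True)
                changed = True
        if not changed:
            return
    logger.warning("mean balancing did not converge in 20 passes")
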