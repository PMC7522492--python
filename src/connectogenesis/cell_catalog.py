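"""Neuron identities, birth times, families, and staged connectome snapshots.

The catalog holds one record per terminally differentiated cell (or cell
class) with its birth time in minutes post-fertilization. Snapshots of the
proto-connectome at a given developmental time are the set of cells born at
or before that time; differencing two snapshots recovers the cohort of newly
differentiated neurons between two sampling points. Cell *families* are
nomenclature groupings sharing a name prefix (e.g. AVDL and AVKR both belong
to AV); *bursts* are maximal runs of non-empty bins in the developmental
birth-time histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fixtures import family_overrides, timeline_constants

HATCH_MINUTES = 800.0

#: suffix letters encoding laterality/position at the end of a cell name
_SUFFIX_LETTERS = frozenset("LRDV")

LATERALITIES = ("left", "right", "unpaired", "class")


class CatalogError(ValueError):
    """Raised for malformed birth-time tables or unresolvable cell names."""


@dataclass(frozen=True)
class CellRecord:
    """A neuron (or neuron class) with its birth time and nomenclature family.

    Parameters
    ----------
    name : str
        Cell or cell-class identifier, e.g. ``"RMEV"``, ``"ADFL"``, ``"AWC"``.
    birth_time : float
        Minutes post-fertilization, in ``[0, 800]`` (hatch).
    family : str
        Nomenclature prefix grouping, e.g. ``"RME"``, ``"ADF"``.
    laterality : str
        One of ``left``, ``right``, ``unpaired``, ``class``.
    """

    name: str
    birth_time: float
    family: str
    laterality: str = "class"

    def __post_init__(self) -> None:
        if not self.name:
            raise CatalogError("cell name must be non-empty")
        if not (0.0 <= self.birth_time <= HATCH_MINUTES):
            raise CatalogError(
                f"cell {self.name!r}: birth_time {self.birth_time} outside "
                f"[0, {HATCH_MINUTES}] minutes"
            )
        if self.laterality not in LATERALITIES:
            raise CatalogError(
                f"cell {self.name!r}: laterality {self.laterality!r} not in "
                f"{LATERALITIES}"
            )


@dataclass(frozen=True)
class StageSnapshot:
    """Membership of the proto-connectome at a developmental time point."""

    time: float
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def parse_family(name: str, overrides: Mapping[str, str] | None = None) -> str:
    """Derive the nomenclature family of a cell name.

    Trailing laterality/position letters (L, R, D, V) are stripped from the
    right while more than two characters remain; a digit blocks further
    stripping so numbered classes (IL1, IL2) keep their digit. Residual
    ambiguities (e.g. URY vs UR) are settled by an override table.
    """
    if overrides is None:
        overrides = family_overrides()
    stem = name
    while len(stem) > 2 and stem[-1] in _SUFFIX_LETTERS and not stem[-2].isdigit():
        stem = stem[:-1]
    # a numbered class keeps everything up to and including the digit
    if len(stem) > 2 and stem[-1] in _SUFFIX_LETTERS and stem[-2].isdigit():
        stem = stem[:-1]
    return overrides.get(stem, stem)


def parse_laterality(name: str) -> str:
    """Heuristic laterality from the final character of a cell name.

    ``L``/``R`` denote the left/right member of a bilateral pair; ``D``/``V``
    endings denote single dorsal/ventral cells (unpaired); anything else is
    treated as a class name (expandable to an L/R pair unless flagged
    otherwise in the catalog).
    """
    if name.endswith("L"):
        return "left"
    if name.endswith("R"):
        return "right"
    if name[-1] in "DV":
        return "unpaired"
    return "class"


def expand_pairs(
    names: Iterable[str], unpaired: Iterable[str] = ()
) -> list[str]:
    """Expand class names to left/right cell names.

    Each name becomes ``name + "L"`` and ``name + "R"`` unless listed in
    ``unpaired``. Names written ``"X/Y"`` shorthand (e.g. ``"IL2L/R"``) are
    expanded on their slash.
    """
    unpaired_set = set(unpaired)
    out: list[str] = []
    for name in names:
        if "/" in name:
            head, *alts = name.split("/")
            prefix = head[:-1]
            out.append(head)
            out.extend(prefix + alt for alt in alts)
        elif name in unpaired_set:
            out.append(name)
        else:
            out.extend((name + "L", name + "R"))
    return out


class CellCatalog:
    """Validated, name-unique collection of :class:`CellRecord`."""

    def __init__(self, records: Iterable[CellRecord]):
        self._records: dict[str, CellRecord] = {}
        for rec in records:
            if rec.name in self._records:
                raise CatalogError(f"duplicate cell name {rec.name!r}")
            self._records[rec.name] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __getitem__(self, name: str) -> CellRecord:
        try:
            return self._records[name]
        except KeyError:
            raise CatalogError(f"unknown cell {name!r}") from None

    @property
    def names(self) -> list[str]:
        return list(self._records)

    def birth_time(self, name: str) -> float:
        return self[name].birth_time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self],
                "birth_time": [r.birth_time for r in self],
                "family": [r.family for r in self],
                "laterality": [r.laterality for r in self],
            }
        )


def load_catalog(source: str | Path | pd.DataFrame) -> CellCatalog:
    """Build a :class:`CellCatalog` from a birth-time table.

    ``source`` is a CSV/TSV path or a DataFrame with columns ``name`` and
    ``birth_time``; optional columns ``family`` and ``laterality`` override
    the name-derived defaults. Duplicate names and negative or missing birth
    times are hard errors naming the offending row.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        sep = "\t" if str(source).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(source, sep=sep)
    missing = {"name", "birth_time"} - set(df.columns)
    if missing:
        raise CatalogError(f"birth-time table lacks columns: {sorted(missing)}")

    records = []
    for idx, row in df.iterrows():
        name = row["name"]
        bt = row["birth_time"]
        if pd.isna(name) or not str(name).strip():
            raise CatalogError(f"row {idx}: missing cell name")
        name = str(name).strip()
        if pd.isna(bt):
            raise CatalogError(f"row {idx} ({name}): missing birth time")
        bt = float(bt)
        if bt < 0:
            raise CatalogError(f"row {idx} ({name}): negative birth time {bt}")
        family = row.get("family")
        if family is None or (isinstance(family, float) and math.isnan(family)):
            family = parse_family(name)
        laterality = row.get("laterality")
        if laterality is None or (
            isinstance(laterality, float) and math.isnan(laterality)
        ):
            laterality = parse_laterality(name)
        records.append(
            CellRecord(
                name=name,
                birth_time=bt,
                family=str(family),
                laterality=str(laterality),
            )
        )
    return CellCatalog(records)


def snapshot(catalog: CellCatalog, t: float) -> StageSnapshot:
    """Proto-connectome membership at time ``t``: cells with birth time <= t.

    A cell born at exactly ``t`` is included, so the 265-minute snapshot
    contains the founder cell born at 265.
    """
    if t < 0:
        raise CatalogError(f"snapshot time must be >= 0, got {t}")
    return StageSnapshot(
        time=t,
        members=frozenset(r.name for r in catalog if r.birth_time <= t),
    )


def snapshot_diff(catalog: CellCatalog, t1: float, t2: float) -> frozenset[str]:
    """Cells born in the half-open interval ``(t1, t2]``."""
    if t1 >= t2:
        raise CatalogError(f"require t1 < t2, got t1={t1}, t2={t2}")
    return frozenset(
        r.name for r in catalog if t1 < r.birth_time <= t2
    )


def family_counts(
    cells: Iterable[str],
    catalog: CellCatalog | None = None,
    overrides: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Count cells per nomenclature family.

    Families come from the catalog when one is given (so explicit family
    columns are honoured), otherwise from :func:`parse_family` on each name.
    Counts always sum to the number of input cells.
    """
    counts: dict[str, int] = {}
    for name in cells:
        if catalog is not None:
            fam = catalog[name].family
        else:
            fam = parse_family(name, overrides)
        counts[fam] = counts.get(fam, 0) + 1
    return dict(sorted(counts.items()))


@dataclass(frozen=True)
class BurstHistogram:
    """Binned developmental birth times plus maximal non-empty runs (bursts)."""

    bin_edges: tuple[float, ...]  # len = n_bins + 1, half-open [lo, hi)
    counts: tuple[int, ...]
    bursts: tuple[tuple[float, float], ...] = field(default=())

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def burst_histogram(
    birth_times: Sequence[float], bin_width: float = 8.0
) -> BurstHistogram:
    """Histogram birth times into half-open bins and find birth bursts.

    The first bin starts at the minimum observed time rounded down to a
    multiple of ``bin_width``; bins are ``[lo, lo + w)``. Bursts are maximal
    runs of consecutive non-empty bins, reported as (start, end) minute
    intervals; runs are separated by at least one empty bin.
    """
    if bin_width <= 0:
        raise CatalogError(f"bin_width must be > 0, got {bin_width}")
    times = np.asarray(list(birth_times), dtype=float)
    if times.size == 0:
        return BurstHistogram(bin_edges=(), counts=(), bursts=())
    lo = math.floor(times.min() / bin_width) * bin_width
    n_bins = int(math.floor((times.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    # np.histogram closes the last bin; widen it so [lo, hi) holds throughout
    idx = np.floor((times - lo) / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)

    bursts: list[tuple[float, float]] = []
    run_start: int | None = None
    for i, c in enumerate(counts):
        if c > 0 and run_start is None:
            run_start = i
        elif c == 0 and run_start is not None:
            bursts.append((float(edges[run_start]), float(edges[i])))
            run_start = None
    if run_start is not None:
        bursts.append((float(edges[run_start]), float(edges[n_bins])))
    return BurstHistogram(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        bursts=tuple(bursts),
    )


def timeline() -> dict:
    """Embryogenesis timeline constants (minutes post-fertilization)."""
    return timeline_constants()
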