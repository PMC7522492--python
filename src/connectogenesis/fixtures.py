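"""Bundled reference data: printed strategy lists and reference tables.

These are the in-text datasets of the source analysis, shipped as versioned
YAML so every downstream computation (frequencies, overlaps, subnetwork
splits, profile conformity) can be recomputed without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

STRATEGIES = ("NP", "XOR_FIRST", "XOR_SECOND", "XNOR", "PN")
STABILITY_CLASSES = ("transient", "developmental", "stable")


def _load_yaml(filename: str) -> dict:
    ref = resources.files("connectogenesis.data").joinpath(filename)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def strategy_lists() -> dict[str, tuple[str, ...]]:
    """The five printed strategy membership lists, by cell class."""
    raw = _load_yaml("strategy_lists.yaml")
    return {k: tuple(v) for k, v in raw.items()}


@lru_cache(maxsize=None)
def reference_tables() -> dict:
    """Strategy profile, family counts, published frequencies, class mix."""
    return _load_yaml("tables.yaml")


@lru_cache(maxsize=None)
def nsy5_network() -> dict[str, tuple[str, ...]]:
    """NSY-5 subnetwork class lists (all paired classes; P-N classes)."""
    raw = _load_yaml("nsy5.yaml")
    return {k: tuple(v) for k, v in raw.items()}


@lru_cache(maxsize=None)
def timeline_constants() -> dict:
    return _load_yaml("timeline.yaml")


@lru_cache(maxsize=None)
def family_overrides() -> dict[str, str]:
    return dict(_load_yaml("family_overrides.yaml"))


@dataclass(frozen=True)
class Fixtures:
    """Convenience bundle of every in-text dataset."""

    strategies: dict[str, tuple[str, ...]]
    strategy_profile: dict
    family_counts_300_400: dict[str, int]
    strategy_frequencies_pct: dict[str, float]
    strategy_stability_pct: dict[str, dict[str, float]]
    stability_class_mix: dict[str, float]
    nsy5_classes: tuple[str, ...]
    nsy5_pn_classes: tuple[str, ...]
    timeline: dict

    @property
    def all_strategy_cells(self) -> frozenset[str]:
        """Union of the five printed lists (53 cell classes)."""
        out: set[str] = set()
        for cells in self.strategies.values():
            out.update(cells)
        return frozenset(out)


def fixtures() -> Fixtures:
    tables = reference_tables()
    nsy5 = nsy5_network()
    return Fixtures(
        strategies=dict(strategy_lists()),
        strategy_profile=tables["strategy_profile"],
        family_counts_300_400=dict(tables["family_counts_300_400"]),
        strategy_frequencies_pct=dict(tables["strategy_frequencies_pct"]),
        strategy_stability_pct={
            k: dict(v) for k, v in tables["strategy_stability_pct"].items()
        },
        stability_class_mix=dict(tables["stability_class_mix"]),
        nsy5_classes=nsy5["classes"],
        nsy5_pn_classes=nsy5["pn_classes"],
        timeline=timeline_constants(),
    )
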