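import pandas as pd
import pytest
from hypothesis import settings

from connectogenesis import load_catalog

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def small_catalog():
    """Five early-born cells with the published founder at 265 min."""
    return load_catalog(
        pd.DataFrame(
            {
                "name": ["RMEV", "ADFL", "ADFR", "AWBL", "AWBR"],
                "birth_time": [265.0, 280.0, 280.0, 280.0, 280.0],
            }
        )
    )


@pytest.fixture
def strategy_oracle():
    """Independent brute-force evaluation of the strategy definitions.

    Works from partner birth times and explicit universal predicates rather
    than from the delta-list machinery of the package, so the two routes
    can disagree if either is wrong.
    """

    def classify(cell, edges, births):
        pre_partners = [p for p, q in edges if q == cell]
        post_partners = [q for p, q in edges if p == cell]
        deltas = [births[p] - births[q] for p, q in edges if cell in (p, q)]
        if not deltas:
            return None
        mean = sum(deltas) / len(deltas)
        if mean > 0:
            return frozenset({"PN"})
        labels = {"NP"}
        all_pre_earlier = all(
            births[p] < births[cell]
            for p in pre_partners
            if births[p] != births[cell]
        )
        all_post_later = all(
            births[q] > births[cell]
            for q in post_partners
            if births[q] != births[cell]
        )
        if all_pre_earlier and all_post_later:
            labels.add("XNOR")
        elif all_pre_earlier:
            labels.add("XOR_FIRST")
        elif all_post_later:
            labels.add("XOR_SECOND")
        return frozenset(labels)

    return classify
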