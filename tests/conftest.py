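import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracle helpers

from irtcalib import (
    AbilityDensity,
    Item,
    SolverConfig,
    optimize_multi_item,
    optimize_one_item,
    tail_anchored_optimize,
)

ITEMS = {
    "item1": Item(1.0, 0.5, "item1"),
    "item2": Item(1.5, -1.2, "item2"),
    "item3": Item(1.6, 2.0, "item3"),
}


@pytest.fixture(scope="session")
def g():
    return AbilityDensity.standard_normal()


@pytest.fixture(scope="session")
def items():
    return ITEMS


class SolveCache:
    """Session-wide memoization of the (expensive) design optimizations."""

    def __init__(self, g):
        self.g = g
        self.config = SolverConfig()
        self._cache = {}

    def design(self, labels, s):
        key = (tuple(labels), round(float(s), 6))
        if key not in self._cache:
            its = [ITEMS[l] for l in labels]
            if len(its) == 1:
                d = optimize_one_item(its[0], s, self.g, self.config)
            elif s >= 1.0:
                d = tail_anchored_optimize(its, self.g, self.config)
            else:
                d = optimize_multi_item(its, s, self.g, self.config)
            self._cache[key] = d
        return self._cache[key]

    def all_designs(self):
        return dict(self._cache)


@pytest.fixture(scope="session")
def solved(g):
    return SolveCache(g)
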