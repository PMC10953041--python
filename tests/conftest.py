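"""Shared fixtures: tiny geographic models and trees built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from paleorange.geography import Area, GeoModel, TimeSlice


def make_geo(adjacencies, bounds, max_range_size, codes=None, high=()):
    """Build a GeoModel from per-slice adjacency arrays and slice bounds."""
    n = len(adjacencies[0])
    codes = codes or [chr(ord("A") + i) for i in range(n)]
    areas = [
        Area(i, codes[i], codes[i], "high" if codes[i] in high else "low")
        for i in range(n)
    ]
    slices = [
        TimeSlice(older, younger, np.array(adj))
        for (older, younger), adj in zip(zip(bounds[:-1], bounds[1:]), adjacencies)
    ]
    return GeoModel(areas=areas, slices=slices, max_range_size=max_range_size)


@pytest.fixture
def geo2():
    """Two fully connected areas, one slice to 50 Ma."""
    return make_geo([np.ones((2, 2), int)], [50.0, 0.0], 2)


@pytest.fixture
def geo3_chain():
    """Three areas in a chain A-B-C, one slice."""
    adj = [[1, 1, 0], [1, 1, 1], [0, 1, 1]]
    return make_geo([adj], [50.0, 0.0], 3)


@pytest.fixture
def geo3_complete():
    return make_geo([np.ones((3, 3), int)], [50.0, 0.0], 3)


@pytest.fixture
def geo3_strat():
    """Three areas, two slices: the chain loses the B-C link after 10 Ma."""
    old = [[1, 1, 0], [1, 1, 1], [0, 1, 1]]
    recent = [[1, 1, 0], [1, 1, 0], [0, 0, 1]]
    return make_geo([old, recent], [50.0, 10.0, 0.0], 3)


@pytest.fixture
def geo5():
    """Five fully connected areas, one slice (parameter-recovery setting)."""
    return make_geo([np.ones((5, 5), int)], [200.0, 0.0], 5)
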