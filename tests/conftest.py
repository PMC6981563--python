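"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by direct enumeration
(python loops, even-odd ray casting) so they share no code path with the
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from officeactivity.accelerometry import EpochSeries, IntensityCategory


def make_series(
    mets,
    start="2023-01-02 08:00",
    pid="p1",
    group="control",
    phase="pre",
) -> EpochSeries:
    ts = pd.date_range(start, periods=len(mets), freq="60s")
    return EpochSeries(pid, group, phase, ts, np.asarray(mets, dtype=float))


@pytest.fixture
def series_factory():
    return make_series


# ---------------------------------------------------------------------------
# Brute-force run-length oracles
# ---------------------------------------------------------------------------

def oracle_nonwear_mask(mets, min_run=20) -> np.ndarray:
    """Enumerate every maximal zero-run with a plain scan and threshold it."""
    mets = list(mets)
    wear = [True] * len(mets)
    i = 0
    while i < len(mets):
        if mets[i] == 0:
            j = i
            while j < len(mets) and mets[j] == 0:
                j += 1
            if j - i >= min_run:
                for k in range(i, j):
                    wear[k] = False
            i = j
        else:
            i += 1
    return np.array(wear)


def oracle_prolonged_minutes(categories, min_run=30) -> int:
    """Sum of maximal SB runs >= min_run by direct scanning."""
    total = 0
    run = 0
    for c in list(categories) + [None]:
        if c == IntensityCategory.SB:
            run += 1
        else:
            if run >= min_run:
                total += run
            run = 0
    return total


# ---------------------------------------------------------------------------
# Even-odd ray-casting point-in-polygon oracle
# ---------------------------------------------------------------------------

def _ray_cast(x, y, ring) -> bool:
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xs = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xs:
                inside = not inside
    return inside


def oracle_assign_zone(x, y, plan):
    """Independent zone assignment: even-odd ray casting, priority then
    lexicographic tie-break (boundary hits are measure-zero for the random
    points these tests draw)."""
    for zone in sorted(plan.zones, key=lambda z: (-z.priority, z.label)):
        ring = list(zone.polygon.exterior.coords)[:-1]
        if _ray_cast(x, y, ring):
            return zone.label
    return None
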