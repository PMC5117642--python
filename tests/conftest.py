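"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (sorting,
double loops, gift wrapping) kept independent of the package code paths
they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from nichecompare import ScenarioConfig
from nichecompare.synth import (
    make_climate_fields,
    make_correction_series,
    make_expert_table,
    make_true_niches,
    sample_occurrences,
)


# ----------------------------------------------------------------------
# Oracles
# ----------------------------------------------------------------------

def sort_quantile(values, q: float) -> float:
    """Linear-interpolation quantile by explicit sort (independent of numpy)."""
    s = sorted(float(v) for v in values)
    if len(s) == 1:
        return s[0]
    h = (len(s) - 1) * q
    f = math.floor(h)
    if f + 1 >= len(s):
        return s[-1]
    return s[f] + (h - f) * (s[f + 1] - s[f])


def brute_force_u(a, b) -> float:
    """Mann-Whitney U of the first sample: #(a > b) pairs + 1/2 per tie."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def hand_kruskal_h(groups) -> float:
    """Kruskal-Wallis H from midranks, with the tie-correction divisor."""
    pooled = [float(v) for g in groups for v in g]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    n_tot = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (sum(r) / len(g)) ** 2
        start += len(g)
    h = 12.0 / (n_tot * (n_tot + 1)) * h - 3 * (n_tot + 1)
    # tie correction
    counts: dict[float, int] = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    c_factor = 1 - tie / (n_tot**3 - n_tot)
    return h / c_factor


def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    """O(n^2) Jarvis-march convex hull; empty for degenerate inputs."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return np.empty((0, 2))

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    start = min(range(len(pts)), key=lambda i: (pts[i][1], pts[i][0]))
    hull = []
    current = start
    while True:
        hull.append(current)
        candidate = (current + 1) % len(pts)
        for i in range(len(pts)):
            if i == current:
                continue
            c = cross(pts[current], pts[candidate], pts[i])
            if c < 0 or (c == 0 and
                         np.linalg.norm(pts[i] - pts[current])
                         > np.linalg.norm(pts[candidate] - pts[current])):
                candidate = i
        current = candidate
        if current == start:
            break
        if len(hull) > len(pts):  # degenerate; should not happen
            return np.empty((0, 2))
    if len(hull) < 3:
        return np.empty((0, 2))
    return pts[hull]


# ----------------------------------------------------------------------
# Fixtures
# ----------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """A compact study: 30 species on a 60x60 grid, default conditions."""
    return ScenarioConfig(seed=7, n_species=30, nrows=60, ncols=60)


@pytest.fixture(scope="session")
def small_fields(small_config):
    return make_climate_fields(small_config)


@pytest.fixture(scope="session")
def small_niches(small_config, small_fields):
    return make_true_niches(small_config, small_fields)


@pytest.fixture(scope="session")
def small_occurrences(small_config, small_fields, small_niches):
    return sample_occurrences(small_niches, small_fields, small_config)


@pytest.fixture(scope="session")
def small_expert(small_config, small_niches):
    return make_expert_table(small_niches, small_config)


@pytest.fixture(scope="session")
def small_series(small_config, small_fields):
    cfg = ScenarioConfig(seed=7, n_species=30, nrows=60, ncols=60,
                         n_precip_locations=120, n_stations=30,
                         station_years=(1990, 2000))
    return make_correction_series(small_fields, cfg)
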