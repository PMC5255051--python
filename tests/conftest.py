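"""Shared fixtures and independent reference implementations (oracles).

The oracles here deliberately re-derive each quantity from its
definition — plain BH by the textbook recipe, the weighted Simes
minimum by an explicit loop, the step-up rejection-count distribution
by a first-crossing recursion — so they share no code with the package
paths they validate.
"""

from math import comb

import numpy as np
import pytest

from wfdr import EndpointTable, load_fixture


@pytest.fixture()
def posaconazole() -> EndpointTable:
    return load_fixture("posaconazole")


@pytest.fixture()
def natalizumab_synthetic() -> EndpointTable:
    return load_fixture("natalizumab_synthetic")


def bh_oracle(p: np.ndarray, q: float) -> np.ndarray:
    """Textbook (unweighted) Benjamini–Hochberg rejection mask."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    crit = q * np.arange(1, m + 1) / m
    ok = np.flatnonzero(ps <= crit)
    if ok.size == 0:
        return np.zeros(m, dtype=bool)
    return p <= ps[ok[-1]]


def simes_loop_oracle(p) -> float:
    """Equal-weight Simes p-value by exhaustive loop over ranks."""
    ps = sorted(p)
    n = len(ps)
    return min(ps[i] * n / (i + 1) for i in range(n))


def stepup_count_pmf_oracle(thresholds) -> np.ndarray:
    """Exact pmf of the rejection count of a step-up test on iid uniforms.

    First-crossing recursion: f[i] is the probability that n - i
    uniforms on (c_i, 1) all clear the remaining critical values, built
    backwards by conditioning on the number of points in (c_i, c_{i+r}].
    Valid for arbitrary ascending thresholds.
    """
    c = np.asarray(thresholds, float)
    n = c.size
    cc = np.concatenate([[0.0], c])
    f = np.zeros(n + 1)
    f[n] = 1.0
    for i in range(n - 1, -1, -1):
        m = n - i
        acc = 0.0
        for r in range(1, m + 1):
            lo = max((cc[i + r] - cc[i]) / (1.0 - cc[i]), 0.0)
            hi = (1.0 - cc[i + r]) / (1.0 - cc[i])
            acc += comb(m, r) * lo**r * hi ** (m - r) * f[i + r]
        f[i] = 1.0 - acc
    pmf = np.zeros(n + 1)
    for j in range(n + 1):
        pmf[j] = comb(n, j) * cc[j] ** j * (1 - cc[j]) ** (n - j) * f[j]
    return pmf


def random_table(rng: np.random.Generator, m: int, equal_weights: bool = False) -> EndpointTable:
    """Random endpoint table with one primary endpoint."""
    p = rng.random(m)
    w = np.ones(m) if equal_weights else rng.uniform(0.2, 5.0, m)
    return EndpointTable(
        ids=tuple(f"h{i}" for i in range(m)),
        levels=("primary",) + ("secondary",) * (m - 1),
        p_values=p,
        weights=w,
    )
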