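"""Familywise-error gatekeeper baselines.

Regulatory practice tests secondary endpoints only after the primary
endpoint succeeds, controlling the familywise error rate (FWER) by
closed testing: a hypothesis is rejected iff every intersection
hypothesis containing it is rejected by a local level-``alpha`` test.
Here the primary endpoint serially gatekeeps the secondary family —
every intersection containing the primary is tested through the primary
p-value alone — so the closure admits a shortcut:

* reject the primary iff ``p_p <= alpha``;
* if (and only if) the primary is rejected, test the secondaries with
  the closed local test at ``alpha``: Holm's step-down for Bonferroni
  local tests, Hommel's procedure for Simes local tests.

The shortcuts are delegated to :func:`statsmodels.stats.multitest.multipletests`
and are validated against a brute-force closed-testing enumeration in
the test suite.  These procedures serve as comparison baselines for the
weighted FDR procedures; they control the FWER, not the wFDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import EndpointTable, TestOutcome, SECONDARY

__all__ = ["GatekeeperSpec", "gatekeeper_test", "closed_testing_oracle"]

MAX_SECONDARIES = 16


@dataclass(frozen=True)
class GatekeeperSpec:
    alpha_fwer: float
    local_test: Literal["bonferroni", "simes"] = "bonferroni"

    def __post_init__(self) -> None:
        if not 0 < self.alpha_fwer < 1:
            raise ValueError("alpha_fwer must lie in (0, 1)")
        if self.local_test not in ("bonferroni", "simes"):
            raise ValueError(f"unknown local test {self.local_test!r}")


def _local_p(p: np.ndarray, local_test: str) -> float:
    """Local intersection test p-value: Bonferroni min(n*p) or Simes."""
    n = p.size
    if local_test == "bonferroni":
        return float(min(1.0, n * p.min()))
    ps = np.sort(p)
    return float(min(1.0, np.min(ps * n / np.arange(1, n + 1))))


def gatekeeper_test(table: EndpointTable, spec: GatekeeperSpec) -> TestOutcome:
    """Serial-gatekeeper closed-testing procedure (shortcut form).

    Requires exactly one primary endpoint and at most 16 secondaries
    (the closure over secondary subsets grows exponentially; the
    shortcut itself is cheap, but the cap keeps the procedure within the
    regime validated against the enumeration oracle).  Weights are
    ignored: gatekeepers control the FWER, where importance is expressed
    through the gate, not through weights.
    """
    if table.n_primary != 1:
        raise ValueError("gatekeeper_test requires exactly one primary endpoint")
    S = table.n_secondary
    if S < 1:
        raise ValueError("gatekeeper_test requires at least one secondary endpoint")
    if S > MAX_SECONDARIES:
        raise ValueError(
            f"gatekeeper_test supports at most {MAX_SECONDARIES} secondaries, got {S}"
        )
    alpha = spec.alpha_fwer
    prim = table.primary_mask
    sec = table.secondary_mask
    p_p = float(table.p_values[prim][0])
    p_s = table.p_values[sec]

    rejected = np.zeros(table.m, dtype=bool)
    thresholds = np.full(table.m, np.nan)
    thresholds[prim] = alpha
    gate_open = p_p <= alpha
    rejected[prim] = gate_open
    k = 0
    if gate_open:
        method = "holm" if spec.local_test == "bonferroni" else "hommel"
        rej_s, _, _, _ = multipletests(p_s, alpha=alpha, method=method)
        rejected[sec] = rej_s
        k = int(rej_s.sum())
        # report each secondary's effective Holm threshold; Hommel has no
        # single per-hypothesis critical value, leave NaN there
        if spec.local_test == "bonferroni":
            order = np.argsort(p_s, kind="stable")
            thr = alpha / (S - np.arange(S))
            t = np.empty(S)
            t[order] = thr
            thresholds[sec] = t

    frame = table.to_frame()
    frame["rejected"] = rejected
    frame["threshold"] = thresholds
    return TestOutcome(
        procedure=f"GK_{spec.local_test}", alpha_used=alpha, frame=frame, k=k
    )


def closed_testing_oracle(table: EndpointTable, spec: GatekeeperSpec) -> np.ndarray:
    """Brute-force closed testing over all nonempty endpoint subsets.

    Enumerates every intersection hypothesis; intersections containing
    the primary are tested through the primary p-value at full level
    (the serial gate), pure-secondary intersections by the local test.
    Returns the rejection mask in table order.  Exponential in S — this
    is the reference implementation the shortcut is checked against.
    """
    if table.n_primary != 1:
        raise ValueError("oracle requires exactly one primary endpoint")
    alpha = spec.alpha_fwer
    p_p = float(table.p_values[table.primary_mask][0])
    p_s = table.p_values[table.secondary_mask]
    S = p_s.size
    sec_rej = np.ones(S, dtype=bool)
    prim_rej = p_p <= alpha
    for size in range(1, S + 1):
        for subset in combinations(range(S), size):
            local = _local_p(p_s[list(subset)], spec.local_test)
            # intersections containing the primary are covered by the gate
            if local > alpha:
                sec_rej[list(subset)] = False
    if not prim_rej:
        sec_rej[:] = False
    out = np.zeros(table.m, dtype=bool)
    out[table.primary_mask] = prim_rej
    out[table.secondary_mask] = sec_rej
    return out
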