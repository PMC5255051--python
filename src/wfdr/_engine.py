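"""Vectorized decision kernels for the simulation study.

All kernels operate on a matrix of p-values with one row per simulated
trial and the standard one-primary layout: column 0 is the primary
endpoint, columns 1..S the secondaries, with secondary weight 1 and
primary weight ``R``.  They replicate the per-table procedures in
:mod:`wfdr.core` and :mod:`wfdr.baselines` decision-for-decision; the
test suite asserts exact agreement on random draws.
"""

from __future__ import annotations

import numpy as np

__all__ = ["decide_wbh", "decide_hwf", "decide_gk"]


def decide_wbh(pmat: np.ndarray, R: float, q: float) -> np.ndarray:
    """Weighted BH step-up per row; returns a boolean rejection matrix."""
    reps, m = pmat.shape
    w = np.concatenate([[float(R)], np.ones(m - 1)])
    order = np.argsort(pmat, axis=1, kind="stable")
    ps = np.take_along_axis(pmat, order, axis=1)
    cum = np.cumsum(w[order], axis=1)
    crit = q * cum / cum[:, -1:]
    hits = ps <= crit
    ranks = np.where(hits, np.arange(1, m + 1), 0)
    k = ranks.max(axis=1)
    any_rej = k > 0
    pk = np.where(any_rej, ps[np.arange(reps), np.maximum(k - 1, 0)], -1.0)
    return pmat <= pk[:, None]


def decide_hwf(
    pmat: np.ndarray, R: float, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical weighted FDR procedure per row.

    Returns ``(rejections, gate_open)`` where ``gate_open`` flags rows
    whose secondary-family intersection was rejected at level 1.
    """
    reps, m = pmat.shape
    S = m - 1
    p_p = pmat[:, 0]
    p_s = np.sort(pmat[:, 1:], axis=1)

    # weighted Simes with equal secondary weights
    p_star = np.min(p_s * (S / np.arange(1, S + 1)), axis=1)

    # level 1: two hypotheses with weights (w* = S) and (R).  Step-up:
    # k = 2 iff max(p*, p_p) <= alpha; else k = 1 iff the smaller one is
    # below its own cumulative-weight critical value.
    both = np.maximum(p_star, p_p) <= alpha
    star_first = p_star <= p_p  # stable order: intersection precedes on ties
    first_p = np.where(star_first, p_star, p_p)
    first_w = np.where(star_first, S, R)
    one = first_p <= alpha * first_w / (S + R)
    gate_open = both | (one & star_first)
    prim_rej = both | (one & ~star_first)

    # level 2: equal-weight BH at alpha on the secondaries, gated
    crit = alpha * np.arange(1, S + 1) / S
    hits = p_s <= crit
    ranks = np.where(hits, np.arange(1, S + 1), 0)
    k2 = ranks.max(axis=1)
    any2 = gate_open & (k2 > 0)
    pk2 = np.where(any2, p_s[np.arange(reps), np.maximum(k2 - 1, 0)], -1.0)

    rej = np.empty_like(pmat, dtype=bool)
    rej[:, 0] = prim_rej
    rej[:, 1:] = pmat[:, 1:] <= pk2[:, None]
    return rej, gate_open


def _holm_reject(p_s_sorted: np.ndarray, alpha: float) -> np.ndarray:
    """Step-down Holm rejection count per row on pre-sorted p-values."""
    reps, S = p_s_sorted.shape
    crit = alpha / (S - np.arange(S))
    fail = p_s_sorted > crit
    # first failing index; all before it are rejected
    first_fail = np.where(fail.any(axis=1), fail.argmax(axis=1), S)
    return first_fail


def decide_gk(pmat: np.ndarray, alpha: float, local_test: str) -> np.ndarray:
    """Serial gatekeeper (closed testing) per row.

    Bonferroni local tests reduce to Holm on the secondaries; Simes
    local tests are evaluated by explicit closure over all secondary
    subsets (feasible for the small S values gatekeepers are run at).
    """
    reps, m = pmat.shape
    S = m - 1
    p_p = pmat[:, 0]
    gate = p_p <= alpha
    rej = np.zeros_like(pmat, dtype=bool)
    rej[:, 0] = gate
    if local_test == "bonferroni":
        order = np.argsort(pmat[:, 1:], axis=1, kind="stable")
        ps = np.take_along_axis(pmat[:, 1:], order, axis=1)
        nrej = _holm_reject(ps, alpha)
        sec = np.arange(S) < nrej[:, None]
        out = np.zeros((reps, S), dtype=bool)
        np.put_along_axis(out, order, sec, axis=1)
        rej[:, 1:] = out & gate[:, None]
        return rej
    if local_test != "simes":
        raise ValueError(f"unknown local test {local_test!r}")
    if S > 10:
        raise ValueError("vectorized Simes gatekeeper supports S <= 10")
    p_s = pmat[:, 1:]
    ok = np.ones((reps, S), dtype=bool)
    # closure: secondary i survives only if every subset containing it
    # has Simes p-value <= alpha
    for mask in range(1, 1 << S):
        idx = [i for i in range(S) if mask >> i & 1]
        sub = np.sort(p_s[:, idx], axis=1)
        n = len(idx)
        local = np.min(sub * (n / np.arange(1, n + 1)), axis=1)
        reject_subset = local <= alpha
        ok[:, idx] &= reject_subset[:, None]
    rej[:, 1:] = ok & gate[:, None]
    return rej
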