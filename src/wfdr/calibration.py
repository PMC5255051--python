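"""Calibration of the working level for the hierarchical weighted FDR test.

The two-level procedure in :func:`wfdr.core.hwf_test` applied at level
``alpha`` does not control the weighted FDR at ``alpha``: the gating step
inflates the error rate.  Its maximum over p-value configurations — the
*worst-case array* (WCA) — pins one secondary p-value low enough to open
the hierarchy with certainty while the remaining secondary p-values and
the primary p-value are independent uniforms.  Under the WCA the wFDR
can be computed exactly for independent test statistics, and closed-form
upper bounds are available under positive regression dependence.  The
calibrator inverts the selected bound to find the largest working level
``alpha`` whose worst-case wFDR does not exceed the target ``q``.

All functions here cover the standard design: one primary endpoint with
weight ``R`` and ``S >= 2`` equally weighted secondary endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Literal

import numpy as np

from .core import EndpointTable, PRIMARY, SECONDARY

__all__ = [
    "CalibrationSpec",
    "CalibrationResult",
    "null_secondary_rejection_pmf",
    "hwfdr_bound_independent",
    "hwfdr_bound_prds",
    "hwfdr_bound_conservative",
    "PrdsExceptionWindow",
    "calibrate_alpha",
    "worst_case_table",
    "mc_wfdr_worst_case",
]

Dependence = Literal["independent", "prds", "conservative"]


@dataclass(frozen=True)
class CalibrationSpec:
    """Parameters of one calibration problem.

    ``q`` is the target wFDR level, ``P`` the number of primary
    endpoints (only ``P = 1`` is supported), ``S`` the number of
    secondary endpoints and ``R >= 1`` the per-hypothesis
    primary:secondary weight ratio.  ``dependence`` selects the bound to
    invert.  ``safety_margin`` is subtracted from ``q`` before inverting
    the independent-case bound in the ``R < S`` regime with many
    secondaries (``S >= 20``), where the single-pin worst case is known
    to undershoot the true maximum by up to roughly 0.0016.
    """

    q: float
    P: int = 1
    S: int = 2
    R: float = 1.0
    dependence: Dependence = "independent"
    safety_margin: float = 0.002

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.P != 1:
            raise ValueError("calibration is only available for P = 1")
        if self.S < 2:
            raise ValueError("calibration requires S >= 2 secondary endpoints")
        if self.R < 1:
            raise ValueError("weight ratio R must be >= 1")
        if self.dependence not in ("independent", "prds", "conservative"):
            raise ValueError(f"unknown dependence assumption {self.dependence!r}")
        if self.safety_margin < 0 or self.safety_margin >= self.q:
            raise ValueError("safety_margin must lie in [0, q)")

    @property
    def R_prime(self) -> float:
        """Total-weight ratio; equals R/S for one primary and equal
        secondary weights."""
        return self.R / self.S


@dataclass(frozen=True)
class CalibrationResult:
    alpha: float
    bound_at_alpha: float
    method: str
    q_effective: float
    iterations: int
    residual: float
    spec: CalibrationSpec


class PrdsExceptionWindow(ValueError):
    """Raised when the positive-dependence bound does not apply.

    The closed-form PRDS bound fails for two small parameter windows
    (S = 2 with R <= 3.15 and S = 3 with R <= 1.28, all hypotheses
    null); callers should fall back to the conservative bound there.
    """


def _validate(alpha: float, S: int, R: float) -> None:
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    if S < 2:
        raise ValueError("S must be >= 2")
    if R < 1:
        raise ValueError("R must be >= 1")


def null_secondary_rejection_pmf(alpha: float, S: int) -> np.ndarray:
    """Distribution of the number of true-null secondaries rejected under the WCA.

    With the hierarchy opened by the pinned secondary, the level-2 pass
    is an equal-weight step-up at level ``alpha`` over the ``S``
    secondaries; the pinned p-value occupies rank 1, so the ``n = S - 1``
    uniform null p-values face the critical values ``alpha*(i+1)/S`` at
    their ranks ``i = 1..n``.  For such linear critical values the
    rejection count ``j`` has the exact Abel-type probabilities

        P(j) = (1 - alpha) * C(n, j) * t_j^j * (1 - t_j)^(n - j - 1),
        t_j = alpha * (j + 1) / S,

    returned here as a vector of length ``S`` (j = 0..S-1).
    """
    n = S - 1
    out = np.empty(n + 1)
    for j in range(n + 1):
        t = alpha * (j + 1) / S
        if j == n:
            # exponent n - j - 1 = -1 cancels against the (1 - alpha) factor
            out[j] = t**n
        else:
            out[j] = (1.0 - alpha) * comb(n, j) * t**j * (1.0 - t) ** (n - j - 1)
    return out


def hwfdr_bound_independent(alpha: float, S: int, R: float) -> float:
    """Exact worst-case wFDR of the hierarchical procedure, independent case.

    Under the WCA the primary endpoint (a true null with weight ``R``)
    is rejected with probability ``alpha``, independently of the
    secondary level, and ``j`` true-null secondaries are rejected with
    the probabilities of :func:`null_secondary_rejection_pmf`.  Every
    outcome also rejects the pinned (false) secondary, so the realized
    weighted FDP is ``(R*k + j) / (R*k + j + 1)`` for ``k`` rejected
    primaries.  The expectation is the finite double sum returned here.

    For ``S = 2`` the worst configuration is all-null and the procedure
    already keeps wFDR <= alpha; the function returns ``alpha``.
    """
    _validate(alpha, S, R)
    if alpha == 0:
        return 0.0
    if S == 2:
        return float(alpha)
    pmf = null_secondary_rejection_pmf(alpha, S)
    j = np.arange(S, dtype=float)
    value = 0.0
    for k, pk in ((0, 1.0 - alpha), (1, alpha)):
        value += pk * float(np.sum(pmf * (R * k + j) / (R * k + j + 1.0)))
    return value


_PRDS_WINDOWS = ((2, 3.15), (3, 1.28))


def hwfdr_bound_prds(alpha: float, S: int, R: float) -> float:
    """Closed-form worst-case wFDR bound under positive regression dependence.

        HWFDR <= (1-a)*a*(S-1)/S + a*[ a*(S-1)/S + (1 - a*(S-1)/S) * R/(R+1) ]

    Valid for ``S > 3``, and for ``S in {2, 3}`` outside the small
    exception windows (S = 2 with R <= 3.15; S = 3 with R <= 1.28) where
    the all-null configuration escapes this bound; those parameters
    raise :class:`PrdsExceptionWindow` and should use
    :func:`hwfdr_bound_conservative` instead.
    """
    _validate(alpha, S, R)
    for s_win, r_max in _PRDS_WINDOWS:
        if S == s_win and R <= r_max:
            raise PrdsExceptionWindow(
                f"the positive-dependence bound does not hold for S={S}, R={R}; "
                "use hwfdr_bound_conservative"
            )
    a = alpha
    g = a * (S - 1) / S
    return (1 - a) * g + a * (g + (1 - g) * R / (R + 1.0))


def hwfdr_bound_conservative(alpha: float, S: int, R: float) -> float:
    """Simple universal worst-case bound ``alpha * (1 + R*S/(R+S)^2)``.

    Higher than the positive-dependence bound wherever that one applies,
    but valid for every ``S >= 2`` and ``R >= 1`` (the factor is at most
    1.25, attained at R = S).
    """
    _validate(alpha, S, R)
    return alpha * (1.0 + R * S / (R + S) ** 2)


_BOUNDS = {
    "independent": hwfdr_bound_independent,
    "prds": hwfdr_bound_prds,
    "conservative": hwfdr_bound_conservative,
}


def calibrate_alpha(spec: CalibrationSpec) -> CalibrationResult:
    """Largest working level ``alpha`` with worst-case wFDR at most ``q``.

    Inverts the bound selected by ``spec.dependence`` by bisection to an
    absolute tolerance of 1e-7 on ``alpha``, after verifying that the
    bound is nondecreasing on the search bracket.  The conservative mode
    has the closed-form solution ``q / (1 + R*S/(R+S)^2)`` and is also
    used automatically when the PRDS bound's exception windows apply.

    In the independent mode with ``R < S`` and ``S >= 20`` the target is
    lowered by ``spec.safety_margin`` before inversion (see
    :class:`CalibrationSpec`).
    """
    method = spec.dependence
    q_eff = spec.q
    if method == "independent" and spec.R < spec.S and spec.S >= 20:
        q_eff = spec.q - spec.safety_margin
    bound = _BOUNDS[method]
    if method == "prds":
        try:
            bound(0.01, spec.S, spec.R)
        except PrdsExceptionWindow:
            method = "conservative"
            bound = hwfdr_bound_conservative

    if method == "conservative":
        alpha = q_eff / (1.0 + spec.R * spec.S / (spec.R + spec.S) ** 2)
        return CalibrationResult(
            alpha=alpha,
            bound_at_alpha=bound(alpha, spec.S, spec.R),
            method="conservative",
            q_effective=q_eff,
            iterations=0,
            residual=abs(bound(alpha, spec.S, spec.R) - q_eff),
            spec=spec,
        )

    lo, hi = 1e-8, min(q_eff * (1.0 + spec.R * spec.S / (spec.R + spec.S) ** 2), 0.5)
    grid = np.linspace(lo, hi, 32)
    values = np.array([bound(a, spec.S, spec.R) for a in grid])
    if np.any(np.diff(values) < -1e-12):
        raise RuntimeError(
            "worst-case bound is not monotone on the search bracket; "
            "cannot calibrate reliably"
        )
    if bound(hi, spec.S, spec.R) <= q_eff:
        lo = hi
    iterations = 0
    while hi - lo > 1e-7 and iterations < 200:
        mid = 0.5 * (lo + hi)
        if bound(mid, spec.S, spec.R) <= q_eff:
            lo = mid
        else:
            hi = mid
        iterations += 1
    alpha = lo
    b = bound(alpha, spec.S, spec.R)
    return CalibrationResult(
        alpha=alpha,
        bound_at_alpha=b,
        method=method,
        q_effective=q_eff,
        iterations=iterations,
        residual=abs(b - q_eff),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo worst-case oracle
# ---------------------------------------------------------------------------

def worst_case_table(
    alpha: float,
    S: int,
    R: float,
    n_false_secondary: int,
    rng: np.random.Generator,
) -> tuple[EndpointTable, dict[str, bool]]:
    """One random draw from the worst-case array.

    ``n_false_secondary`` secondary p-values are pinned at
    ``alpha / (R + S) / 2`` — safely inside the region that opens the
    hierarchy — while the remaining secondaries and the primary are
    uniform true nulls.  Returns the table and the truth labels
    (id -> True when the hypothesis is a true null).
    """
    if n_false_secondary < 1 or n_false_secondary > S:
        raise ValueError("n_false_secondary must lie in [1, S]")
    pin = alpha / (R + S) / 2.0
    p_sec = np.concatenate(
        [np.full(n_false_secondary, pin), rng.random(S - n_false_secondary)]
    )
    table = EndpointTable.from_pvalues([rng.random()], p_sec, R=R)
    truth = {table.ids[0]: True}
    for j in range(S):
        truth[table.ids[1 + j]] = j >= n_false_secondary
    return table, truth


def _wca_wfdr_draws(
    alpha: float, S: int, R: float, n_false: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized realized-wFDR draws under the WCA (one primary, equal
    secondary weights).  Mirrors hwf_test exactly; agreement with the
    per-table path is asserted in the test suite."""
    pin = alpha / (R + S) / 2.0
    p_prim = rng.random(reps)
    p_null = rng.random((reps, S - n_false))
    p_null.sort(axis=1)

    # weighted Simes over the S secondaries: pinned values occupy the
    # lowest ranks, so p* <= pin * S < alpha*S/(R+S) and the gate is open
    # with certainty; the primary is rejected at level 1 iff p_p <= alpha.
    prim_rej = p_prim <= alpha

    # level 2: equal-weight step-up at alpha over the S secondaries; the
    # pinned values fill ranks 1..n_false, so the i-th null order
    # statistic faces the critical value alpha*(i+n_false)/S.
    n = S - n_false
    if n:
        crit = alpha * (np.arange(1, n + 1) + n_false) / S
        hits = p_null <= crit
        ranks = np.where(hits, np.arange(1, n + 1), 0)
        j = ranks.max(axis=1)
    else:
        j = np.zeros(reps, dtype=int)

    num = R * prim_rej + j
    den = R * prim_rej + j + n_false
    return num / den


def mc_wfdr_worst_case(
    alpha: float,
    S: int,
    R: float,
    n_false_secondary: int = 1,
    reps: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the worst-case-array wFDR, with its standard error.

    Simulates ``reps`` draws of the WCA, applies the hierarchical
    procedure at ``alpha`` and averages the realized weighted FDP.
    Deterministic given ``seed``.  With one pinned secondary the
    estimate validates :func:`hwfdr_bound_independent`; with two or more
    pins it illustrates that the single-pin array remains the maximum.
    """
    _validate(alpha, S, R)
    if reps < 1000:
        raise ValueError("use at least 1000 replicates")
    if alpha == 0:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    draws = _wca_wfdr_draws(alpha, S, R, n_false_secondary, reps, rng)
    est = float(draws.mean())
    se = float(draws.std(ddof=1) / np.sqrt(reps))
    return est, se
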