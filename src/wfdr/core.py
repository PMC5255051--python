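"""Weighted FDR procedures for primary/secondary endpoint families.

A clinical trial typically pre-specifies one (or a few) primary endpoints
and a larger family of secondary endpoints.  Assigning each endpoint a
nonnegative importance weight and controlling the *weighted* false
discovery rate (wFDR) lets both families be tested jointly while the
error criterion reflects that a false rejection of the primary endpoint
counts more than one of a secondary endpoint.

This module provides the data model (:class:`EndpointTable`,
:class:`TestOutcome`) and the two weighted procedures built on the
step-up principle:

* :func:`wbh_adjust` — the single-level weighted Benjamini–Hochberg
  step-up procedure with cumulative-weight critical values.
* :func:`hwf_test` — the two-level hierarchical weighted FDR procedure:
  level 1 tests the primary endpoint(s) together with a weighted-Simes
  intersection of all secondaries; individual secondaries are tested at
  level 2 only if the intersection is rejected.

The realized weighted false discovery proportion of an outcome, given
ground-truth null labels, is computed by :func:`wfdr_realized`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EndpointTable",
    "WeightScheme",
    "IntersectionResult",
    "TestOutcome",
    "normalize_weights",
    "wbh_adjust",
    "weighted_simes",
    "hwf_test",
    "wfdr_realized",
]

PRIMARY = "primary"
SECONDARY = "secondary"
_LEVELS = (PRIMARY, SECONDARY)


@dataclass(frozen=True)
class EndpointTable:
    """Labelled family of hypotheses with p-values and importance weights.

    Parameters
    ----------
    ids
        Unique hypothesis identifiers.
    levels
        Per-hypothesis label, ``"primary"`` or ``"secondary"``.
    p_values
        Observed p-values, each in [0, 1].
    weights
        Nonnegative importance weights; at least one must be positive.
        Procedures are invariant to a common positive rescaling of the
        weights, so weights need not be normalized.
    """

    ids: tuple[str, ...]
    levels: tuple[str, ...]
    p_values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        levels = tuple(str(l) for l in self.levels)
        p = np.asarray(self.p_values, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "p_values", p)
        object.__setattr__(self, "weights", w)
        m = len(ids)
        if m == 0:
            raise ValueError("endpoint table must contain at least one hypothesis")
        if not (len(levels) == len(p) == len(w) == m):
            raise ValueError("ids, levels, p_values and weights must have equal length")
        if len(set(ids)) != m:
            raise ValueError("hypothesis ids must be unique")
        bad = [l for l in levels if l not in _LEVELS]
        if bad:
            raise ValueError(f"levels must be 'primary' or 'secondary', got {bad[:3]}")
        if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
            raise ValueError("p-values must be finite and lie in [0, 1]")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and nonnegative")
        if not np.any(w > 0):
            raise ValueError("at least one weight must be positive")
        p.flags.writeable = False
        w.flags.writeable = False

    # -- basic sizes -------------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.ids)

    @property
    def n_primary(self) -> int:
        return sum(l == PRIMARY for l in self.levels)

    @property
    def n_secondary(self) -> int:
        return sum(l == SECONDARY for l in self.levels)

    @property
    def primary_mask(self) -> np.ndarray:
        return np.array([l == PRIMARY for l in self.levels])

    @property
    def secondary_mask(self) -> np.ndarray:
        return ~self.primary_mask

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EndpointTable":
        """Build a table from a DataFrame with columns
        ``id, level, p_value, weight``."""
        required = {"id", "level", "p_value", "weight"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        return cls(
            ids=tuple(frame["id"].astype(str)),
            levels=tuple(frame["level"].astype(str)),
            p_values=frame["p_value"].to_numpy(dtype=float),
            weights=frame["weight"].to_numpy(dtype=float),
        )

    @classmethod
    def from_pvalues(
        cls,
        primary: Sequence[float],
        secondary: Sequence[float],
        R: float = 1.0,
    ) -> "EndpointTable":
        """Build a table from raw p-values with the standard weighting:
        every primary endpoint gets weight ``R`` and every secondary
        endpoint weight 1 (``R >= 1`` is the primary:secondary ratio)."""
        if R < 1:
            raise ValueError("weight ratio R must be >= 1")
        P, S = len(primary), len(secondary)
        return cls(
            ids=tuple(f"P{i+1}" for i in range(P)) + tuple(f"S{j+1}" for j in range(S)),
            levels=(PRIMARY,) * P + (SECONDARY,) * S,
            p_values=np.concatenate([np.asarray(primary, float), np.asarray(secondary, float)]),
            weights=np.concatenate([np.full(P, float(R)), np.ones(S)]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "level": self.levels,
                "p_value": self.p_values,
                "weight": self.weights,
            }
        )

    def subset(self, mask: np.ndarray) -> "EndpointTable":
        idx = np.flatnonzero(mask)
        return EndpointTable(
            ids=tuple(self.ids[i] for i in idx),
            levels=tuple(self.levels[i] for i in idx),
            p_values=self.p_values[idx],
            weights=self.weights[idx],
        )


@dataclass(frozen=True)
class WeightScheme:
    """Ratio view of an endpoint table's weights.

    ``R`` is the per-hypothesis primary:secondary ratio; ``R_prime`` is
    the ratio of total primary weight to total secondary weight.  For a
    single primary endpoint with equal secondary weights,
    ``R_prime = R / S``.
    """

    R: float
    R_prime: float
    m: int

    @classmethod
    def from_table(cls, table: EndpointTable) -> "WeightScheme":
        wp = table.weights[table.primary_mask]
        ws = table.weights[table.secondary_mask]
        if wp.size == 0 or ws.size == 0:
            raise ValueError("need at least one primary and one secondary endpoint")
        R = float(wp.min() / ws.max()) if ws.max() > 0 else np.inf
        R_prime = float(wp.sum() / ws.sum()) if ws.sum() > 0 else np.inf
        return cls(R=R, R_prime=R_prime, m=table.m)


@dataclass(frozen=True)
class IntersectionResult:
    """Weighted-Simes intersection of the secondary family (level 1)."""

    p_star: float
    w_star: float
    threshold: float
    rejected: bool


@dataclass(frozen=True)
class TestOutcome:
    """Result of one multiple-testing procedure on one endpoint table.

    ``frame`` mirrors the input table with ``rejected`` flags and the
    critical value each p-value was compared against at its own sorted
    position (NaN for secondaries whose level-2 test never ran).  ``k``
    is the index of the largest rejected order statistic in the relevant
    step-up pass (0 when nothing is rejected).
    """

    procedure: str
    alpha_used: float
    frame: pd.DataFrame
    k: int
    intersection: IntersectionResult | None = None

    @property
    def rejected_ids(self) -> list[str]:
        return list(self.frame.loc[self.frame["rejected"], "id"])

    @property
    def n_rejected(self) -> int:
        return int(self.frame["rejected"].sum())

    def n_rejected_secondary(self) -> int:
        f = self.frame
        return int((f["rejected"] & (f["level"] == SECONDARY)).sum())

    def summary(self) -> dict:
        out = {
            "procedure": self.procedure,
            "alpha_used": self.alpha_used,
            "k": self.k,
            "n_rejected": self.n_rejected,
            "rejected_ids": self.rejected_ids,
        }
        if self.intersection is not None:
            out["intersection"] = {
                "p_star": self.intersection.p_star,
                "w_star": self.intersection.w_star,
                "threshold": self.intersection.threshold,
                "rejected": self.intersection.rejected,
            }
        return out


# ---------------------------------------------------------------------------
# weight normalization
# ---------------------------------------------------------------------------

def normalize_weights(table: EndpointTable) -> EndpointTable:
    """Rescale weights by one positive constant so they sum to ``m``.

    All procedures in this module use normalization-free thresholds
    (cumulative weight over total weight), so this step is cosmetic: it
    reproduces the conventional presentation in which the weights of the
    ``m`` hypotheses sum to ``m``, without changing any decision.
    """
    total = float(table.weights.sum())
    if total <= 0:
        raise ValueError("cannot normalize all-zero weights")
    scale = table.m / total
    return EndpointTable(
        ids=table.ids,
        levels=table.levels,
        p_values=table.p_values,
        weights=table.weights * scale,
    )


# ---------------------------------------------------------------------------
# weighted step-up machinery
# ---------------------------------------------------------------------------

def _stepup(p: np.ndarray, w: np.ndarray, q: float):
    """Weighted BH step-up on raw arrays.

    Sorts stably by (p, original index), compares the j-th order
    statistic with ``q * cumulative_weight_j / total_weight`` and rejects
    all p-values <= p_(k) for the largest satisfying j.  Returns
    (rejected mask, per-hypothesis threshold at its sorted position, k).
    """
    m = p.size
    order = np.lexsort((np.arange(m), p))
    ps = p[order]
    cum = np.cumsum(w[order])
    total = cum[-1]
    crit = q * cum / total
    ok = np.flatnonzero(ps <= crit)
    k = int(ok[-1]) + 1 if ok.size else 0
    rejected = np.zeros(m, dtype=bool)
    if k:
        rejected = p <= ps[k - 1]
    thresholds = np.empty(m)
    thresholds[order] = crit
    return rejected, thresholds, k


def wbh_adjust(table: EndpointTable, q: float) -> TestOutcome:
    """Single-level weighted Benjamini–Hochberg step-up at level ``q``.

    Sorting all ``m`` p-values ascending, the procedure finds the
    largest ``j`` with ``p_(j) <= q * sum_{i<=j} w_(i) / sum_i w_i`` and
    rejects the hypotheses with the ``j`` smallest p-values.  With equal
    weights this is exactly the classic BH procedure.  A p-value exactly
    equal to its critical value is rejected.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    rejected, thresholds, k = _stepup(table.p_values, table.weights, q)
    frame = table.to_frame()
    frame["rejected"] = rejected
    frame["threshold"] = thresholds
    return TestOutcome(procedure="wBH", alpha_used=q, frame=frame, k=k)


def weighted_simes(p_values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted Simes combination p-value for an intersection null.

    ``p* = min_i p_(i) * (sum_j w_j) / (sum_{j<=i} w_(j))`` with the
    p-values sorted ascending and weights carried along.  Equal weights
    recover the classic Simes test ``min_i p_(i) * n / i``; a single
    p-value is returned unchanged.  Invariant to joint permutations of
    (p, w) pairs.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.size == 0:
        raise ValueError("weighted_simes requires at least one p-value")
    if p.shape != w.shape:
        raise ValueError("p_values and weights must have the same length")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    order = np.lexsort((np.arange(p.size), p))
    ps = p[order]
    cum = np.cumsum(w[order])
    return float(np.min(ps * cum[-1] / cum))


def hwf_test(table: EndpointTable, alpha: float) -> TestOutcome:
    """Two-level hierarchical weighted FDR procedure at working level ``alpha``.

    Level 1 pools the primary endpoint(s) with the weighted-Simes
    intersection p-value ``p*`` of the secondary family, carrying weight
    ``w* = sum of secondary weights``, and applies the weighted BH
    step-up at level ``alpha``.  Rejected primaries are discoveries.  If
    and only if the intersection is among the level-1 rejections, the
    secondary endpoints are tested by a second weighted BH pass at the
    same ``alpha``.  The intersection itself is reported but never counts
    as a discovered endpoint.

    ``alpha`` should normally come from
    :func:`wfdr.calibration.calibrate_alpha`, which guarantees
    wFDR <= q under the stated dependence assumption; passing the raw
    target level ``q`` does not control the wFDR at ``q``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    sec = table.secondary_mask
    if not sec.any():
        raise ValueError(
            "hwf_test requires at least one secondary endpoint; "
            "with primaries only, use wbh_adjust"
        )
    prim = table.primary_mask
    p_sec = table.p_values[sec]
    w_sec = table.weights[sec]
    if np.any(w_sec <= 0):
        raise ValueError("secondary weights must be positive for the intersection test")

    p_star = weighted_simes(p_sec, w_sec)
    w_star = float(w_sec.sum())

    # level 1: intersection (slot 0) pooled with the primaries
    p1 = np.concatenate([[p_star], table.p_values[prim]])
    w1 = np.concatenate([[w_star], table.weights[prim]])
    rej1, thr1, _k1 = _stepup(p1, w1, alpha)
    inter = IntersectionResult(
        p_star=p_star, w_star=w_star, threshold=float(thr1[0]), rejected=bool(rej1[0])
    )

    m = table.m
    rejected = np.zeros(m, dtype=bool)
    thresholds = np.full(m, np.nan)
    rejected[prim] = rej1[1:]
    thresholds[prim] = thr1[1:]

    k = 0
    if inter.rejected:
        rej2, thr2, k = _stepup(p_sec, w_sec, alpha)
        rejected[sec] = rej2
        thresholds[sec] = thr2

    # gating invariant: secondaries can only be rejected through an open gate
    assert inter.rejected or not rejected[sec].any()

    frame = table.to_frame()
    frame["rejected"] = rejected
    frame["threshold"] = thresholds
    return TestOutcome(
        procedure="HWF", alpha_used=alpha, frame=frame, k=k, intersection=inter
    )


def wfdr_realized(outcome: TestOutcome, truth: Mapping[str, bool]) -> float:
    """Realized weighted false discovery proportion ``Q(w)`` of one outcome.

    ``truth`` maps each hypothesis id to True when the hypothesis is a
    true null.  Returns ``sum(w_i V_i) / sum(w_i R_i)`` where ``V_i``
    flags erroneous rejections, or 0 when nothing was rejected.
    """
    f = outcome.frame
    missing = [i for i in f["id"] if i not in truth]
    if missing:
        raise ValueError(f"truth labels missing for ids: {missing[:5]}")
    w = f["weight"].to_numpy(float)
    r = f["rejected"].to_numpy(bool)
    null = np.array([bool(truth[i]) for i in f["id"]])
    denom = float(w[r].sum())
    if denom <= 0:
        return 0.0
    return float(w[r & null].sum() / denom)
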