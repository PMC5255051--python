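"""Reading, writing, and bundled example data.

Endpoint tables travel as delimited text (CSV or TSV) with the columns
``id, level, p_value, weight``; the weight column may be omitted when a
weight ratio ``R`` is supplied instead, in which case the primary
endpoints get weight ``R`` and the secondaries weight 1.

Two published trials serve as worked examples:

* ``posaconazole`` — antifungal prophylaxis trial: one primary endpoint
  (invasive fungal infection by day 112, p = 0.07) and six secondary
  endpoints.  The largest secondary p-value was reported only as
  "> 0.5" and is stored as 0.51; every procedure's decision is
  invariant to the exact stand-in because 0.5 already exceeds every
  relevant critical value.
* ``natalizumab_head`` — Crohn's disease trial: one primary endpoint
  (p = 0.533) and 50 secondary endpoints, of which the three smallest
  p-values (4.77e-5, 6.29e-5, 1.44e-4) and the largest (0.992) are
  published in the main text.  The head fixture carries only these four
  and is flagged incomplete.
* ``natalizumab_full`` — the complete 50-value secondary list, which is
  not redistributed here; supply it as a one-column text file.
* ``natalizumab_synthetic`` — a synthetic stand-in for the full list,
  constructed to match the published order statistics and decision
  boundaries; useful for end-to-end demonstrations.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EndpointTable, PRIMARY, SECONDARY, TestOutcome

__all__ = [
    "read_endpoint_table",
    "write_endpoint_table",
    "write_outcome",
    "load_fixture",
    "FIXTURES",
]

_REQUIRED = ("id", "level", "p_value")


def read_endpoint_table(
    path: str | Path | _io.IOBase, R: float | None = None, sep: str | None = None
) -> EndpointTable:
    """Read an endpoint table from delimited text.

    The delimiter is sniffed unless ``sep`` is given.  A ``weight``
    column is required unless ``R`` is supplied (mutually exclusive with
    the column).  Non-numeric p-value entries such as ``">0.5"`` are
    rejected with instructions to substitute a numeric stand-in: any
    value above every critical value in play gives identical decisions.
    """
    frame = pd.read_csv(path, sep=sep, engine="python", skipinitialspace=True)
    if frame.empty and frame.columns.size == 0:
        raise ValueError("empty input file")
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if "weight" in frame.columns and R is not None:
        raise ValueError("give either a weight column or R, not both")
    if "weight" not in frame.columns and R is None:
        raise ValueError("no weight column: supply the weight ratio R instead")

    problems: list[str] = []
    p_parsed = pd.to_numeric(frame["p_value"], errors="coerce")
    for i, (raw, val) in enumerate(zip(frame["p_value"], p_parsed)):
        if pd.isna(val):
            problems.append(
                f"row {i}: p_value {raw!r} is not numeric; one-sided entries "
                "like '>0.5' must be replaced by a numeric stand-in "
                "(any value above the largest critical value is equivalent)"
            )
        elif not 0 <= val <= 1:
            problems.append(f"row {i}: p_value {val} outside [0, 1]")
    levels = frame["level"].astype(str).str.strip().str.lower()
    for i, l in enumerate(levels):
        if l not in (PRIMARY, SECONDARY):
            problems.append(f"row {i}: level {l!r} is not primary/secondary")
    if "weight" in frame.columns:
        w_parsed = pd.to_numeric(frame["weight"], errors="coerce")
        for i, val in enumerate(w_parsed):
            if pd.isna(val) or val < 0:
                problems.append(f"row {i}: weight {val!r} must be a nonnegative number")
    else:
        w_parsed = pd.Series(np.where(levels == PRIMARY, float(R), 1.0))
    if problems:
        raise ValueError("invalid endpoint table:\n" + "\n".join(problems))
    return EndpointTable(
        ids=tuple(frame["id"].astype(str).str.strip()),
        levels=tuple(levels),
        p_values=p_parsed.to_numpy(float),
        weights=w_parsed.to_numpy(float),
    )


def write_endpoint_table(table: EndpointTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_outcome(outcome: TestOutcome, path: str | Path) -> None:
    """Write the per-hypothesis decisions, mirroring the input columns."""
    frame = outcome.frame.copy()
    frame["procedure"] = outcome.procedure
    frame["alpha_used"] = outcome.alpha_used
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------

POSACONAZOLE_PRIMARY = 0.07
# sorted secondary p-values; the last was published only as "> 0.5"
POSACONAZOLE_SECONDARY = (0.001, 0.004, 0.006, 0.046, 0.048, 0.51)
POSACONAZOLE_R = 3.0

NATALIZUMAB_PRIMARY = 0.533
NATALIZUMAB_HEAD = (4.77e-5, 6.29e-5, 1.44e-4)
NATALIZUMAB_MAX = 0.992
NATALIZUMAB_R = 100.0
NATALIZUMAB_S = 50


def _posaconazole() -> EndpointTable:
    return EndpointTable.from_pvalues(
        [POSACONAZOLE_PRIMARY], POSACONAZOLE_SECONDARY, R=POSACONAZOLE_R
    )


def _natalizumab_head() -> EndpointTable:
    """The published subset only: NOT a valid 50-endpoint table.

    Weighted-Simes on this four-value head gives an upper bound for the
    full-list intersection p-value when each term uses its true rank out
    of 50; the bound coincides with the published value because the
    minimum is attained at rank 2.
    """
    p = NATALIZUMAB_HEAD + (NATALIZUMAB_MAX,)
    return EndpointTable.from_pvalues([NATALIZUMAB_PRIMARY], p, R=NATALIZUMAB_R)


def natalizumab_synthetic_secondary() -> np.ndarray:
    """Synthetic 50-value secondary p-value list.

    The published values (three smallest, the 12th, the largest) are
    kept; the 45 unpublished values are filled in so that the published
    decision boundaries are respected: the intersection p-value is
    attained at rank 2 (6.29e-5 * 50/2 = 1.57e-3), the hierarchical
    procedure at its calibrated level rejects exactly 12 secondaries,
    and the single-level weighted BH at q = 0.05 rejects exactly 10.
    Synthetic data — only the anchors are real.
    """
    filler_low = [3e-4, 5e-4, 8e-4, 1.2e-3, 1.8e-3, 2.6e-3]  # ranks 4-9
    tail = np.linspace(0.02, 0.95, 36)  # ranks 14-49
    p = np.concatenate(
        [
            NATALIZUMAB_HEAD,
            filler_low,
            [3.1e-3, 5.0e-3, 6.0e-3, 8.0e-3],  # ranks 10-13
            tail,
            [NATALIZUMAB_MAX],
        ]
    )
    assert p.size == NATALIZUMAB_S and np.all(np.diff(p) > 0)
    return p


def _natalizumab_synthetic() -> EndpointTable:
    return EndpointTable.from_pvalues(
        [NATALIZUMAB_PRIMARY], natalizumab_synthetic_secondary(), R=NATALIZUMAB_R
    )


FIXTURES = (
    "posaconazole",
    "natalizumab_head",
    "natalizumab_full",
    "natalizumab_synthetic",
)


def load_fixture(name: str, path: str | Path | None = None) -> EndpointTable:
    """Load a bundled example table by name.

    ``natalizumab_full`` is not bundled: pass ``path`` to a one-column
    text file (no header needed) holding the 50 secondary p-values.
    """
    if name == "posaconazole":
        return _posaconazole()
    if name == "natalizumab_head":
        return _natalizumab_head()
    if name == "natalizumab_synthetic":
        return _natalizumab_synthetic()
    if name == "natalizumab_full":
        if path is None:
            raise ValueError(
                "the full 50-value secondary list is not bundled; supply "
                "path=<file with one p-value per line> (see the trial's "
                "supplementary material), or use 'natalizumab_synthetic'"
            )
        values = np.loadtxt(path, ndmin=1)
        if values.size != NATALIZUMAB_S:
            raise ValueError(
                f"expected {NATALIZUMAB_S} secondary p-values, got {values.size}"
            )
        return EndpointTable.from_pvalues(
            [NATALIZUMAB_PRIMARY], values, R=NATALIZUMAB_R
        )
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
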