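"""Power and error simulation study for the weighted FDR procedures.

One simulated trial draws independent standard normal test statistics,
adds the scenario's effect sizes, and converts them to two-sided
p-values ``p = 2 * (1 - Phi(|X|))``.  The scenario fixes: the primary
effect ``mu_p``; the number of secondaries ``S``; the fraction of false
secondaries; the effect ``mu_s1`` of one designated false secondary and
``mu_si`` of the remaining false ones; the weight ratio ``R``; and the
target level ``q``.  Each procedure is applied to every replicate and
five power measures are estimated together with the empirical wFDR:

* ``pi_G``  — overall weighted power, the expected weight-fraction of
  false endpoints that are rejected;
* ``pi_P``  — probability of rejecting the (false) primary endpoint;
* ``pi_S``  — weighted power over the false secondaries alone;
* ``pi_ALOS`` — probability of at least one secondary discovery;
* ``pi_delta(d)`` — the convex combination d/(d+1)*pi_P + 1/(d+1)*pi_S,
  a design-stage trade-off curve computable after the fact.

The hierarchical procedure runs at the level calibrated for
``(q, S, R)`` under independence; the single-level weighted BH runs at
``q``; the gatekeepers run at FWER level ``q``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import _engine
from .calibration import CalibrationSpec, calibrate_alpha
from .core import EndpointTable

__all__ = [
    "SimulationScenario",
    "PowerReport",
    "PROCEDURES",
    "simulate_trial",
    "power_measures",
    "run_scenario",
    "run_grid",
    "default_grid",
]

PROCEDURES = ("hwf", "wbh", "gk_bonferroni", "gk_simes")
GK_MAX_S = 8  # gatekeepers are compared only on small secondary families


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation grid."""

    mu_p: float
    mu_s1: float
    mu_si: float
    S: int
    R: float
    frac_false: float
    q: float = 0.05
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if min(self.mu_p, self.mu_s1, self.mu_si) < 0:
            raise ValueError("effects must be nonnegative")
        n_false = self.frac_false * self.S
        if abs(n_false - round(n_false)) > 1e-9:
            raise ValueError("frac_false * S must be an integer")

    @property
    def n_false_secondary(self) -> int:
        return int(round(self.frac_false * self.S))

    def effects(self) -> np.ndarray:
        """Mean vector (primary first).  The designated false secondary
        sits at index 1; further false secondaries follow it.  When only
        one secondary is false, mu_si plays no role."""
        mu = np.zeros(self.S + 1)
        mu[0] = self.mu_p
        m1 = self.n_false_secondary
        if m1 >= 1:
            mu[1] = self.mu_s1
        if m1 >= 2:
            mu[2 : m1 + 1] = self.mu_si
        return mu

    def truth_null(self) -> np.ndarray:
        """Boolean mask, True where the endpoint is a true null."""
        return self.effects() == 0.0


def _pvalues(z: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return 2.0 * norm.sf(np.abs(z + mu))


def simulate_trial(
    scenario: SimulationScenario, rep_index: int
) -> tuple[EndpointTable, dict[str, bool]]:
    """Draw one replicate as an endpoint table plus truth labels.

    Deterministic in ``(scenario.seed, rep_index)``; distinct replicate
    indices use independent streams, so per-replicate and batched
    execution can be cross-checked.
    """
    rng = np.random.default_rng([scenario.seed, rep_index])
    mu = scenario.effects()
    p = _pvalues(rng.standard_normal(scenario.S + 1), mu)
    table = EndpointTable.from_pvalues([p[0]], p[1:], R=scenario.R)
    null = scenario.truth_null()
    truth = {table.ids[i]: bool(null[i]) for i in range(table.m)}
    return table, truth


def _pvalue_matrix(scenario: SimulationScenario) -> np.ndarray:
    """All replicates at once, one independent stream per replicate."""
    ss = np.random.SeedSequence([scenario.seed, 0x5EED])
    rng = np.random.default_rng(ss)
    z = rng.standard_normal((scenario.reps, scenario.S + 1))
    return _pvalues(z, scenario.effects())


@dataclass(frozen=True)
class PowerReport:
    """Monte-Carlo power and error estimates for one (scenario, procedure)."""

    procedure: str
    alpha_used: float
    reps: int
    pi_G: float
    pi_P: float
    pi_S: float
    pi_ALOS: float
    wfdr_hat: float
    se: Mapping[str, float]

    def pi_delta(self, delta: float) -> float:
        """Trade-off combination of primary and secondary power; the
        weight delta >= 0 is a reporting choice, not an analysis input."""
        if delta < 0:
            raise ValueError("delta must be >= 0")
        return delta / (delta + 1.0) * self.pi_P + 1.0 / (delta + 1.0) * self.pi_S

    def to_dict(self) -> dict:
        d = {
            "procedure": self.procedure,
            "alpha_used": self.alpha_used,
            "reps": self.reps,
            "pi_G": self.pi_G,
            "pi_P": self.pi_P,
            "pi_S": self.pi_S,
            "pi_ALOS": self.pi_ALOS,
            "wfdr_hat": self.wfdr_hat,
        }
        d.update({f"se_{k}": v for k, v in self.se.items()})
        return d


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))


def power_measures(
    rejections: np.ndarray,
    null: np.ndarray,
    weights: np.ndarray,
    procedure: str = "",
    alpha_used: float = float("nan"),
) -> PowerReport:
    """Aggregate per-replicate rejection masks into a :class:`PowerReport`.

    ``rejections`` is (reps, m) boolean with the primary in column 0;
    ``null`` is the length-m truth mask (True = true null) and
    ``weights`` the endpoint weights.  Power measures require at least
    one false hypothesis; the empirical wFDR is always available.
    """
    rejections = np.asarray(rejections, dtype=bool)
    null = np.asarray(null, dtype=bool)
    w = np.asarray(weights, dtype=float)
    reps = rejections.shape[0]
    false = ~null
    if not false.any():
        raise ValueError("power is undefined when no hypothesis is false")

    w_false = w * false
    gain = rejections @ w_false
    pi_G, se_G = _mean_se(gain / w_false.sum())

    if false[0]:
        pi_P, se_P = _mean_se(rejections[:, 0].astype(float))
    else:
        pi_P, se_P = float("nan"), float("nan")

    false_sec = false.copy()
    false_sec[0] = False
    if false_sec.any():
        ws = w * false_sec
        pi_S, se_S = _mean_se((rejections @ ws) / ws.sum())
        pi_A, se_A = _mean_se((rejections[:, false_sec].any(axis=1)).astype(float))
    else:
        pi_S = se_S = pi_A = se_A = float("nan")

    w_v = w * null
    num = rejections @ w_v
    den = rejections @ w
    q_w = np.divide(num, den, out=np.zeros(reps), where=den > 0)
    wfdr_hat, se_w = _mean_se(q_w)

    return PowerReport(
        procedure=procedure,
        alpha_used=alpha_used,
        reps=reps,
        pi_G=pi_G,
        pi_P=pi_P,
        pi_S=pi_S,
        pi_ALOS=pi_A,
        wfdr_hat=wfdr_hat,
        se={"pi_G": se_G, "pi_P": se_P, "pi_S": se_S, "pi_ALOS": se_A, "wfdr_hat": se_w},
    )


def _decide(pmat: np.ndarray, procedure: str, scenario: SimulationScenario, alpha: float):
    if procedure == "hwf":
        rej, _ = _engine.decide_hwf(pmat, scenario.R, alpha)
        return rej
    if procedure == "wbh":
        return _engine.decide_wbh(pmat, scenario.R, alpha)
    if procedure == "gk_bonferroni":
        return _engine.decide_gk(pmat, alpha, "bonferroni")
    if procedure == "gk_simes":
        return _engine.decide_gk(pmat, alpha, "simes")
    raise ValueError(f"unknown procedure {procedure!r}")


def run_scenario(
    scenario: SimulationScenario,
    procedures: Sequence[str] = PROCEDURES,
) -> dict[str, PowerReport]:
    """Estimate all power measures for each procedure on one scenario.

    The hierarchical procedure's working level is calibrated once per
    scenario from ``(q, S, R)`` under independence; wBH and the
    gatekeepers run at ``q`` directly.  Replicates are processed in
    batches so memory stays bounded in ``reps``.
    """
    null = scenario.truth_null()
    weights = np.concatenate([[scenario.R], np.ones(scenario.S)])
    alphas: dict[str, float] = {}
    for proc in procedures:
        if proc == "hwf":
            spec = CalibrationSpec(q=scenario.q, S=scenario.S, R=scenario.R)
            alphas[proc] = calibrate_alpha(spec).alpha
        else:
            alphas[proc] = scenario.q
        if proc.startswith("gk_") and scenario.S > GK_MAX_S:
            raise ValueError(
                f"gatekeeper baselines are run only for S <= {GK_MAX_S}"
            )

    batch = 50_000
    masks: dict[str, list[np.ndarray]] = {p: [] for p in procedures}
    done = 0
    ss = np.random.SeedSequence([scenario.seed, 0x5EED])
    rng = np.random.default_rng(ss)
    mu = scenario.effects()
    while done < scenario.reps:
        n = min(batch, scenario.reps - done)
        pmat = _pvalues(rng.standard_normal((n, scenario.S + 1)), mu)
        for proc in procedures:
            masks[proc].append(_decide(pmat, proc, scenario, alphas[proc]))
        done += n
    return {
        proc: power_measures(
            np.concatenate(masks[proc]), null, weights, proc, alphas[proc]
        )
        for proc in procedures
    }


def default_grid(
    mu_p: Iterable[float] = (0, 1, 2, 3, 4),
    R: Iterable[float] = (1, 2, 8, 32, 128, 512),
    S: Iterable[int] = (2, 4, 8, 16, 32),
    frac_false: Iterable[float] = (0.25, 0.5, 0.75, 1.0),
    mu_s1: Iterable[float] = (2, 3, 4, 5, 6),
    mu_si: Iterable[float] = (1, 1.5, 2, 2.5, 3),
    q: float = 0.05,
    reps: int = 10_000,
    seed: int = 0,
) -> list[SimulationScenario]:
    """Enumerate the full factorial grid of scenarios.

    ``S = 2`` is restricted to whole or half false fractions (0.25 and
    0.75 do not yield integer counts there), and cells whose
    ``frac_false * S`` is not an integer are dropped.  When only one
    secondary is false, ``mu_si`` is irrelevant and collapsed to a
    single representative cell.  The builder documents its own
    enumeration; no particular total cell count is asserted.
    """
    cells: list[SimulationScenario] = []
    seen: set[tuple] = set()
    idx = 0
    for s in S:
        for frac in frac_false:
            n_false = frac * s
            if abs(n_false - round(n_false)) > 1e-9 or round(n_false) < 1:
                continue
            for r in R:
                for mp in mu_p:
                    for ms1 in mu_s1:
                        for msi in mu_si if round(n_false) >= 2 else (0.0,):
                            key = (s, frac, r, mp, ms1, msi)
                            if key in seen:
                                continue
                            seen.add(key)
                            cells.append(
                                SimulationScenario(
                                    mu_p=mp,
                                    mu_s1=ms1,
                                    mu_si=msi,
                                    S=s,
                                    R=r,
                                    frac_false=frac,
                                    q=q,
                                    reps=reps,
                                    seed=seed + idx,
                                )
                            )
                            idx += 1
    return cells


def run_grid(
    scenarios: Sequence[SimulationScenario],
    procedures: Sequence[str] = PROCEDURES,
    delta: Sequence[float] = (),
) -> pd.DataFrame:
    """Run every (scenario, procedure) cell and return a tidy table.

    Gatekeeper procedures are silently skipped for cells with
    ``S > 8``, mirroring the restriction under which they are feasible.
    Optional ``delta`` values add pi_delta columns.
    """
    rows = []
    for scn in scenarios:
        procs = [
            p for p in procedures if not (p.startswith("gk_") and scn.S > GK_MAX_S)
        ]
        reports = run_scenario(scn, procs)
        for proc, rep in reports.items():
            row = {
                "mu_p": scn.mu_p,
                "mu_s1": scn.mu_s1,
                "mu_si": scn.mu_si,
                "S": scn.S,
                "R": scn.R,
                "frac_false": scn.frac_false,
                "q": scn.q,
                "seed": scn.seed,
            }
            row.update(rep.to_dict())
            for d in delta:
                row[f"pi_delta_{d:g}"] = rep.pi_delta(d)
            rows.append(row)
    return pd.DataFrame(rows)
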