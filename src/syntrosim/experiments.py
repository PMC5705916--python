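"""Simulation experiments: parameter scans, outcome classification, yields.

The scans mirror the standard in-silico protocols: vary the producer:
recipient NH4+ affinity ratio, the producer's NH4+ excretion level, or the
inoculum composition, run batch (or serial-transfer) cultures, and classify
each grid point by whether each species achieved net growth.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import CultureState, ModelVariant
from .params import ParameterSet
from .simulate import (
    FeedSchedule,
    Trajectory,
    TransferProtocol,
    TransferSeries,
    default_initial_state,
    serial_transfer,
    simulate_batch,
)

__all__ = [
    "OutcomeClass",
    "Outcome",
    "ScanTable",
    "YieldTable",
    "classify_outcome",
    "affinity_ratio_scan",
    "excretion_scan",
    "inoculum_ratio_scan",
    "find_critical_ratio",
    "compute_yields",
    "competitive_index",
    "NoBracketError",
    "FIG2B_RATIO_GRID",
]

#: canonical log-decade affinity-ratio grid used for phase-behaviour scans
FIG2B_RATIO_GRID = tuple(float(10.0 ** k) for k in range(-3, 4))

#: minimum fold-change counting as net growth of a species in a batch.
#: In a death-free ODE every density is weakly increasing, so the literal
#: "final > initial" test is degenerate (vanishing residual growth always
#: satisfies it); requiring at least one doubling over the run makes the
#: classification meaningful while keeping boundary equality a failure.
DEFAULT_GROWTH_MARGIN = 2.0

#: relative per-transfer decline that counts as "strictly decreasing" when
#: detecting collapse over serial transfers (guards against float noise).
DEFAULT_DECLINE_TOL = 0.01


class NoBracketError(ValueError):
    """Bisection endpoints evaluate to the same classification."""


class OutcomeClass(enum.Enum):
    BOTH_GROW = "both_grow"
    EC_FAILS = "ec_fails"
    RP_FAILS = "rp_fails"
    BOTH_FAIL = "both_fail"
    COLLAPSE_OVER_TRANSFERS = "collapse_over_transfers"


@dataclass(frozen=True)
class Outcome:
    """Classification of one completed batch or transfer series."""

    category: OutcomeClass
    ec_grew: bool
    rp_grew: bool
    final_Ec: float
    final_Rp: float
    final_pct_Ec: float

    def as_record(self) -> Dict[str, object]:
        return {
            "outcome": self.category.value,
            "ec_grew": self.ec_grew,
            "rp_grew": self.rp_grew,
            "final_Ec": self.final_Ec,
            "final_Rp": self.final_Rp,
            "final_pct_Ec": self.final_pct_Ec,
        }


@dataclass
class ScanTable:
    """Map from scanned parameter values to outcome summaries."""

    parameter: str
    grid: np.ndarray
    outcomes: List[Outcome]
    fixed: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if len(self.outcomes) != self.grid.size:
            raise ValueError("one outcome required per grid point")
        d = np.diff(self.grid)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("scan grid must be strictly monotone")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for v, o in zip(self.grid, self.outcomes):
            rows.append({self.parameter: v, **o.as_record()})
        return pd.DataFrame(rows)

    def categories(self) -> List[OutcomeClass]:
        return [o.category for o in self.outcomes]


@dataclass(frozen=True)
class YieldTable:
    """Product yields in mol per mol glucose consumed."""

    yield_C: float
    yield_F: float
    yield_E: float
    yield_H: float
    yield_A_net: float
    glucose_consumed: float     # mM
    nh4_fixed: float            # mM routed through fixation (communal only bookkeeping)
    n2_consumed: float          # mM N2; 1 N2 -> 2 NH4+

    def as_record(self) -> Dict[str, float]:
        return {
            "yield_C": self.yield_C, "yield_F": self.yield_F,
            "yield_E": self.yield_E, "yield_H": self.yield_H,
            "yield_A_net": self.yield_A_net,
            "glucose_consumed": self.glucose_consumed,
            "nh4_fixed": self.nh4_fixed, "n2_consumed": self.n2_consumed,
        }


# ---------------------------------------------------------------------------
# classification


def _net_growth(initial: float, final: float, margin: float) -> bool:
    return final > initial * margin


def classify_outcome(result: Union[Trajectory, TransferSeries],
                     *,
                     growth_margin: float = DEFAULT_GROWTH_MARGIN,
                     decline_tol: float = DEFAULT_DECLINE_TOL,
                     collapse_requires_both: bool = True) -> Outcome:
    """Classify a finished run.

    For a :class:`Trajectory`, each species shows net growth when its final
    density exceeds its starting density by at least ``growth_margin``
    (boundary equality counts as failure).  For a :class:`TransferSeries`,
    the run is a collapse when the per-transfer final densities of both
    species (or of the fermenter only, with ``collapse_requires_both=False``)
    decline monotonically over the last ``max(3, n_transfers - 1)``
    transfers, each step by more than ``decline_tol`` relatively.
    """
    if isinstance(result, Trajectory):
        if result.times.size == 0:
            raise ValueError("empty trajectory")
        ini, fin = result.initial, result.final
        ec = _net_growth(ini.Ec, fin.Ec, growth_margin)
        rp = _net_growth(ini.Rp, fin.Rp, growth_margin)
        if ec and rp:
            cat = OutcomeClass.BOTH_GROW
        elif rp:
            cat = OutcomeClass.EC_FAILS
        elif ec:
            cat = OutcomeClass.RP_FAILS
        else:
            cat = OutcomeClass.BOTH_FAIL
        total = fin.Ec + fin.Rp
        pct = 100.0 * fin.Ec / total if total > 0 else float("nan")
        return Outcome(cat, ec, rp, fin.Ec, fin.Rp, pct)

    if isinstance(result, TransferSeries):
        if not result.trajectories:
            raise ValueError("empty transfer series")
        n = len(result.trajectories)
        window = min(n, max(3, n - 1))
        ec_fin = result.final_densities("Ec")[-window:]
        rp_fin = result.final_densities("Rp")[-window:]

        def declining(vals: np.ndarray) -> bool:
            return bool(np.all(vals[1:] < vals[:-1] * (1.0 - decline_tol)))

        ec_declines = declining(ec_fin)
        rp_declines = declining(rp_fin)
        collapse = (ec_declines and rp_declines) if collapse_requires_both \
            else ec_declines
        last = result.trajectories[-1]
        inner = classify_outcome(last, growth_margin=growth_margin)
        if collapse:
            return Outcome(OutcomeClass.COLLAPSE_OVER_TRANSFERS,
                           inner.ec_grew, inner.rp_grew,
                           inner.final_Ec, inner.final_Rp, inner.final_pct_Ec)
        return inner

    raise TypeError(f"cannot classify {type(result).__name__}")


# ---------------------------------------------------------------------------
# scans


def affinity_ratio_scan(params: ParameterSet,
                        ratios: Sequence[float],
                        duration: float = 300.0,
                        variant: ModelVariant | str = ModelVariant.DEFAULT,
                        *,
                        init: Optional[CultureState] = None,
                        growth_margin: float = DEFAULT_GROWTH_MARGIN,
                        rtol: Optional[float] = None) -> ScanTable:
    """One batch per producer:recipient affinity ratio; classify each."""
    variant = ModelVariant.coerce(variant)
    ratios = np.asarray(list(ratios), dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("affinity ratios must be > 0")
    init = init or default_initial_state()
    kwargs = {} if rtol is None else {"rtol": rtol}
    outcomes = []
    for r in ratios:
        p = params.with_affinity_ratio(float(r))
        traj = simulate_batch(p, init, duration, variant, **kwargs)
        outcomes.append(classify_outcome(traj, growth_margin=growth_margin))
    return ScanTable("affinity_ratio", ratios, outcomes,
                     fixed={"variant": variant.value, "duration_h": duration,
                            "growth_margin": growth_margin})


def excretion_scan(params: ParameterSet,
                   RA_values: Sequence[float],
                   duration: float = 300.0,
                   *,
                   affinity_ratio: float = 1000.0,
                   init: Optional[CultureState] = None,
                   growth_margin: float = DEFAULT_GROWTH_MARGIN) -> ScanTable:
    """Scan the producer NH4+ excretion level R_A at a fixed affinity ratio.

    By default the producer is given a 1000-fold NH4+ affinity advantage
    (K_A = 10 mM, K_AR = 0.01 mM), the regime in which only increased
    excretion can rescue the recipient.
    """
    RA_values = np.asarray(list(RA_values), dtype=float)
    if np.any(RA_values < 0):
        raise ValueError("R_A values must be >= 0")
    base = params.with_affinity_ratio(affinity_ratio)
    init = init or default_initial_state()
    outcomes = []
    for ra in RA_values:
        p = base.with_overrides(R_A=float(ra))
        traj = simulate_batch(p, init, duration, ModelVariant.DEFAULT)
        outcomes.append(classify_outcome(traj, growth_margin=growth_margin))
    return ScanTable("R_A", RA_values, outcomes,
                     fixed={"affinity_ratio": affinity_ratio,
                            "duration_h": duration,
                            "growth_margin": growth_margin})


def inoculum_ratio_scan(params: ParameterSet,
                        rp_to_ec_ratios: Sequence[float],
                        duration: float = 300.0,
                        *,
                        affinity_ratio: float = 1000.0,
                        reference_density: float = 2.7e6,
                        glucose: float = 25.0,
                        growth_margin: float = DEFAULT_GROWTH_MARGIN) -> ScanTable:
    """Scan the producer:recipient inoculum ratio at a fixed affinity ratio.

    A ratio of 1 inoculates both species at ``reference_density``; other
    ratios are reached by diluting whichever species is in the minority
    (never by concentrating above the reference).
    """
    ratios = np.asarray(list(rp_to_ec_ratios), dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("inoculum ratios must be > 0")
    p = params.with_affinity_ratio(affinity_ratio)
    outcomes = []
    for rho in ratios:
        if rho >= 1.0:
            rp0, ec0 = reference_density, reference_density / rho
        else:
            rp0, ec0 = reference_density * rho, reference_density
        init = CultureState(Ec=ec0, Rp=rp0, G=glucose)
        traj = simulate_batch(p, init, duration, ModelVariant.DEFAULT)
        outcomes.append(classify_outcome(traj, growth_margin=growth_margin))
    return ScanTable("rp_to_ec_inoculum_ratio", ratios, outcomes,
                     fixed={"affinity_ratio": affinity_ratio,
                            "reference_density": reference_density,
                            "duration_h": duration,
                            "growth_margin": growth_margin})


# ---------------------------------------------------------------------------
# critical-ratio search


def _batch_ok(params: ParameterSet, ratio: float, duration: float,
              variant: ModelVariant, growth_margin: float) -> bool:
    p = params.with_affinity_ratio(ratio)
    traj = simulate_batch(p, default_initial_state(), duration, variant)
    return classify_outcome(
        traj, growth_margin=growth_margin).category is OutcomeClass.BOTH_GROW


def _transfer_ok(params: ParameterSet, ratio: float,
                 protocol: TransferProtocol, variant: ModelVariant,
                 growth_margin: float, decline_tol: float) -> bool:
    p = params.with_affinity_ratio(ratio)
    series = serial_transfer(p, default_initial_state(), protocol, variant)
    out = classify_outcome(series, growth_margin=growth_margin,
                           decline_tol=decline_tol)
    return out.category is not OutcomeClass.COLLAPSE_OVER_TRANSFERS


def find_critical_ratio(params: ParameterSet,
                        criterion: str = "batch_net_growth",
                        bounds: Sequence[float] = (0.1, 10.0),
                        tol: float = 0.05,
                        *,
                        duration: float = 300.0,
                        variant: ModelVariant | str = ModelVariant.DEFAULT,
                        protocol: Optional[TransferProtocol] = None,
                        growth_margin: float = DEFAULT_GROWTH_MARGIN,
                        decline_tol: float = DEFAULT_DECLINE_TOL) -> float:
    """Bisect the affinity ratio at which the chosen criterion flips.

    ``batch_net_growth``: flip from BOTH_GROW to a failure class in one
    batch.  ``transfer_stability``: flip from stable serial transfers to
    collapse.  Endpoints must straddle the flip, otherwise
    :class:`NoBracketError` is raised.  Bisection proceeds on a log scale
    until the bracket width is <= ``tol`` (in ratio units).
    """
    variant = ModelVariant.coerce(variant)
    if criterion == "batch_net_growth":
        pred: Callable[[float], bool] = lambda r: _batch_ok(
            params, r, duration, variant, growth_margin)
    elif criterion == "transfer_stability":
        protocol = protocol or TransferProtocol()
        pred = lambda r: _transfer_ok(params, r, protocol, variant,
                                      growth_margin, decline_tol)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    lo, hi = float(bounds[0]), float(bounds[1])
    if lo <= 0 or hi <= 0 or lo > hi:
        raise ValueError("bounds must be positive with lo <= hi")
    if lo == hi:
        # degenerate bracket: accept only if perturbing by tol flips the sign
        f_lo = pred(max(lo - tol, lo * 0.5))
        f_hi = pred(hi + tol)
        if f_lo == f_hi:
            raise NoBracketError("criterion does not flip around the "
                                 f"degenerate bracket {lo}")
        return lo
    ok_lo, ok_hi = pred(lo), pred(hi)
    if ok_lo == ok_hi:
        raise NoBracketError(
            f"criterion {criterion!r} evaluates identically "
            f"({'ok' if ok_lo else 'fail'}) at both bounds {bounds}")
    while hi - lo > tol:
        mid = float(np.sqrt(lo * hi))
        if pred(mid) == ok_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# derived quantities


def compute_yields(traj: Trajectory) -> YieldTable:
    """Mol product per mol glucose consumed over a trajectory.

    Also books the nitrogen fixed through the communal pathway and the N2
    it required (2 NH4+ per N2).  Requires nonzero glucose consumption.
    """
    ini, fin = traj.initial, traj.final
    dG = ini.G - fin.G
    if dG <= 0:
        raise ValueError("no glucose consumed; yields are undefined")
    p = traj.params
    produced = {
        "C": max(fin.C - ini.C, 0.0),
        "F": max(fin.F - ini.F, 0.0),
        "E": max(fin.E - ini.E, 0.0),
        "H": max(fin.H - ini.H, 0.0),
    }
    a_net = max(fin.A - ini.A, 0.0)
    if traj.variant is ModelVariant.COMMUNAL:
        nh4_fixed = ((fin.A - ini.A)
                     + (fin.Ec - ini.Ec) / p.Y_EA
                     + (fin.Rp - ini.Rp) / p.Y_RA)
    else:
        # default variant: only the excreted share transits the pool
        nh4_fixed = p.R_A * p.unit_conv * (fin.Rp - ini.Rp)
    return YieldTable(
        yield_C=produced["C"] / dG,
        yield_F=produced["F"] / dG,
        yield_E=produced["E"] / dG,
        yield_H=produced["H"] / dG,
        yield_A_net=a_net / dG,
        glucose_consumed=dG,
        nh4_fixed=nh4_fixed,
        n2_consumed=nh4_fixed / 2.0,
    )


def competitive_index(traj: Trajectory) -> float:
    """Fermenter fold-change divided by fixer fold-change.

    1 means equally competitive for the limiting pulsed nutrient.
    """
    ini, fin = traj.initial, traj.final
    if ini.Ec <= 0 or ini.Rp <= 0:
        raise ValueError("competitive index requires both species inoculated")
    return (fin.Ec / ini.Ec) / (fin.Rp / ini.Rp)
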