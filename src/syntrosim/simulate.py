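"""Batch, serial-transfer and pulsed fed-batch integration drivers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    STATE_FIELDS,
    STATE_UNITS,
    CultureState,
    ModelVariant,
    rhs_array,
)
from .params import ParameterSet

__all__ = [
    "SimulationError",
    "Trajectory",
    "TransferProtocol",
    "FeedSchedule",
    "TransferSeries",
    "simulate_batch",
    "serial_transfer",
    "fed_batch",
    "default_initial_state",
]

# default integration tolerances; per-component atol reflects the very
# different magnitudes of cell densities (~1e9) and NH4+ (~1e-3 mM)
_DEFAULT_RTOL = 1e-8
_DEFAULT_ATOL = np.array([1e-1, 1e-1, 1e-10, 1e-13, 1e-10, 1e-10, 1e-10, 1e-10])

#: fresh-medium composition used at transfers (mM per dissolved species)
FRESH_MEDIUM: Dict[str, float] = {"G": 25.0, "A": 0.0, "C": 0.0, "F": 0.0, "E": 0.0, "H": 0.0}


class SimulationError(RuntimeError):
    """Integration failed; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class Trajectory:
    """Time-indexed solution of one uninterrupted (or pulsed) culture run."""

    times: np.ndarray                 # h, strictly increasing
    states: np.ndarray                # shape (n_times, 8), columns STATE_FIELDS
    variant: ModelVariant
    params: ParameterSet
    diagnostics: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(STATE_FIELDS)):
            raise ValueError("states shape does not match times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    # -- accessors ---------------------------------------------------------

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_FIELDS.index(name)]

    @property
    def initial(self) -> CultureState:
        return CultureState.from_array(self.states[0])

    @property
    def final(self) -> CultureState:
        return CultureState.from_array(self.states[-1])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time", self.times)
        return df

    def csv_header(self) -> List[str]:
        return ["time [h]"] + [f"{n} [{STATE_UNITS[n]}]" for n in STATE_FIELDS]


@dataclass(frozen=True)
class TransferProtocol:
    """Serial-passaging recipe: grow a batch, dilute, repeat."""

    batch_duration: float = 300.0          # h
    dilution_fraction: float = 0.01        # 1% inoculum
    n_transfers: int = 8
    fresh_medium: Dict[str, float] = field(default_factory=lambda: dict(FRESH_MEDIUM))
    carry_spent_medium: bool = True        # carry dissolved species at dilution

    def __post_init__(self) -> None:
        if not 0 < self.dilution_fraction <= 1:
            raise ValueError("dilution_fraction must lie in (0, 1]")
        if self.batch_duration <= 0:
            raise ValueError("batch_duration must be > 0")
        if self.n_transfers < 1:
            raise ValueError("n_transfers must be >= 1")
        unknown = set(self.fresh_medium) - set(FRESH_MEDIUM)
        if unknown:
            raise ValueError(f"unknown fresh-medium species: {sorted(unknown)}")


@dataclass(frozen=True)
class FeedSchedule:
    """Pulsed feeding of one dissolved species (instantaneous increments)."""

    pulse_times: Sequence[float] = field(
        default_factory=lambda: tuple(float(t) for t in range(1, 97)))
    increment: float = 0.005               # mM added per pulse (~5 uM)
    species: str = "A"
    duration: float = 96.0                 # h

    def __post_init__(self) -> None:
        if self.increment < 0:
            raise ValueError("pulse increment must be >= 0")
        if self.species not in STATE_FIELDS[2:]:
            raise ValueError(f"cannot feed species {self.species!r}")
        times = np.asarray(self.pulse_times, dtype=float)
        if times.size and (times.min() < 0 or times.max() > self.duration):
            raise ValueError("pulse times must lie within [0, duration]")
        if np.any(np.diff(times) < 0):
            raise ValueError("pulse times must be sorted")


@dataclass
class TransferSeries:
    """Trajectories and per-transfer summaries from serial passaging."""

    trajectories: List[Trajectory]
    protocol: TransferProtocol

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, traj in enumerate(self.trajectories, start=1):
            ini, fin = traj.initial, traj.final
            total = fin.Ec + fin.Rp
            rows.append({
                "transfer": k,
                "Ec_initial": ini.Ec, "Rp_initial": ini.Rp,
                "Ec_final": fin.Ec, "Rp_final": fin.Rp,
                "pct_Ec_final": 100.0 * fin.Ec / total if total > 0 else float("nan"),
            })
        return pd.DataFrame(rows)

    def final_densities(self, species: str) -> np.ndarray:
        idx = STATE_FIELDS.index(species)
        return np.array([t.states[-1, idx] for t in self.trajectories])


# ---------------------------------------------------------------------------


def _integrate(params: ParameterSet, y0: np.ndarray, t0: float, t1: float,
               variant: ModelVariant, grid_dt: float,
               rtol: float, atol) -> tuple:
    """Integrate one uninterrupted span; returns (times, states, diagnostics)."""
    n = max(1, int(round((t1 - t0) / grid_dt)))
    t_eval = np.linspace(t0, t1, n + 1)
    sol = solve_ivp(
        rhs_array, (t0, t1), y0, args=(params, variant),
        method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol,
        dense_output=False,
    )
    diag = {
        "success": bool(sol.success),
        "message": str(sol.message),
        "nfev": int(sol.nfev),
        "njev": int(getattr(sol, "njev", 0) or 0),
        "n_internal_steps": int(sol.t.size),
    }
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}", diag)
    states = sol.y.T.copy()
    # clamp tiny negative excursions to zero, recording the event
    neg = states < 0
    if np.any(neg):
        diag["clamped_points"] = int(neg.sum())
        diag["clamp_min_value"] = float(states[neg].min())
        states[neg] = 0.0
    else:
        diag["clamped_points"] = 0
    return t_eval, states, diag


def simulate_batch(params: ParameterSet,
                   init: CultureState,
                   duration: float = 300.0,
                   variant: ModelVariant | str = ModelVariant.DEFAULT,
                   *,
                   grid_dt: float = 1.0,
                   rtol: float = _DEFAULT_RTOL,
                   atol=None) -> Trajectory:
    """Integrate one batch culture and sample it on a regular grid.

    Uses a stiff-aware adaptive integrator (LSODA); states are clamped to be
    non-negative on output with any clamping recorded in the diagnostics.
    Integrator failure raises :class:`SimulationError` rather than silently
    truncating.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    variant = ModelVariant.coerce(variant)
    atol = _DEFAULT_ATOL if atol is None else atol
    y0 = init.to_array()
    times, states, diag = _integrate(
        params, y0, 0.0, float(duration), variant, grid_dt, rtol, atol)
    states[0] = y0  # first state is exactly the supplied initial state
    return Trajectory(times, states, variant, params, diag)


def dilute(final: CultureState, protocol: TransferProtocol) -> CultureState:
    """Apply the transfer carryover rule to a finished batch state."""
    d = protocol.dilution_fraction
    vals = {"Ec": d * final.Ec, "Rp": d * final.Rp}
    for name, fresh in protocol.fresh_medium.items():
        old = getattr(final, name)
        if protocol.carry_spent_medium:
            vals[name] = d * old + (1.0 - d) * fresh
        else:
            vals[name] = fresh
    return CultureState(**vals)


def serial_transfer(params: ParameterSet,
                    init: CultureState,
                    protocol: TransferProtocol = TransferProtocol(),
                    variant: ModelVariant | str = ModelVariant.DEFAULT,
                    *,
                    grid_dt: float = 1.0,
                    rtol: float = _DEFAULT_RTOL,
                    atol=None) -> TransferSeries:
    """Run ``n_transfers`` consecutive batches with dilution between them."""
    variant = ModelVariant.coerce(variant)
    trajectories: List[Trajectory] = []
    state = init
    for k in range(protocol.n_transfers):
        try:
            traj = simulate_batch(
                params, state, protocol.batch_duration, variant,
                grid_dt=grid_dt, rtol=rtol, atol=atol)
        except SimulationError as err:
            raise SimulationError(
                f"transfer {k + 1}/{protocol.n_transfers}: {err}",
                err.diagnostics) from err
        trajectories.append(traj)
        state = dilute(traj.final, protocol)
    return TransferSeries(trajectories, protocol)


def fed_batch(params: ParameterSet,
              init: CultureState,
              feed: FeedSchedule = FeedSchedule(),
              variant: ModelVariant | str = ModelVariant.DEFAULT,
              *,
              grid_dt: float = 1.0,
              rtol: float = _DEFAULT_RTOL,
              atol=None) -> Trajectory:
    """Batch culture with instantaneous solute pulses at scheduled times.

    The integrator restarts at every pulse; each pulse adds ``increment`` mM
    of the fed species to the running state (concentration increments, not
    volumes, are modeled).
    """
    variant = ModelVariant.coerce(variant)
    atol = _DEFAULT_ATOL if atol is None else atol
    idx = STATE_FIELDS.index(feed.species)
    pulse_times = [float(t) for t in feed.pulse_times]
    breakpoints = sorted({0.0, feed.duration, *pulse_times})
    breakpoints = [t for t in breakpoints if 0.0 <= t <= feed.duration]

    y = init.to_array()
    all_t: List[np.ndarray] = []
    all_y: List[np.ndarray] = []
    merged_diag: Dict[str, object] = {"segments": 0, "nfev": 0, "clamped_points": 0,
                                      "n_pulses": 0}
    t_prev = 0.0
    if breakpoints and breakpoints[0] == 0.0 and 0.0 in pulse_times:
        y[idx] += feed.increment
        merged_diag["n_pulses"] += 1
    for t_next in breakpoints:
        if t_next <= t_prev:
            continue
        times, states, diag = _integrate(
            params, y, t_prev, t_next, variant, grid_dt, rtol, atol)
        states[0] = y
        keep = slice(0, -1) if t_next < feed.duration else slice(None)
        all_t.append(times[keep])
        all_y.append(states[keep])
        y = states[-1].copy()
        merged_diag["segments"] = int(merged_diag["segments"]) + 1
        merged_diag["nfev"] = int(merged_diag["nfev"]) + diag["nfev"]
        merged_diag["clamped_points"] = (int(merged_diag["clamped_points"])
                                         + diag["clamped_points"])
        if t_next in pulse_times and t_next < feed.duration:
            y[idx] += feed.increment
            merged_diag["n_pulses"] = int(merged_diag["n_pulses"]) + 1
        t_prev = t_next
    if not all_t:  # degenerate: no positive span
        raise ValueError("feed schedule spans no positive duration")
    times = np.concatenate(all_t)
    states = np.vstack(all_y)
    return Trajectory(times, states, variant, params, merged_diag)


def default_initial_state(glucose: float = 25.0,
                          total_density: float = 1e9,
                          fermenter_fraction: float = 0.10,
                          dilution: float = 0.01) -> CultureState:
    """Standard inoculum: 1% dilution of a stationary coculture.

    The stationary coculture carries ``total_density`` cells/ml of which
    ``fermenter_fraction`` are the fermenter; the diluted batch starts in
    fresh medium (glucose only).  Defaults give Ec=1e6, Rp=9e6 cells/ml in
    25 mM glucose.  The absolute stationary density is calibrated, not a
    printed value.
    """
    return CultureState(
        Ec=total_density * fermenter_fraction * dilution,
        Rp=total_density * (1.0 - fermenter_fraction) * dilution,
        G=glucose,
    )
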