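"""Regulatory-loop dynamics: from intermittent luminal fluid trapping to
sustained sodium retention, ECF expansion and a blood-pressure surrogate.

The causal chain simulated here, over multi-day ingestion schedules:

1. Each ingestion of a hyperosmolar drink sequesters water in the small bowel
   (static trapping model, :mod:`osmotrap.trapping`).  The unreturned trapped
   water is a transient circulatory volume deficit.
2. The deficit drives dimensionless aldosterone and ADH indices (saturating
   linear response to the fractional deficit of circulating volume).  The
   aldosterone response is gated to zero while unabsorbed sodium from an
   electrolyte-rich beverage sits in the lumen (a salty meal blunts it).
3. Colonic sodium-absorption capacity adapts slowly — first-order relaxation
   with a days-scale time constant toward a target set by the *trailing
   average* aldosterone index over a few previous days (crypt cell renewal
   makes colon function an exposure memory, not an instantaneous response).
4. Sodium balance: dietary sodium not captured by the small bowel reaches the
   colon, which absorbs up to its current capacity; the kidney excretes
   proportionally to sodium above a setpoint that aldosterone shifts upward
   (renal sodium sparing).  ECF water follows sodium isotonically through
   urine-volume regulation, which ADH damps.
5. Mean arterial pressure surrogate: MAP = MAP0 * (1 + beta_bp * fractional
   ECF expansion).

Integration is fixed-step explicit Euler with event-aligned steps (fine steps
while any ingestion is being absorbed, coarse steps otherwise), so
trajectories are bit-reproducible; water and sodium ledgers close to machine
precision at every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .solutes import Beverage
from .trapping import (
    FAST_COMPLETION_H,
    ISOTONIC_REFERENCE,
    SLOW_COMPLETION_H,
    TrappingResult,
    analyze_beverage,
    absorption_timecourse,
)

__all__ = [
    "PhysiologyParams",
    "IngestionSchedule",
    "daily_schedule",
    "Trajectory",
    "SteadyStateSummary",
    "hormone_drive",
    "colon_adaptation_step",
    "simulate_schedule",
    "steady_state_summary",
    "replay_colon_capacity",
    "fit_colon_parameters",
]


@dataclass(frozen=True)
class PhysiologyParams:
    """Constants of the regulatory loop.

    The hormone, renal and colonic gains are illustrative defaults: the
    underlying physiology is qualitative, so they are chosen to give a
    plausible baseline (MAP 93 mmHg) and a steady-state rise of a few mmHg
    under a three-drinks-per-day hyperosmolar schedule.  All of them live
    here and round-trip through YAML parameter files.
    """

    # Compartments
    V_ecf0: float = 15.0        # baseline extracellular fluid volume, L
    V_circ0: float = 5.0        # baseline circulating (blood) volume, L
    na_conc: float = 140.0      # ECF sodium concentration, mmol/L

    # Sodium intake and handling
    Na_intake_basal: float = 150.0   # dietary sodium, mmol/day
    colon_na_delivery: float = 30.0  # sodium reaching the colon, mmol/day
    C0: float = 25.0            # baseline colonic sodium absorption, mmol/day
    C_gain: float = 25.0        # mmol/day of extra capacity per unit avg aldo index
    tau_colon: float = 2.0      # colon adaptation time constant, days
    window_days: float = 3.0    # trailing window for hormone exposure averaging
    k_renal: float = 0.1        # renal sodium excretion rate constant, /day
    na_set_aldo: float = 100.0  # upward setpoint shift, mmol per unit aldo index

    # Hormone drive
    k_aldo: float = 6.0         # aldo index per unit fractional circulatory deficit
    k_adh: float = 6.0          # ADH index per unit fractional circulatory deficit
    aldo_saturation: float = 2.0  # cap on either index

    # Water handling
    water_intake_basal: float = 2.0  # background drinking, L/day
    k_water: float = 40.0       # urine-volume gain, L/day per L of ECF excess
    s_adh: float = 0.5          # urine damping per unit ADH index

    # Pressure surrogate
    beta_bp: float = 2.0        # fractional MAP rise per fractional ECF expansion
    MAP0: float = 93.0          # baseline mean arterial pressure, mmHg

    # Intestinal kinetics
    fructose_completion_h: float = SLOW_COMPLETION_H  # raise for impaired absorbers
    O_iso: float = ISOTONIC_REFERENCE                 # isotonic reference, mosm/L

    def __post_init__(self) -> None:
        for name in (
            "V_ecf0", "V_circ0", "na_conc", "Na_intake_basal", "C0", "k_renal",
            "water_intake_basal", "k_water", "MAP0", "fructose_completion_h", "O_iso",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "colon_na_delivery", "C_gain", "k_aldo", "k_adh", "aldo_saturation",
            "na_set_aldo", "s_adh", "beta_bp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_colon < 1.0:
            raise ValueError("tau_colon must be >= 1 day")
        if self.window_days < 1.0:
            raise ValueError("window_days must be >= 1 day")

    # Derived baseline quantities (chosen so the no-ingestion state is an
    # exact fixed point of the integrator).
    @property
    def na_total0(self) -> float:
        """Baseline total ECF sodium, mmol."""
        return self.na_conc * self.V_ecf0

    @property
    def na_absorbed_basal(self) -> float:
        """Baseline absorbed dietary sodium, mmol/day (stool loses the rest)."""
        return (
            self.Na_intake_basal
            - self.colon_na_delivery
            + min(self.C0, self.colon_na_delivery)
        )

    @property
    def na_setpoint0(self) -> float:
        """Renal setpoint balancing baseline absorption at baseline sodium."""
        return self.na_total0 - self.na_absorbed_basal / self.k_renal

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PhysiologyParams":
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "PhysiologyParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of parameter values")
        return cls.from_dict(data)


@dataclass(frozen=True)
class IngestionSchedule:
    """Timed ingestion events over a simulation horizon.

    ``events`` are (time in hours since start, beverage) pairs, ascending;
    ``duration_days`` is the simulated horizon.
    """

    events: tuple[tuple[float, Beverage], ...]
    duration_days: float

    def __post_init__(self) -> None:
        if not self.duration_days > 0:
            raise ValueError("duration_days must be > 0")
        object.__setattr__(self, "events", tuple(self.events))
        horizon_h = self.duration_days * 24.0
        last = -math.inf
        for t, bev in self.events:
            if not 0.0 <= t <= horizon_h:
                raise ValueError(
                    f"event at t={t} h outside schedule duration of "
                    f"{self.duration_days} days"
                )
            if t < last:
                raise ValueError("events must be sorted by time")
            last = t


def daily_schedule(
    beverage: Beverage,
    drinks_per_day: int,
    days: float,
    start_hour: float = 8.0,
    interval_h: float = 4.0,
) -> IngestionSchedule:
    """Regular habitual intake: ``drinks_per_day`` ingestions at fixed times each day."""
    if drinks_per_day < 0:
        raise ValueError("drinks_per_day must be >= 0")
    events = []
    for day in range(int(math.ceil(days))):
        for k in range(drinks_per_day):
            t = day * 24.0 + start_hour + k * interval_h
            if t <= days * 24.0:
                events.append((t, beverage))
    return IngestionSchedule(events=tuple(events), duration_days=days)


def hormone_drive(deficit: float, params: PhysiologyParams) -> tuple[float, float]:
    """Aldosterone and ADH indices for a circulatory water deficit (L).

    Saturating linear response to the deficit as a fraction of baseline
    circulating volume; zero deficit means zero incremental drive.  Sodium
    gating of the aldosterone response is applied by the simulator, which
    knows the luminal sodium state.
    """
    frac = max(0.0, deficit) / params.V_circ0
    aldo = min(params.aldo_saturation, params.k_aldo * frac)
    adh = min(params.aldo_saturation, params.k_adh * frac)
    return aldo, adh


def colon_adaptation_step(
    C: float, avg_aldo: float, dt: float, params: PhysiologyParams
) -> float:
    """One Euler step of colonic capacity relaxation (dt in days).

    dC/dt = (C0 + C_gain * avg_aldo - C) / tau_colon — capacity relaxes toward
    a target set by the trailing-average aldosterone index.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    target = params.C0 + params.C_gain * avg_aldo
    return C + dt * (target - C) / params.tau_colon


@dataclass
class Trajectory:
    """Simulated time series on the integration grid (one row per step)."""

    time_h: np.ndarray
    luminal: np.ndarray          # water in the small bowel + colon handoff, L
    deficit: np.ndarray          # circulatory water deficit from trapping, L
    aldo: np.ndarray             # aldosterone index (dimensionless)
    adh: np.ndarray              # ADH index (dimensionless)
    avg_aldo: np.ndarray         # trailing mean aldo over window_days
    colon_capacity: np.ndarray   # mmol/day
    na_total: np.ndarray         # total ECF sodium, mmol
    ecf: np.ndarray              # ECF volume, L
    map: np.ndarray              # mean arterial pressure surrogate, mmHg
    intake_cum: np.ndarray       # cumulative water intake (drinks + basal), L
    urine_cum: np.ndarray        # cumulative urine output, L
    params: PhysiologyParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time_h,
                "luminal_L": self.luminal,
                "deficit_L": self.deficit,
                "aldosterone_index": self.aldo,
                "adh_index": self.adh,
                "avg_aldosterone_index": self.avg_aldo,
                "colon_capacity_mmol_per_day": self.colon_capacity,
                "na_total_mmol": self.na_total,
                "ecf_L": self.ecf,
                "map_mmHg": self.map,
                "water_intake_cum_L": self.intake_cum,
                "urine_cum_L": self.urine_cum,
            }
        )

    @property
    def duration_days(self) -> float:
        return float(self.time_h[-1]) / 24.0


def _build_grid(
    schedule: IngestionSchedule,
    completions_h: Sequence[float],
    dt_fine_min: float,
    dt_coarse_min: float,
) -> np.ndarray:
    """Event-aligned fixed-step grid (hours): fine steps inside absorption
    windows, coarse elsewhere, with every event start and window end a grid
    point."""
    horizon = schedule.duration_days * 24.0
    windows = [
        (t, min(horizon, t + c))
        for (t, _), c in zip(schedule.events, completions_h)
    ]
    boundaries = sorted({0.0, horizon} | {b for w in windows for b in w})
    dt_fine = dt_fine_min / 60.0
    dt_coarse = dt_coarse_min / 60.0
    grid = [0.0]
    t = 0.0
    wi = 0  # windows are sorted by start; advance a pointer as t grows
    eps = 1e-9
    while t < horizon - eps:
        while wi < len(windows) and windows[wi][1] <= t + eps:
            wi += 1
        active = any(
            a <= t + eps < b for a, b in windows[wi:] if a <= t + eps
        )
        dt = dt_fine if active else dt_coarse
        nxt = t + dt
        for b in boundaries:
            if t + eps < b < nxt:
                nxt = b
                break
        nxt = min(nxt, horizon)
        grid.append(nxt)
        t = nxt
    return np.asarray(grid)


def simulate_schedule(
    schedule: IngestionSchedule,
    params: PhysiologyParams,
    seed: int = 0,
    dt_fine_min: float = 1.0,
    dt_coarse_min: float = 15.0,
) -> Trajectory:
    """Simulate the regulatory loop over an ingestion schedule.

    Deterministic for a given (schedule, params, seed); the seed is reserved
    for optional stochastic extensions and does not perturb the default
    model.  Raises if the integration produces a non-finite state.
    """
    del seed  # reserved: the default model has no noise sources
    results: list[TrappingResult] = [
        analyze_beverage(bev, O_iso=params.O_iso,
                         slow_completion_h=params.fructose_completion_h)
        for _, bev in schedule.events
    ]
    grid = _build_grid(
        schedule, [r.completion_h for r in results],
        dt_fine_min, dt_coarse_min,
    )
    n = len(grid)
    event_times = [t for t, _ in schedule.events]

    # State
    C = params.C0
    Na = params.na_total0
    ecf = params.V_ecf0
    lumen = 0.0           # small bowel + colonic handoff water
    intake_cum = 0.0
    urine_cum = 0.0
    na_set0 = params.na_setpoint0
    window_h = params.window_days * 24.0

    # Trailing aldo integral (index * days) with a two-pointer lookup
    hist_t: list[float] = []      # step start times, h
    hist_I: list[float] = []      # cumulative integral at step start
    hist_a: list[float] = []      # aldo held on [t_i, t_{i+1})
    I_total = 0.0
    tail = 0

    cols = {k: np.empty(n) for k in (
        "luminal", "deficit", "aldo", "adh", "avg_aldo", "colon",
        "na", "ecf", "map", "intake", "urine",
    )}

    ei = 0          # next event to activate
    active: list[int] = []   # indices of events already ingested
    # absorbed/diverted water per event at the previous grid time (for exact
    # per-step increments)
    prev_abs = [0.0] * len(results)
    prev_col = [0.0] * len(results)

    for i in range(n):
        t = float(grid[i])
        # Ingestion impulses at this grid point: drink enters the lumen and
        # the dilution water V_d steps out of the ECF instantaneously.
        while ei < len(results) and event_times[ei] <= t + 1e-9:
            r = results[ei]
            intake_cum += r.V
            lumen += r.V + r.V_d
            ecf -= r.V_d
            active.append(ei)
            ei += 1

        # Instantaneous deficit and hormone indices
        deficit = 0.0
        na_gate = 1.0
        for j in active:
            r = results[j]
            age = max(0.0, t - event_times[j])  # events activate within float eps
            state = absorption_timecourse(r, age)
            deficit += max(0.0, r.V_d - state.absorbed)
            if r.sodium_mmol > 0.0 and age < FAST_COMPLETION_H:
                na_gate = 0.0  # luminal sodium blunts the aldosterone response
        aldo, adh = hormone_drive(deficit, params)
        aldo *= na_gate

        # Trailing mean aldosterone over window_days (zero-padded before t=0)
        t0 = t - window_h
        if t0 <= 0.0 or not hist_t:
            avg_aldo = I_total / params.window_days
        else:
            while tail + 1 < len(hist_t) and hist_t[tail + 1] <= t0:
                tail += 1
            I0 = hist_I[tail] + hist_a[tail] * (t0 - hist_t[tail]) / 24.0
            avg_aldo = (I_total - I0) / params.window_days

        ecf_target = Na / params.na_conc
        mapv = params.MAP0 * (
            1.0 + params.beta_bp * (ecf - params.V_ecf0) / params.V_ecf0
        )
        if not (math.isfinite(Na) and math.isfinite(ecf) and math.isfinite(C)):
            raise RuntimeError(
                f"integration failure: non-finite state at step {i} (t={t:.3f} h)"
            )

        for key, val in (
            ("luminal", lumen), ("deficit", deficit), ("aldo", aldo),
            ("adh", adh), ("avg_aldo", avg_aldo), ("colon", C), ("na", Na),
            ("ecf", ecf), ("map", mapv), ("intake", intake_cum),
            ("urine", urine_cum),
        ):
            cols[key][i] = val

        if i == n - 1:
            break
        dt_h = float(grid[i + 1]) - t
        dt_d = dt_h / 24.0

        # Exact per-event water increments over the step
        d_abs = 0.0
        d_col = 0.0
        for j in active:
            r = results[j]
            age_next = max(0.0, t + dt_h - event_times[j])
            state = absorption_timecourse(r, age_next)
            d_abs += state.absorbed - prev_abs[j]
            d_col += state.to_colon - prev_col[j]
            prev_abs[j] = state.absorbed
            prev_col[j] = state.to_colon

        # Sodium balance.  Beverage electrolyte sodium counts within the
        # fixed daily dietary intake (it gates the aldosterone response but
        # is not an extra load on the ledger).
        absorb_rate = (
            params.Na_intake_basal
            - params.colon_na_delivery
            + min(C, params.colon_na_delivery)
        )
        excrete_rate = params.k_renal * max(
            0.0, Na - (na_set0 + params.na_set_aldo * aldo)
        )
        Na += (absorb_rate - excrete_rate) * dt_d

        # Colon capacity
        C = colon_adaptation_step(C, avg_aldo, dt_d, params)

        # Water balance: basal intake, regulated urine (ADH-damped), and the
        # analytic lumen fluxes
        urine_rate = max(
            0.0, params.water_intake_basal + params.k_water * (ecf - ecf_target)
        ) / (1.0 + params.s_adh * adh)
        intake_cum += params.water_intake_basal * dt_d
        urine_cum += urine_rate * dt_d
        ecf += params.water_intake_basal * dt_d - urine_rate * dt_d + d_abs
        lumen -= d_abs  # colonic handoff water stays in the luminal ledger

        # Aldosterone history for the trailing average
        hist_t.append(t)
        hist_I.append(I_total)
        hist_a.append(aldo)
        I_total += aldo * dt_d

    return Trajectory(
        time_h=grid,
        luminal=cols["luminal"],
        deficit=cols["deficit"],
        aldo=cols["aldo"],
        adh=cols["adh"],
        avg_aldo=cols["avg_aldo"],
        colon_capacity=cols["colon"],
        na_total=cols["na"],
        ecf=cols["ecf"],
        map=cols["map"],
        intake_cum=cols["intake"],
        urine_cum=cols["urine"],
        params=params,
    )


@dataclass(frozen=True)
class SteadyStateSummary:
    """Trailing-window means of the slow state variables."""

    mean_map_mmHg: float
    ecf_expansion_pct: float
    mean_colon_capacity: float
    mean_daily_aldo_exposure: float  # time-mean aldo index (index-days per day)
    mean_ecf_L: float

    def to_dict(self) -> dict:
        return asdict(self)


def steady_state_summary(traj: Trajectory, last_n_days: float = 3.0) -> SteadyStateSummary:
    """Time-weighted means over the trailing ``last_n_days`` of a trajectory."""
    horizon = traj.duration_days
    if last_n_days > horizon + 1e-9:  # tolerate float grid-endpoint error
        raise ValueError(
            f"window of {last_n_days} days exceeds trajectory of {horizon:.3g} days"
        )
    t0 = (horizon - last_n_days) * 24.0
    i0 = int(np.searchsorted(traj.time_h, t0))
    t = traj.time_h[i0:]
    if len(t) < 2:
        raise ValueError("trailing window contains fewer than two grid points")
    w = np.diff(t)

    def mean(x: np.ndarray) -> float:
        return float(np.sum(0.5 * (x[i0:][1:] + x[i0:][:-1]) * w) / np.sum(w))

    ecf_mean = mean(traj.ecf)
    p = traj.params
    return SteadyStateSummary(
        mean_map_mmHg=mean(traj.map),
        ecf_expansion_pct=100.0 * (ecf_mean - p.V_ecf0) / p.V_ecf0,
        mean_colon_capacity=mean(traj.colon_capacity),
        mean_daily_aldo_exposure=mean(traj.aldo),
        mean_ecf_L=ecf_mean,
    )


def replay_colon_capacity(
    time_h: np.ndarray,
    avg_aldo: np.ndarray,
    C_init: float,
    C0: float,
    C_gain: float,
    tau_colon: float,
) -> np.ndarray:
    """Re-integrate the colon-capacity ODE on a recorded grid for candidate
    parameters — the forward model used by :func:`fit_colon_parameters`."""
    C = np.empty_like(avg_aldo)
    C[0] = C_init
    dt_d = np.diff(time_h) / 24.0
    c = C_init
    for i, dt in enumerate(dt_d):
        c = c + dt * (C0 + C_gain * avg_aldo[i] - c) / tau_colon
        C[i + 1] = c
    return C


def fit_colon_parameters(
    traj: Trajectory,
    c_gain_grid: Sequence[float],
    tau_grid: Sequence[float],
) -> tuple[float, float]:
    """Grid-search (C_gain, tau_colon) that best reproduce a recorded
    colon-capacity series, given the trajectory's own hormone exposure.

    Returns the least-squares grid point.  The hormone drive does not depend
    on colonic capacity, so the recorded trailing-average aldosterone series
    is a valid exogenous input for every candidate.
    """
    best = (math.inf, None)
    p = traj.params
    for cg in c_gain_grid:
        for tau in tau_grid:
            pred = replay_colon_capacity(
                traj.time_h, traj.avg_aldo, traj.colon_capacity[0],
                p.C0, cg, tau,
            )
            sse = float(np.sum((pred - traj.colon_capacity) ** 2))
            if sse < best[0]:
                best = (sse, (cg, tau))
    assert best[1] is not None
    return best[1]
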