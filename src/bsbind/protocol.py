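"""Simulation of the cell-surface binding assay protocol and derived outputs.

Reproduces the in-vitro protocol in silico: antibody is dosed at t=0 and
associates with surface receptors for a fixed period (default 2 h); the
well may then be washed, which zeroes the free-antibody concentration, and
the system evolves for a further detection-incubation window (default
15 min) during which only dissociation and rebinding of tethered antibody
occur.  Longer no-washout simulations (24 h) approach binding equilibrium
and are used for dose x receptor-expression sweeps.

Summary outputs follow the bound-receptor accounting

    R_bound,binary  = [Ab·R1] + [Ab·R2]
    R_bound,ternary = 2 [R1·Ab·R2]
    R_bound,total   = R_bound,binary + R_bound,ternary

plus the bound-antibody signal (each antibody scaffold counted once,
regardless of valence engaged) which is the quantity comparable to a
flow-cytometry MFI readout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint, solve_ivp

from .kinetics import (
    DEFAULT_UNIT_CONTEXT,
    AntibodySpec,
    RateConstantSet,
    ReactionNetwork,
    UnitContext,
    build_network,
)

__all__ = [
    "DoseSchedule",
    "SolverSettings",
    "TimeCourse",
    "SimulationSummary",
    "SimulationError",
    "simulate",
    "summarize",
    "bound_antibody_signal",
    "auc",
    "sweep",
    "relative_binding",
    "ASSAY_SCHEDULE",
    "ENDPOINT_SCHEDULE",
]


class SimulationError(RuntimeError):
    """Integration failure, carrying the solver's diagnostic message."""


@dataclass(frozen=True)
class DoseSchedule:
    """Dosing and timing of one binding experiment.

    ``doses_nM`` maps antibody name -> initial free concentration.  If
    ``washout`` is set, free antibody is reset to zero at the end of the
    association phase and the simulation continues for
    ``post_washout_duration`` seconds.
    """

    doses_nM: dict[str, float]
    association_duration: float = 7200.0  # s
    washout: bool = True
    post_washout_duration: float = 900.0  # s

    def __post_init__(self) -> None:
        if self.association_duration < 0 or self.post_washout_duration < 0:
            raise ValueError("durations must be >= 0")
        for name, dose in self.doses_nM.items():
            if dose < 0 or not math.isfinite(dose):
                raise ValueError(f"dose for {name!r} must be finite and >= 0")

    @property
    def total_duration(self) -> float:
        return self.association_duration + (
            self.post_washout_duration if self.washout else 0.0
        )


#: The experimental assay timeline: 2 h association, washout, 15 min detection.
ASSAY_SCHEDULE = dict(association_duration=7200.0, washout=True,
                      post_washout_duration=900.0)
#: The 24 h no-washout endpoint used for dose/receptor sweeps.
ENDPOINT_SCHEDULE = dict(association_duration=86400.0, washout=False)


@dataclass(frozen=True)
class SolverSettings:
    """Stiff-integrator configuration.

    Absolute tolerances are unit-aware: ``atol_nM`` for solution species and
    ``atol_per_cell`` for surface species.  ``points_per_phase`` sets the
    log-spaced dense output grid; endpoint-only integrations pass 0.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol_per_cell: float = 1e-6
    atol_nM: float = 1e-12
    points_per_phase: int = 200
    first_grid_time: float = 1e-2  # s; first log-spaced output point after 0


DEFAULT_SOLVER = SolverSettings()
FAST_SOLVER = SolverSettings(rtol=1e-6, atol_per_cell=1e-3, atol_nM=1e-9,
                             points_per_phase=0)


@dataclass
class TimeCourse:
    """A simulated trajectory: times (s) by species matrix plus metadata."""

    times: np.ndarray                 # (n_t,)
    states: np.ndarray                # (n_t, n_species)
    network: ReactionNetwork
    rates: RateConstantSet
    schedule: DoseSchedule
    ctx: UnitContext
    solver: SolverSettings

    def state_at(self, at_time: float) -> np.ndarray:
        """Linearly interpolated state at ``at_time`` (must be in range)."""
        t0, t1 = self.times[0], self.times[-1]
        if not (t0 <= at_time <= t1 * (1 + 1e-12)):
            raise ValueError(f"time {at_time} outside simulated range [{t0}, {t1}]")
        return np.array([
            np.interp(at_time, self.times, self.states[:, j])
            for j in range(self.states.shape[1])
        ])

    def series(self, species: str) -> np.ndarray:
        return self.states[:, self.network.index(species)]


def _atol_vector(network: ReactionNetwork, settings: SolverSettings) -> np.ndarray:
    return np.where(np.array(network.is_solution), settings.atol_nM,
                    settings.atol_per_cell)


def _compiled_rhs(network: ReactionNetwork, rates: RateConstantSet,
                  ctx: UnitContext):
    """Precompute index/rate arrays for the mass-action RHS and its Jacobian.

    Identical math to :func:`bsbind.kinetics.rhs`, but with the per-reaction
    lookups hoisted out of the integration loop and an analytic Jacobian so
    the stiff solver does not have to finite-difference it.
    """
    n = network.n_species
    ra = np.array([rx.reactant_a for rx in network.reactions], dtype=np.intp)
    rb = np.array([rx.reactant_b for rx in network.reactions], dtype=np.intp)
    pr = np.array([rx.product for rx in network.reactions], dtype=np.intp)
    kf = np.array([
        (rates.kon(rx.receptor) if rx.first_association else rates.kon_star(rx.receptor))
        * rx.stat_forward
        for rx in network.reactions
    ])
    kr = np.array([rates.koff(rx.receptor) * rx.stat_backward
                   for rx in network.reactions])
    dep = np.array([ctx.alpha if rx.first_association else 1.0
                    for rx in network.reactions])

    def fun(t: float, y: np.ndarray) -> np.ndarray:
        flux = kf * y[ra] * y[rb] - kr * y[pr]
        dy = np.zeros(n)
        np.add.at(dy, pr, flux)
        np.subtract.at(dy, rb, flux)
        np.subtract.at(dy, ra, dep * flux)
        return dy

    def jac(t: float, y: np.ndarray) -> np.ndarray:
        J = np.zeros((n, n))
        for k in range(len(ra)):
            a, b, p = ra[k], rb[k], pr[k]
            da = kf[k] * y[b]   # dflux/dy[a]
            db = kf[k] * y[a]   # dflux/dy[b]
            dp = -kr[k]         # dflux/dy[p]
            for col, d in ((a, da), (b, db), (p, dp)):
                J[p, col] += d
                J[b, col] -= d
                J[a, col] -= dep[k] * d
        return J

    return fun, jac


def _phase_grid(duration: float, settings: SolverSettings) -> np.ndarray | None:
    if settings.points_per_phase <= 0:
        return np.array([0.0, duration]) if duration > 0 else np.array([0.0])
    if duration <= 0:
        return np.array([0.0])
    t1 = min(settings.first_grid_time, duration / 10)
    grid = np.geomspace(t1, duration, settings.points_per_phase)
    return np.concatenate([[0.0], grid])


def _integrate_phase(y0: np.ndarray, duration: float, network: ReactionNetwork,
                     rates: RateConstantSet, ctx: UnitContext,
                     settings: SolverSettings,
                     clamp_solution: bool = False) -> tuple[np.ndarray, np.ndarray]:
    if duration <= 0:
        return np.array([0.0]), y0[None, :]
    t_eval = _phase_grid(duration, settings)
    fun, jac = _compiled_rhs(network, rates, ctx)
    if clamp_solution:
        # washed phase: the medium is a sink, so dissociated antibody is
        # removed rather than returned to the free pool
        mask = np.array(network.is_solution)

        def fun(t, y, _f=fun):
            dy = _f(t, y)
            dy[mask] = 0.0
            return dy

        def jac(t, y, _j=jac):
            J = _j(t, y)
            J[mask, :] = 0.0
            return J
    if settings.method == "LSODA":
        # odeint is the same LSODA core as solve_ivp's wrapper but with far
        # less per-step overhead, which matters inside the fitting loop
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ys, info = odeint(fun, y0, t_eval, Dfun=jac, tfirst=True,
                              rtol=settings.rtol,
                              atol=_atol_vector(network, settings),
                              full_output=True, printmessg=False, mxstep=100000)
        if info["message"] != "Integration successful.":
            raise SimulationError(f"stiff integration failed: {info['message']}")
        return t_eval, ys
    sol = solve_ivp(fun, (0.0, duration), y0, method=settings.method,
                    rtol=settings.rtol, atol=_atol_vector(network, settings),
                    t_eval=t_eval, jac=jac)
    if not sol.success:
        raise SimulationError(f"stiff integration failed: {sol.message}")
    return sol.t, sol.y.T


def simulate(
    network: ReactionNetwork,
    rates: RateConstantSet,
    schedule: DoseSchedule,
    ctx: UnitContext = DEFAULT_UNIT_CONTEXT,
    solver: SolverSettings = DEFAULT_SOLVER,
) -> TimeCourse:
    """Integrate the binding model over the schedule.

    Washout is implemented as integrate-stop-reset-reintegrate: the
    association phase ends, every solution-phase species is set to zero, and
    integration restarts for the post-washout window.
    """
    y0 = network.initial_state(schedule.doses_nM)
    t_a, y_a = _integrate_phase(y0, schedule.association_duration,
                                network, rates, ctx, solver)
    times, states = t_a, y_a
    if schedule.washout:
        y_w = y_a[-1].copy()
        y_w[np.array(network.is_solution)] = 0.0
        t_b, y_b = _integrate_phase(y_w, schedule.post_washout_duration,
                                    network, rates, ctx, solver,
                                    clamp_solution=True)
        times = np.concatenate([t_a, t_a[-1] + t_b[1:]])
        states = np.concatenate([y_a, y_b[1:]], axis=0)
    # clip tiny negative solver excursions
    states = np.maximum(states, 0.0)
    return TimeCourse(times=times, states=states, network=network, rates=rates,
                      schedule=schedule, ctx=ctx, solver=solver)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationSummary:
    """Bound-receptor and bound-antibody accounting at one time point.

    All complex quantities are receptors/cell except ``bound_antibody_signal``
    (antibodies/cell) and the dimensionless fractions.
    """

    time: float
    bound_binary: float
    bound_ternary: float
    bound_total: float
    bound_antibody_signal: float
    occupancy: dict[str, float]       # per receptor, plus "total"
    binary_occupancy: dict[str, float]
    ternary_occupancy: dict[str, float]
    free_antibody_fraction: dict[str, float]
    receptor_totals: dict[str, float] = field(default_factory=dict)


def summarize(tc: TimeCourse, at_time: float | None = None) -> SimulationSummary:
    """Compute the complex-type accounting at ``at_time`` (default: final)."""
    if at_time is None:
        at_time = float(tc.times[-1])
    y = tc.state_at(at_time)
    net = tc.network
    alpha = tc.ctx.alpha

    bound_binary = 0.0
    bound_ternary = 0.0
    signal = 0.0
    per_rec_binary = {r.name: 0.0 for r in net.receptors}
    per_rec_ternary = {r.name: 0.0 for r in net.receptors}
    for i in range(net.n_species):
        n_rec = sum(net.receptor_content[i].values())
        n_ab = sum(net.antibody_content[i].values())
        if n_ab == 0 or n_rec == 0:
            continue  # free antibody or free receptor
        signal += n_ab * y[i]
        if n_rec == 1:
            bound_binary += y[i]
        else:
            bound_ternary += n_rec * y[i]
        for rec, count in net.receptor_content[i].items():
            if n_rec == 1:
                per_rec_binary[rec] += count * y[i]
            else:
                per_rec_ternary[rec] += count * y[i]

    totals = {r.name: net.receptor_total(y, r.name) for r in net.receptors}
    grand_total = sum(totals.values())
    occupancy: dict[str, float] = {}
    binary_occ: dict[str, float] = {}
    ternary_occ: dict[str, float] = {}
    for rec, tot in totals.items():
        bound = per_rec_binary[rec] + per_rec_ternary[rec]
        occupancy[rec] = bound / tot if tot > 0 else 0.0
        binary_occ[rec] = per_rec_binary[rec] / tot if tot > 0 else 0.0
        ternary_occ[rec] = per_rec_ternary[rec] / tot if tot > 0 else 0.0
    occupancy["total"] = (bound_binary + bound_ternary) / grand_total if grand_total else 0.0
    binary_occ["total"] = bound_binary / grand_total if grand_total else 0.0
    ternary_occ["total"] = bound_ternary / grand_total if grand_total else 0.0

    free_frac: dict[str, float] = {}
    for ab in net.antibodies:
        dosed = tc.schedule.doses_nM.get(ab.name, 0.0)
        free = y[net.index(ab.name)]
        free_frac[ab.name] = free / dosed if dosed > 0 else 0.0

    return SimulationSummary(
        time=float(at_time),
        bound_binary=bound_binary,
        bound_ternary=bound_ternary,
        bound_total=bound_binary + bound_ternary,
        bound_antibody_signal=signal,
        occupancy=occupancy,
        binary_occupancy=binary_occ,
        ternary_occupancy=ternary_occ,
        free_antibody_fraction=free_frac,
        receptor_totals=totals,
    )


def bound_antibody_signal(tc: TimeCourse, at_time: float | None = None) -> float:
    """Antibodies bound per cell (MFI-comparable; scaffolds counted once)."""
    return summarize(tc, at_time).bound_antibody_signal


def _output_series(tc: TimeCourse, output_name: str) -> np.ndarray:
    """Named output as a time series over the trajectory grid."""
    net = tc.network
    values = np.zeros_like(tc.times)
    if output_name in net.species:
        return tc.series(output_name)
    for i in range(net.n_species):
        n_rec = sum(net.receptor_content[i].values())
        n_ab = sum(net.antibody_content[i].values())
        if n_ab == 0 or n_rec == 0:
            continue
        col = tc.states[:, i]
        if output_name == "bound_total":
            values = values + n_rec * col
        elif output_name == "bound_binary" and n_rec == 1:
            values = values + col
        elif output_name == "bound_ternary" and n_rec == 2:
            values = values + n_rec * col
        elif output_name == "bound_antibody_signal":
            values = values + n_ab * col
    if output_name not in {"bound_total", "bound_binary", "bound_ternary",
                           "bound_antibody_signal"} and output_name not in net.species:
        raise ValueError(f"unknown output {output_name!r}")
    return values


def auc(tc: TimeCourse, output_name: str, window: tuple[float, float] | None = None) -> float:
    """Trapezoidal integral of a named output over a time window.

    Units are the output's units times seconds.  Window endpoints inside the
    grid are handled by linear interpolation.
    """
    if window is None:
        window = (float(tc.times[0]), float(tc.times[-1]))
    t0, t1 = window
    if not (t0 < t1):
        raise ValueError(f"empty AUC window [{t0}, {t1}]")
    series = _output_series(tc, output_name)
    mask = (tc.times > t0) & (tc.times < t1)
    ts = np.concatenate([[t0], tc.times[mask], [t1]])
    vs = np.concatenate([
        [np.interp(t0, tc.times, series)],
        series[mask],
        [np.interp(t1, tc.times, series)],
    ])
    return float(np.trapezoid(vs, ts))


# ---------------------------------------------------------------------------
# Sweeps and comparisons
# ---------------------------------------------------------------------------

def _split_doses(antibodies: Sequence[AntibodySpec], total_dose: float) -> dict[str, float]:
    """Equal-nM split of a total dose across the antibodies in a combination."""
    return {ab.name: total_dose / len(antibodies) for ab in antibodies}


def sweep(
    antibodies: AntibodySpec | Sequence[AntibodySpec],
    dose_grid: Iterable[float],
    receptor_grid: Iterable[tuple[float, float]],
    rates: RateConstantSet,
    schedule_kwargs: dict | None = None,
    ctx: UnitContext = DEFAULT_UNIT_CONTEXT,
    solver: SolverSettings | None = None,
) -> pd.DataFrame:
    """Endpoint summaries over a dose x (R6, R8) expression grid.

    Each grid point runs the 24 h no-washout endpoint by default.  A list of
    antibodies is treated as a combination sharing the total dose equally
    (the 1:1 nM mixing convention).  Returns a tidy DataFrame with one row
    per grid point carrying occupancies by complex type.
    """
    from .kinetics import IL6R, IL8R, ReceptorSpecies

    if isinstance(antibodies, AntibodySpec):
        antibodies = [antibodies]
    antibodies = list(antibodies)
    sched = dict(ENDPOINT_SCHEDULE)
    if schedule_kwargs:
        sched.update(schedule_kwargs)
    if solver is None:
        solver = SolverSettings(points_per_phase=0)
    rows = []
    for r6, r8 in receptor_grid:
        receptors = []
        if r6 > 0:
            receptors.append(ReceptorSpecies(IL6R, r6))
        if r8 > 0:
            receptors.append(ReceptorSpecies(IL8R, r8))
        network = build_network(antibodies, receptors, ctx)
        for dose in dose_grid:
            schedule = DoseSchedule(doses_nM=_split_doses(antibodies, dose), **sched)
            tc = simulate(network, rates, schedule, ctx, solver)
            s = summarize(tc)
            rows.append({
                "antibody": "+".join(ab.name for ab in antibodies),
                "dose_nM": dose,
                "R6": r6,
                "R8": r8,
                "time_s": s.time,
                "bound_binary": s.bound_binary,
                "bound_ternary": s.bound_ternary,
                "bound_total": s.bound_total,
                "bound_antibody_signal": s.bound_antibody_signal,
                "occupancy_total": s.occupancy["total"],
                "binary_occupancy_total": s.binary_occupancy["total"],
                "ternary_occupancy_total": s.ternary_occupancy["total"],
                "occupancy_IL6R": s.occupancy.get(IL6R, float("nan")),
                "occupancy_IL8R": s.occupancy.get(IL8R, float("nan")),
            })
    return pd.DataFrame(rows)


def relative_binding(bsab_summary: SimulationSummary,
                     mab_combo_summary: SimulationSummary) -> dict[str, float]:
    """Fold-change in fractional occupancy, bispecific over combination.

    Zero-denominator entries are reported as NaN (undefined), not infinity.
    """
    out: dict[str, float] = {}
    for key, num in bsab_summary.occupancy.items():
        den = mab_combo_summary.occupancy.get(key)
        if den is None:
            continue
        out[key] = num / den if den > 0 else float("nan")
    return out
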