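"""Univariate sensitivity analyses of the calibrated binding model.

Local analysis: with BS1 at 10 nM on a cell expressing 5e4 IL-6R and 5e4
IL-8R per cell, each rate constant and each initial concentration is raised
10% above baseline (one at a time) and the model is run for 2 h.  The
output is the area under the curve (AUC) of the ternary-bound and the
total-bound receptor over [0, 2 h], and the sensitivity coefficient is the
percentage change in AUC divided by the percentage change in the parameter.

Global analysis: each rate constant is swept over two orders of magnitude
below and above its calibrated value, the model is run for 24 h (closer to
equilibrium) across a dose grid, and the ternary and total fractional
occupancy (of IL-6R + IL-8R) is reported per multiplier.

When a first-step on-rate is perturbed, the cycle-derived kon_8R* is by
default held at its baseline value (exactly one constant changes per
simulation); pass ``rederive_dependent=True`` to propagate the cycle
constraint through the perturbation instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kinetics import (
    DEFAULT_UNIT_CONTEXT,
    IL6R,
    IL8R,
    BS1,
    RateConstantSet,
    ReceptorSpecies,
    UnitContext,
    build_network,
    complete_rates,
)
from .protocol import DoseSchedule, SolverSettings, auc, simulate, summarize

__all__ = [
    "RATE_PARAMS",
    "CONCENTRATION_PARAMS",
    "LocalBaseline",
    "local_sensitivity",
    "global_sweep",
]

RATE_PARAMS = ("kon_6R", "kon_8R", "kon_6R_star", "kon_8R_star",
               "koff_6R", "koff_8R")
CONCENTRATION_PARAMS = ("BS1", IL6R, IL8R)

_DENSE = SolverSettings(points_per_phase=200)
_ENDPOINT = SolverSettings(points_per_phase=0)


@dataclass(frozen=True)
class LocalBaseline:
    """Reference condition for the local analysis."""

    dose_nM: float = 10.0
    R6: float = 5e4            # receptors/cell
    R8: float = 5e4
    duration: float = 7200.0   # s


def _perturb_rates(rates: RateConstantSet, name: str, factor: float,
                   rederive_dependent: bool,
                   ctx: UnitContext) -> RateConstantSet:
    if rederive_dependent and name != "kon_8R_star":
        free = {p: getattr(rates, p)
                for p in ("kon_6R", "kon_8R", "kon_6R_star", "koff_6R", "koff_8R")}
        free[name] = free[name] * factor
        return complete_rates(**free, ctx=ctx)
    return replace(rates, **{name: getattr(rates, name) * factor})


def _run_local(rates: RateConstantSet, dose: float, r6: float, r8: float,
               duration: float, ctx: UnitContext) -> tuple[float, float]:
    receptors = [ReceptorSpecies(IL6R, r6), ReceptorSpecies(IL8R, r8)]
    network = build_network(BS1, receptors, ctx)
    schedule = DoseSchedule(doses_nM={"BS1": dose},
                            association_duration=duration, washout=False)
    tc = simulate(network, rates, schedule, ctx, _DENSE)
    return (auc(tc, "bound_ternary", (0.0, duration)),
            auc(tc, "bound_total", (0.0, duration)))


def local_sensitivity(
    rates: RateConstantSet,
    baseline: LocalBaseline = LocalBaseline(),
    targets: tuple[str, ...] = RATE_PARAMS + CONCENTRATION_PARAMS,
    rel_step: float = 0.10,
    rederive_dependent: bool = False,
    ctx: UnitContext = DEFAULT_UNIT_CONTEXT,
) -> pd.DataFrame:
    """+10% one-at-a-time perturbations; %ΔAUC / %Δparameter coefficients.

    Returns a tidy frame with columns parameter, output ('ternary_auc' or
    'total_auc') and coefficient.  A zero baseline AUC yields coefficient 0
    (nothing forms, so nothing changes).
    """
    base_tern, base_total = _run_local(rates, baseline.dose_nM, baseline.R6,
                                       baseline.R8, baseline.duration, ctx)
    rows = []
    for name in targets:
        dose, r6, r8 = baseline.dose_nM, baseline.R6, baseline.R8
        prates = rates
        if name in RATE_PARAMS:
            prates = _perturb_rates(rates, name, 1.0 + rel_step,
                                    rederive_dependent, ctx)
        elif name == "BS1":
            dose = dose * (1.0 + rel_step)
        elif name == IL6R:
            r6 = r6 * (1.0 + rel_step)
        elif name == IL8R:
            r8 = r8 * (1.0 + rel_step)
        else:
            raise ValueError(f"unknown sensitivity target {name!r}")
        tern, total = _run_local(prates, dose, r6, r8, baseline.duration, ctx)
        for output, new, base in (("ternary_auc", tern, base_tern),
                                  ("total_auc", total, base_total)):
            coeff = 0.0 if base == 0 else ((new - base) / base) / rel_step
            rows.append({"parameter": name, "output": output,
                         "coefficient": coeff})
    return pd.DataFrame(rows)


def global_sweep(
    rates: RateConstantSet,
    multipliers: np.ndarray | None = None,
    doses_nM: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0),
    R6: float = 5e4,
    R8: float = 5e4,
    duration: float = 86400.0,
    params: tuple[str, ...] = RATE_PARAMS,
    rederive_dependent: bool = False,
    ctx: UnitContext = DEFAULT_UNIT_CONTEXT,
) -> pd.DataFrame:
    """Two-decade univariate sweeps of each rate constant.

    For each parameter, multiplier and dose, runs the 24 h endpoint and
    reports the ternary and total fractional occupancy of IL-6R + IL-8R.
    Tidy columns: parameter, multiplier, dose_nM, output, value.
    """
    if multipliers is None:
        multipliers = np.geomspace(1e-2, 1e2, 9)
    receptors = [ReceptorSpecies(IL6R, R6), ReceptorSpecies(IL8R, R8)]
    network = build_network(BS1, receptors, ctx)
    rows = []
    for name in params:
        for m in multipliers:
            prates = _perturb_rates(rates, name, float(m),
                                    rederive_dependent, ctx)
            for dose in doses_nM:
                schedule = DoseSchedule(doses_nM={"BS1": float(dose)},
                                        association_duration=duration,
                                        washout=False)
                tc = simulate(network, prates, schedule, ctx, _ENDPOINT)
                s = summarize(tc)
                rows.append({"parameter": name, "multiplier": float(m),
                             "dose_nM": float(dose), "output": "ternary_occupancy",
                             "value": s.ternary_occupancy["total"]})
                rows.append({"parameter": name, "multiplier": float(m),
                             "dose_nM": float(dose), "output": "total_occupancy",
                             "value": s.occupancy["total"]})
    return pd.DataFrame(rows)
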