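"""Flow-cytometry-like synthetic dose-response data from known parameters.

Emulates the structure of the cell-surface binding assay: three transduced
HEK 293T cell lines (IL-6R+, IL-8R+, IL-6R+/IL-8R+), three antibodies
(tocilizumab, 10H2, BS1), a log-spaced dose series from 1e-2 to 1e3 nM,
and three technical replicates per condition.  The generated signal is the
forward-simulated bound-antibody count at the end of the assay timeline
(2 h association, washout, 15 min detection incubation), scaled by an
arbitrary fluorescence gain and perturbed by mean-preserving multiplicative
log-normal replicate noise.  Antibody/cell-line pairs where no antibody arm
has a target receptor (10H2 on IL-6R+, tocilizumab on IL-8R+) are omitted,
leaving the seven informative condition sets.

The generator exists so calibration and normalization can be exercised
against a known ground truth; it makes no claim about the magnitude of real
cytometer noise (the coefficient of variation is a free knob).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    ANTIBODIES,
    DEFAULT_UNIT_CONTEXT,
    HEK293T_LINES,
    RateConstantSet,
    UnitContext,
    build_network,
    cell_line_receptors,
)
from .protocol import DoseSchedule, SolverSettings, bound_antibody_signal, simulate

__all__ = [
    "AssayDesign",
    "NoiseModel",
    "DEFAULT_DOSES",
    "simulate_assay",
    "generate",
]

#: The experimental dose series: 1e-2 to 1e3 nM, log-spaced.
DEFAULT_DOSES: tuple[float, ...] = tuple(np.geomspace(1e-2, 1e3, 10))

_ENDPOINT_SOLVER = SolverSettings(points_per_phase=0)


@dataclass(frozen=True)
class AssayDesign:
    """Which conditions the binding assay covers and its timeline."""

    cell_lines: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in HEK293T_LINES.items()})
    antibodies: tuple[str, ...] = ("BS1", "tocilizumab", "10H2")
    doses_nM: tuple[float, ...] = DEFAULT_DOSES
    replicates: int = 3
    association_duration: float = 7200.0
    washout: bool = True
    post_washout_duration: float = 900.0

    def conditions(self) -> list[tuple[str, str]]:
        """Feasible (cell line, antibody) pairs: at least one arm can bind."""
        pairs = []
        for line, receptors in self.cell_lines.items():
            for ab_name in self.antibodies:
                ab = ANTIBODIES[ab_name]
                if any(t in receptors for t in ab.arm_targets):
                    pairs.append((line, ab_name))
        return pairs

    def schedule(self, antibody: str, dose_nM: float) -> DoseSchedule:
        return DoseSchedule(
            doses_nM={antibody: dose_nM},
            association_duration=self.association_duration,
            washout=self.washout,
            post_washout_duration=self.post_washout_duration,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise: mean-preserving multiplicative log-normal.

    ``cv`` is the coefficient of variation of the multiplicative factor
    (fluorescence intensities are positive and roughly scale-proportional);
    ``background`` is an optional additive offset in signal units.
    """

    cv: float = 0.05
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    def apply(self, signal: float, rng: np.random.Generator, n: int) -> np.ndarray:
        values = np.full(n, float(signal))
        if self.cv > 0:
            sigma = np.sqrt(np.log1p(self.cv ** 2))
            values = values * rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=n)
        return values + self.background


def simulate_assay(
    rates: RateConstantSet,
    design: AssayDesign | None = None,
    ctx: UnitContext = DEFAULT_UNIT_CONTEXT,
    solver: SolverSettings = _ENDPOINT_SOLVER,
) -> pd.DataFrame:
    """Noiseless assay signals: one row per (cell_line, antibody, dose_nM).

    The signal is the bound-antibody count per cell (the MFI-comparable
    output) at the final time of the assay schedule.
    """
    design = design or AssayDesign()
    rows = []
    for line, ab_name in design.conditions():
        network = build_network(ANTIBODIES[ab_name],
                                cell_line_receptors(design.cell_lines[line]), ctx)
        for dose in design.doses_nM:
            tc = simulate(network, rates, design.schedule(ab_name, dose), ctx, solver)
            rows.append({"cell_line": line, "antibody": ab_name,
                         "dose_nM": float(dose),
                         "signal": bound_antibody_signal(tc)})
    return pd.DataFrame(rows)


def generate(
    truth: RateConstantSet,
    design: AssayDesign | None = None,
    noise: NoiseModel | None = None,
    gain: float = 1.0,
    seed: int | np.random.Generator = 0,
    ctx: UnitContext = DEFAULT_UNIT_CONTEXT,
    solver: SolverSettings = _ENDPOINT_SOLVER,
) -> tuple[pd.DataFrame, dict]:
    """Raw synthetic dataset plus a provenance sidecar.

    Returns ``(frame, meta)`` where ``frame`` has columns cell_line,
    antibody, dose_nM, replicate, signal, and ``meta`` records the
    generating parameters, design, gain and seed for recovery tests.
    """
    design = design or AssayDesign()
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = simulate_assay(truth, design, ctx, solver)
    rows = []
    for _, row in base.iterrows():
        values = noise.apply(row["signal"] * gain, rng, design.replicates)
        for rep, value in enumerate(values, start=1):
            rows.append({"cell_line": row["cell_line"], "antibody": row["antibody"],
                         "dose_nM": row["dose_nM"], "replicate": rep,
                         "signal": float(value)})
    frame = pd.DataFrame(rows)
    meta = {
        "truth": truth.as_dict(),
        "design": {
            "cell_lines": design.cell_lines,
            "antibodies": list(design.antibodies),
            "doses_nM": [float(d) for d in design.doses_nM],
            "replicates": design.replicates,
            "association_duration": design.association_duration,
            "washout": design.washout,
            "post_washout_duration": design.post_washout_duration,
        },
        "noise": {"cv": noise.cv, "background": noise.background},
        "gain": gain,
        "seed": None if isinstance(seed, np.random.Generator) else int(seed),
        "unit_context": {"cells_per_well": ctx.cells_per_well,
                         "well_volume": ctx.well_volume},
    }
    return frame, meta
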