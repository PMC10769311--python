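"""Calibration of the five free rate constants against dose-response data.

The assay readout (MFI) is in arbitrary fluorescence units, so both the
data and the model output are normalized before comparison.  The data are
divided, per cell line, by the mean BS1 signal at the doses where BS1
binding saturates; the simulated signals can be normalized by one of four
schemes (reference: BS1 or each antibody individually; denominator taken at
the data's saturation doses or at the maximum dose).  The cost is the plain
sum of squared differences between normalized simulation and every
normalized replicate row.

Optimization runs in log10 parameter space (the five parameters span ~9
decades) with box bounds, from Latin-hypercube initial guesses drawn
log-uniformly.  Runs that fail to converge or that never move from their
guess are discarded; the lowest-cost surviving run is the best fit, and the
per-parameter standard deviation of the log10 optima measures how well the
data constrain each parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .kinetics import (
    ANTIBODIES,
    DEFAULT_UNIT_CONTEXT,
    FREE_PARAM_NAMES,
    RateConstantSet,
    UnitContext,
    build_network,
    cell_line_receptors,
    complete_rates,
)
from .protocol import SimulationError, SolverSettings, bound_antibody_signal, simulate
from .synthetic import AssayDesign

__all__ = [
    "DATA_COLUMNS",
    "DEFAULT_GUESS_RANGES",
    "DEFAULT_BOUNDS",
    "NormalizationScheme",
    "DoseResponseDataset",
    "OptimizationRun",
    "OptimizationEnsemble",
    "default_saturation_doses",
    "normalize_data",
    "normalize_simulation",
    "AssayProblem",
    "cost",
    "lhs_guesses",
    "fit_multistart",
    "filter_runs",
    "select_best",
]

logger = logging.getLogger(__name__)

DATA_COLUMNS = ("cell_line", "antibody", "dose_nM", "replicate", "signal")

#: Log-uniform initial-guess ranges per free parameter.
DEFAULT_GUESS_RANGES: dict[str, tuple[float, float]] = {
    "kon_6R": (1e-9, 1e-2),
    "kon_8R": (1e-9, 1e-2),
    "kon_6R_star": (1e-13, 1e-5),
    "koff_6R": (1e-10, 1e-7),
    "koff_8R": (1e-7, 1e-2),
}

#: Box bounds for the optimizer per free parameter.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "kon_6R": (1e-11, 1.0),
    "kon_8R": (1e-11, 1.0),
    "kon_6R_star": (1e-15, 1e-3),
    "koff_6R": (1e-9, 1.0),
    "koff_8R": (1e-9, 1.0),
}

#: Movement threshold (log10 units) below which a run "did not vary".
MOVEMENT_TOL = 1e-3

_FIT_SOLVER = SolverSettings(rtol=1e-6, atol_per_cell=1e-3, atol_nM=1e-9,
                             points_per_phase=0)


@dataclass(frozen=True)
class NormalizationScheme:
    """One of the four (reference, denominator concentration) combinations."""

    reference: str = "BS1"        # "BS1" or "antibody"
    concentrations: str = "data"  # "data" (saturation doses) or "max"

    def __post_init__(self) -> None:
        if self.reference not in ("BS1", "antibody"):
            raise ValueError(f"reference must be 'BS1' or 'antibody', got {self.reference!r}")
        if self.concentrations not in ("data", "max"):
            raise ValueError(f"concentrations must be 'data' or 'max', got {self.concentrations!r}")


@dataclass
class DoseResponseDataset:
    """Tabular assay data with a raw/normalized flag.

    ``frame`` has columns cell_line, antibody, dose_nM, replicate, signal;
    ``denominators`` records the per-cell-line normalization constant once
    normalized.
    """

    frame: pd.DataFrame
    normalized: bool = False
    denominators: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in DATA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")

    @classmethod
    def from_csv(cls, path) -> "DoseResponseDataset":
        frame = pd.read_csv(path)
        missing = [c for c in DATA_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        bad = frame[~np.isfinite(frame["dose_nM"]) | (frame["dose_nM"] <= 0)]
        if len(bad):
            raise ValueError(f"{path}: non-positive dose_nM in row(s) {list(bad.index)}")
        return cls(frame=frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def default_saturation_doses(doses, n: int = 2) -> list[float]:
    """Top-``n`` doses of a series, the default 'binding reached saturation' set."""
    return sorted(set(float(d) for d in doses))[-n:]


def _as_frame(data) -> pd.DataFrame:
    return data.frame if isinstance(data, DoseResponseDataset) else data


def normalize_data(
    data: DoseResponseDataset | pd.DataFrame,
    saturation_doses: dict[str, list[float]] | list[float] | None = None,
) -> DoseResponseDataset:
    """Divide every row by its cell line's mean BS1 signal at saturation.

    ``saturation_doses`` may be one list applied to all cell lines, or a
    per-cell-line mapping; by default the top two doses present for BS1 in
    that cell line are used.
    """
    frame = _as_frame(data).copy()
    denominators: dict[str, float] = {}
    for line, group in frame.groupby("cell_line"):
        bs1 = group[group["antibody"] == "BS1"]
        if bs1.empty:
            raise ValueError(f"no BS1 rows for cell line {line!r}; cannot normalize")
        if saturation_doses is None:
            doses = default_saturation_doses(bs1["dose_nM"])
        elif isinstance(saturation_doses, dict):
            doses = list(saturation_doses[line])
        else:
            doses = list(saturation_doses)
        ref = bs1[bs1["dose_nM"].isin(doses)]
        if ref.empty:
            raise ValueError(
                f"no BS1 rows at saturation doses {doses} for cell line {line!r}")
        denominators[line] = float(ref["signal"].mean())
    frame["signal"] = frame.apply(
        lambda row: row["signal"] / denominators[row["cell_line"]], axis=1)
    return DoseResponseDataset(frame=frame, normalized=True, denominators=denominators)


def normalize_simulation(
    signals: pd.DataFrame,
    scheme: NormalizationScheme,
    saturation_doses: dict[str, list[float]] | list[float],
) -> pd.DataFrame:
    """Apply a scheme-specific denominator to simulated signals, per cell line.

    ``signals`` has columns cell_line, antibody, dose_nM, signal.  The
    denominator is the mean simulated signal of the reference antibody (BS1
    or each antibody itself) at the saturation doses ("data") or at the
    maximum dose ("max").
    """
    out = signals.copy()
    out["signal"] = out["signal"].astype(float)
    for line, group in out.groupby("cell_line"):
        if isinstance(saturation_doses, dict):
            doses = list(saturation_doses[line])
        else:
            doses = list(saturation_doses)
        if scheme.reference == "BS1":
            ref_ab_list = ["BS1"]
        else:
            ref_ab_list = group["antibody"].unique().tolist()
        for ref_ab in ref_ab_list:
            ref_rows = group[group["antibody"] == ref_ab]
            if ref_rows.empty:
                raise ValueError(f"no {ref_ab!r} simulation for cell line {line!r}")
            if scheme.concentrations == "max":
                sel = ref_rows[ref_rows["dose_nM"] == ref_rows["dose_nM"].max()]
            else:
                sel = ref_rows[ref_rows["dose_nM"].isin(doses)]
                if sel.empty:
                    raise ValueError(
                        f"simulation lacks saturation doses {doses} for "
                        f"{ref_ab!r} on {line!r}")
            denom = float(sel["signal"].mean())
            if denom <= 0:
                raise ValueError(f"non-positive normalization denominator for "
                                 f"{ref_ab!r} on {line!r}")
            if scheme.reference == "BS1":
                mask = out["cell_line"] == line
            else:
                mask = (out["cell_line"] == line) & (out["antibody"] == ref_ab)
            out.loc[mask, "signal"] = out.loc[mask, "signal"] / denom
    return out


# ---------------------------------------------------------------------------
# Cost
# ---------------------------------------------------------------------------

class AssayProblem:
    """Pre-assembled least-squares problem for one normalized dataset.

    Builds the reaction network for every (cell line, antibody) pair once
    and reuses it for each cost evaluation; a residual evaluation simulates
    the assay timeline at every dose present in the data and compares the
    scheme-normalized bound-antibody signal to each replicate row.
    """

    PENALTY = 1e3  # residual magnitude assigned to failed simulations

    def __init__(
        self,
        data: DoseResponseDataset,
        design: AssayDesign | None = None,
        scheme: NormalizationScheme = NormalizationScheme(),
        saturation_doses: dict[str, list[float]] | list[float] | None = None,
        ctx: UnitContext = DEFAULT_UNIT_CONTEXT,
        solver: SolverSettings = _FIT_SOLVER,
    ) -> None:
        if not data.normalized:
            raise ValueError("fit data must be normalized first (normalize_data)")
        self.data = data
        self.design = design or AssayDesign()
        self.scheme = scheme
        self.ctx = ctx
        self.solver = solver
        frame = data.frame
        if saturation_doses is None:
            saturation_doses = {
                line: default_saturation_doses(
                    frame[(frame["cell_line"] == line) & (frame["antibody"] == "BS1")]["dose_nM"])
                for line in frame["cell_line"].unique()
            }
        self.saturation_doses = saturation_doses
        self.conditions = (
            frame[["cell_line", "antibody", "dose_nM"]]
            .drop_duplicates().reset_index(drop=True)
        )
        self._networks = {}
        for line in frame["cell_line"].unique():
            receptors = cell_line_receptors(self.design.cell_lines[line])
            for ab in frame[frame["cell_line"] == line]["antibody"].unique():
                self._networks[(line, ab)] = build_network(ANTIBODIES[ab], receptors, ctx)
        # align data rows to conditions for fast residuals
        key = ["cell_line", "antibody", "dose_nM"]
        self._row_cond = frame.merge(
            self.conditions.reset_index(names="cond_idx"), on=key, how="left"
        )["cond_idx"].to_numpy()
        self._row_signal = frame["signal"].to_numpy(dtype=float)

    def simulate_signals(self, rates: RateConstantSet) -> pd.DataFrame:
        """Raw simulated signal per condition in the data."""
        signals = np.empty(len(self.conditions))
        for i, cond in self.conditions.iterrows():
            network = self._networks[(cond["cell_line"], cond["antibody"])]
            schedule = self.design.schedule(cond["antibody"], cond["dose_nM"])
            try:
                tc = simulate(network, rates, schedule, self.ctx, self.solver)
                signals[i] = bound_antibody_signal(tc)
            except SimulationError as exc:
                logger.warning("simulation failed at %s: %s", tuple(cond), exc)
                signals[i] = np.nan
        out = self.conditions.copy()
        out["signal"] = signals
        return out

    def residuals(self, log10_params: np.ndarray) -> np.ndarray:
        rates = complete_rates(*(10.0 ** np.asarray(log10_params, dtype=float)),
                               ctx=self.ctx)
        sim = self.simulate_signals(rates)
        failed = ~np.isfinite(sim["signal"].to_numpy())
        if failed.any():
            res = np.full(len(self._row_signal), self.PENALTY)
            ok = ~failed[self._row_cond]
            if ok.any():
                sim_ok = sim.copy()
                sim_ok.loc[failed, "signal"] = 0.0
                norm = normalize_simulation(sim_ok, self.scheme, self.saturation_doses)
                res[ok] = (norm["signal"].to_numpy()[self._row_cond][ok]
                           - self._row_signal[ok])
            return res
        norm = normalize_simulation(sim, self.scheme, self.saturation_doses)
        return norm["signal"].to_numpy()[self._row_cond] - self._row_signal

    def cost(self, log10_params: np.ndarray) -> float:
        """Sum of squared normalized residuals over every replicate row."""
        r = self.residuals(log10_params)
        return float(np.dot(r, r))


def cost(
    log10_params: np.ndarray,
    data: DoseResponseDataset,
    design: AssayDesign | None = None,
    scheme: NormalizationScheme = NormalizationScheme(),
    **kwargs,
) -> float:
    """Convenience wrapper: assemble an :class:`AssayProblem` and evaluate."""
    return AssayProblem(data, design, scheme, **kwargs).cost(log10_params)


# ---------------------------------------------------------------------------
# Multi-start optimization
# ---------------------------------------------------------------------------

def lhs_guesses(
    n: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Latin-hypercube initial guesses, log-uniform per parameter.

    Returns an (n, 5) array of log10 values ordered as
    (kon_6R, kon_8R, kon_6R_star, koff_6R, koff_8R); each parameter is
    stratified into ``n`` equal log10 bins with exactly one sample per bin.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or DEFAULT_GUESS_RANGES
    lo = np.log10([ranges[p][0] for p in FREE_PARAM_NAMES])
    hi = np.log10([ranges[p][1] for p in FREE_PARAM_NAMES])
    if np.any(lo >= hi):
        raise ValueError("each range must satisfy lo < hi")
    sampler = qmc.LatinHypercube(d=len(FREE_PARAM_NAMES), seed=seed)
    unit = sampler.random(n)
    return lo + unit * (hi - lo)


@dataclass
class OptimizationRun:
    """One local least-squares solve from one initial guess."""

    initial_guess: np.ndarray  # log10, shape (5,)
    fitted: np.ndarray         # log10, shape (5,)
    cost: float
    converged: bool
    moved: bool
    nfev: int = 0
    message: str = ""


@dataclass
class OptimizationEnsemble:
    """All multi-start runs plus the kept/discarded partition."""

    runs: list[OptimizationRun]
    kept: list[OptimizationRun] = field(default_factory=list)
    discarded: list[OptimizationRun] = field(default_factory=list)

    @property
    def best(self) -> OptimizationRun:
        pool = self.kept if self.kept else [r for r in self.runs if r.converged]
        if not pool:
            raise ValueError("no usable optimization runs")
        return min(pool, key=lambda r: r.cost)

    @property
    def discard_fraction(self) -> float:
        if not (self.kept or self.discarded):
            return 0.0
        return len(self.discarded) / (len(self.kept) + len(self.discarded))


def fit_multistart(
    data: DoseResponseDataset,
    n_starts: int = 300,
    ranges: dict[str, tuple[float, float]] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    scheme: NormalizationScheme = NormalizationScheme(),
    seed: int | np.random.Generator = 0,
    design: AssayDesign | None = None,
    max_nfev: int | None = 80,
    tol: float = 1e-8,
    **problem_kwargs,
) -> OptimizationEnsemble:
    """Bounded nonlinear least squares from Latin-hypercube starts.

    Each start runs a trust-region-reflective solve in log10 space within
    the box ``bounds``.  The returned ensemble is unfiltered; apply
    :func:`filter_runs` before :func:`select_best`.
    """
    bounds = bounds or DEFAULT_BOUNDS
    problem = AssayProblem(data, design, scheme, **problem_kwargs)
    guesses = lhs_guesses(n_starts, ranges, seed)
    lo = np.log10([bounds[p][0] for p in FREE_PARAM_NAMES])
    hi = np.log10([bounds[p][1] for p in FREE_PARAM_NAMES])
    runs: list[OptimizationRun] = []
    for x0 in guesses:
        x0c = np.clip(x0, lo, hi)
        try:
            res = least_squares(problem.residuals, x0c, bounds=(lo, hi),
                                method="trf", ftol=tol, xtol=tol, gtol=tol,
                                max_nfev=max_nfev)
            run = OptimizationRun(
                initial_guess=x0c,
                fitted=res.x,
                cost=float(np.dot(res.fun, res.fun)),
                converged=bool(res.success),
                moved=bool(np.max(np.abs(res.x - x0c)) > MOVEMENT_TOL),
                nfev=int(res.nfev),
                message=str(res.message),
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("optimization start failed: %s", exc)
            run = OptimizationRun(initial_guess=x0c, fitted=x0c,
                                  cost=float("inf"), converged=False,
                                  moved=False, message=str(exc))
        runs.append(run)
    if all(not r.converged for r in runs):
        raise RuntimeError("every optimization start failed to converge")
    return OptimizationEnsemble(runs=runs)


def filter_runs(ensemble: OptimizationEnsemble) -> OptimizationEnsemble:
    """Partition runs: discard non-converged runs and runs that never moved."""
    kept, discarded = [], []
    for run in ensemble.runs:
        if run.converged and run.moved:
            kept.append(run)
        else:
            discarded.append(run)
    if not kept:
        raise RuntimeError("all optimization runs were discarded")
    ensemble.kept = kept
    ensemble.discarded = discarded
    logger.info("kept %d/%d runs (%.0f%% discarded)", len(kept), len(ensemble.runs),
                100 * ensemble.discard_fraction)
    return ensemble


def select_best(ensemble: OptimizationEnsemble) -> dict:
    """Best kept run, log10 dispersion per parameter, and histogram groups.

    The standard deviation of the log10 optima across kept runs is the
    per-parameter spread analogue used to judge identifiability; with a
    single kept run it is reported as NaN.  Histogram groups collect runs
    whose (rounded) fitted vector and cost coincide, with a multiplicity.
    """
    best = ensemble.best
    fitted = np.array([r.fitted for r in ensemble.kept])
    if len(fitted) > 1:
        sd = fitted.std(axis=0, ddof=1)
    else:
        sd = np.full(fitted.shape[1], np.nan)
    groups = pd.DataFrame({
        **{p: np.round(fitted[:, i], 3) for i, p in enumerate(FREE_PARAM_NAMES)},
        "cost": np.round([r.cost for r in ensemble.kept], 6),
    }).value_counts().reset_index(name="multiplicity")
    return {
        "best": best,
        "best_params_log10": dict(zip(FREE_PARAM_NAMES, best.fitted)),
        "best_params": dict(zip(FREE_PARAM_NAMES, 10.0 ** best.fitted)),
        "sd_log10": dict(zip(FREE_PARAM_NAMES, sd)),
        "histogram": groups,
        "discard_fraction": ensemble.discard_fraction,
    }
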