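"""Shared fixtures and independent oracles for the binding-model tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

import bsbind as b


@pytest.fixture(scope="session")
def rates():
    """Calibrated reference rate constants."""
    return b.REFERENCE_RATES


@pytest.fixture(scope="session")
def ctx():
    return b.DEFAULT_UNIT_CONTEXT


@pytest.fixture(scope="session")
def bs1_network(ctx):
    return b.build_network(b.BS1, "IL6R+IL8R+", ctx)


@pytest.fixture(scope="session")
def small_design():
    """Assay design with a reduced dose series to keep fits affordable."""
    return b.AssayDesign(doses_nM=tuple(np.geomspace(1e-2, 1e3, 6)))


@pytest.fixture(scope="session")
def noiseless_data(small_design):
    """Noiseless synthetic dataset generated at the reference parameters."""
    raw, meta = b.generate(b.REFERENCE_RATES, small_design,
                           b.NoiseModel(cv=0.0), seed=11)
    return b.normalize_data(b.DoseResponseDataset(raw)), meta


def equilibrium_bs1(rates, ctx, dose_nM: float, R6: float, R8: float) -> dict:
    """Algebraic steady state of BS1 on a double-positive cell, solved
    independently of the ODE path.

    Mass-action equilibrium gives closed forms for the complexes given the
    free species; the free receptors are eliminated by fixed-point
    substitution at fixed free antibody, and the free antibody is bracketed
    on [0, dose] via its conservation equation.
    """
    alpha = ctx.alpha
    K6 = rates.kon_6R / rates.koff_6R          # nM^-1
    K8 = rates.kon_8R / rates.koff_8R
    Ks8 = rates.kon_8R_star / rates.koff_8R    # (#/cell)^-1

    def free_receptors(a: float) -> tuple[float, float]:
        r6, r8 = R6, R8
        for _ in range(500):
            r6_new = R6 / (1 + K6 * a + Ks8 * K6 * a * r8)
            r8_new = R8 / (1 + K8 * a + Ks8 * K6 * a * r6_new)
            if abs(r6_new - r6) < 1e-12 * R6 and abs(r8_new - r8) < 1e-12 * R8:
                r6, r8 = r6_new, r8_new
                break
            r6, r8 = r6_new, r8_new
        return r6, r8

    def antibody_balance(a: float) -> float:
        r6, r8 = free_receptors(a)
        B6 = K6 * a * r6
        B8 = K8 * a * r8
        T = Ks8 * B6 * r8
        return a + alpha * (B6 + B8 + T) - dose_nM

    a = brentq(antibody_balance, 0.0, dose_nM, xtol=1e-300, rtol=1e-14)
    r6, r8 = free_receptors(a)
    B6 = K6 * a * r6
    B8 = K8 * a * r8
    T = Ks8 * B6 * r8
    return {"Ab": a, "R6": r6, "R8": r8, "B6": B6, "B8": B8, "T": T,
            "bound_total": B6 + B8 + 2 * T}
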