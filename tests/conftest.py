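"""Shared fixtures and independent oracles.

The oracles deliberately take a different computational route from the
library code they check: the state-curve oracle solves the absolute-units
flux balance numerically instead of using the normalized closed form, and
the regression oracle solves the normal equations directly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.optimize import brentq

from oxycap.state_curve import ModelParams
from oxycap.transport_core import (
    ArterialInput,
    HemoglobinParams,
    calibrate_baseline,
    mean_capillary_po2,
)


@pytest.fixture
def hb() -> HemoglobinParams:
    return HemoglobinParams()


@pytest.fixture
def arterial() -> ArterialInput:
    return ArterialInput()


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


def cbf_prime_oracle(j_prime: float, params: ModelParams, cbf_o: float = 50.0) -> float:
    """Absolute-units route to the above-baseline state curve.

    Calibrates a baseline in physical units, fixes the diffusivity at its
    awake value, and solves the flux balance J = D_o * (PO2_cap(OEF) -
    PO2_tissue) for the absolute flow, then normalizes.  Valid for
    j_prime >= 1 (the fixed-diffusivity branch).
    """
    art = ArterialInput(po2_a=params.po2_a)
    base = calibrate_baseline(
        params.oef_o, cbf_o, art, params.po2_t_base, params.hb
    )
    j_abs = j_prime * base.j_o
    o2 = art.o2_content

    def imbalance(cbf: float) -> float:
        oef = j_abs / (cbf * o2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            po2c = mean_capillary_po2(oef, params.hb)
        return base.d_o * (po2c - params.po2_t_act) - j_abs

    lo = j_abs / (o2 * 1.999)  # OEF -> 2: capillary PO2 -> 0, flux deficit
    hi = max(10.0 * cbf_o, 4.0 * lo)
    for _ in range(200):
        if imbalance(hi) > 0:
            break
        hi *= 2.0
    cbf = brentq(imbalance, lo, hi, xtol=1e-12, rtol=1e-15, maxiter=500)
    return cbf / cbf_o


def ols_oracle(x, y, through_origin: bool = False):
    """Normal-equations least squares: returns (slope, intercept, r2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
        resid = y - slope * x
        r2 = 1.0 - float(resid @ resid) / float(y @ y)
    else:
        design = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept, slope = float(coef[0]), float(coef[1])
        resid = y - (intercept + slope * x)
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss
    return slope, intercept, r2


def random_valid_draws(rng: np.random.Generator, n: int):
    """Random (oef_o, p50, h, po2t) tuples with a positive baseline gradient."""
    draws = []
    while len(draws) < n:
        oef = rng.uniform(0.25, 0.75)
        p50 = rng.uniform(20.0, 35.0)
        h = rng.uniform(2.0, 3.5)
        hb = HemoglobinParams(p50=p50, h=h)
        po2c = mean_capillary_po2(oef, hb)
        po2t = rng.uniform(5.0, 0.9 * po2c)
        draws.append((oef, hb, po2t))
    return draws
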