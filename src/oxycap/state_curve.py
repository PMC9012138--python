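"""Normalized flow-metabolism curve across brain states.

Everything here is expressed relative to the undisturbed awake baseline:
``J' = J / J_o`` (normalized oxygen use, equal to rCMRO2/rCMRO2_o) and
``CBF' = CBF / CBF_o`` (normalized flow).  Above baseline the effective
capillary diffusivity stays pinned at its awake value ``D_o`` while tissue
PO2 is held homeostatically constant, so extra oxygen delivery can only
come from raising the mean capillary tension -- which demands a
disproportionate rise in flow:

    CBF' = (OEF_o * J' / 2) * (1 + [(J' * (J_o/D_o) + PO2^T_act) / P50]^h)

with ``J_o/D_o = P50 * (2/OEF_o - 1)**(1/h) - PO2^T_base`` fixed by the
baseline calibration.  Below baseline, diffusivity falls in proportion to
flow (``D = D_o * CBF'``), whose unique steady state is the identity
``CBF' = J'``.  The forward map is strictly increasing, so the inverse is
obtained by bracketed root finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, NumericalError, UsageError
from .transport_core import (
    DEFAULT_PO2_A,
    HemoglobinParams,
    mean_capillary_po2,
)

__all__ = [
    "ModelParams",
    "CurvePoint",
    "cbf_prime_from_j_prime",
    "j_prime_from_cbf_prime",
    "j_prime_max",
    "normalized_flux_ceiling",
    "curve",
    "curve_family",
    "default_j_grid",
]

#: Default tissue oxygen tension (torr) of the undisturbed awake state.
DEFAULT_PO2_T = 27.0
#: Normalized flow ceiling: regional CBF does not exceed twice baseline
#: outside of pathological states.
DEFAULT_CBF_PRIME_MAX = 2.0

_ROOT_XTOL = 1e-12
_ROOT_MAXITER = 200


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the normalized supply-limited model.

    ``po2_t_base`` is the tissue tension at which ``D_o`` is calibrated;
    ``po2_t_act`` is the tissue tension prevailing above baseline (defaults
    to ``po2_t_base``, i.e. strict PO2 homeostasis).  Setting
    ``po2_t_act < po2_t_base`` models a lowered tissue-tension operating
    point while keeping the baseline calibration unchanged.
    """

    oef_o: float = 0.40
    hb: HemoglobinParams = field(default_factory=HemoglobinParams)
    po2_t_base: float = DEFAULT_PO2_T
    po2_t_act: float | None = None
    cbf_prime_max: float = DEFAULT_CBF_PRIME_MAX
    po2_a: float = DEFAULT_PO2_A

    def __post_init__(self) -> None:
        if not 0 < self.oef_o < 1:
            raise DomainError(f"OEF_o must lie in (0, 1), got {self.oef_o}")
        if self.po2_t_act is None:
            object.__setattr__(self, "po2_t_act", self.po2_t_base)
        if self.cbf_prime_max < 1:
            raise DomainError(
                f"flow ceiling must be >= 1 (baseline), got {self.cbf_prime_max}"
            )
        po2c_o = mean_capillary_po2(self.oef_o, self.hb)
        if self.po2_t_base >= po2c_o:
            raise DomainError(
                f"baseline tissue PO2 {self.po2_t_base} torr >= mean capillary "
                f"PO2 {po2c_o:.3f} torr: no positive baseline gradient"
            )
        if self.po2_t_act > po2c_o:
            raise DomainError(
                f"activated tissue PO2 {self.po2_t_act} torr exceeds the baseline "
                f"mean capillary PO2 {po2c_o:.3f} torr"
            )

    @property
    def jo_over_do(self) -> float:
        """Baseline flux-to-diffusivity ratio ``J_o/D_o`` (torr)."""
        return mean_capillary_po2(self.oef_o, self.hb) - self.po2_t_base


@dataclass(frozen=True)
class CurvePoint:
    """One point of the normalized state curve: (J', CBF', OEF)."""

    j_prime: float
    cbf_prime: float
    oef: float


def cbf_prime_from_j_prime(j_prime: float, params: ModelParams) -> float:
    """Normalized flow required to sustain normalized oxygen use ``j_prime``.

    Above baseline the closed-form supply curve applies; below baseline the
    proportional-diffusivity branch reduces to the identity ``CBF' = J'``
    (its unique fixed point).  At ``j_prime == 1`` with unchanged tissue
    tension the result is exactly 1 by construction.
    """
    if j_prime <= 0:
        raise DomainError(f"J' must be positive, got {j_prime}")
    if j_prime < 1:
        return j_prime
    if j_prime == 1 and params.po2_t_act == params.po2_t_base:
        return 1.0
    hb = params.hb
    gradient_term = (j_prime * params.jo_over_do + params.po2_t_act) / hb.p50
    return (params.oef_o * j_prime / 2.0) * (1.0 + gradient_term**hb.h)


def j_prime_from_cbf_prime(cbf_prime: float, params: ModelParams) -> float:
    """Numerical inverse of the forward map: oxygen use sustainable at a flow.

    For ``cbf_prime <= 1`` the below-baseline identity applies.  Above 1,
    the strictly increasing forward map is bracketed (upper bound grown
    geometrically from J' = 1) and solved by Brent's method.
    """
    if cbf_prime <= 0:
        raise DomainError(f"CBF' must be positive, got {cbf_prime}")
    if cbf_prime <= 1:
        return cbf_prime

    def residual(j: float) -> float:
        return cbf_prime_from_j_prime(j, params) - cbf_prime

    lo, hi = 1.0, 2.0
    for _ in range(64):
        if residual(hi) >= 0:
            break
        lo, hi = hi, hi * 2.0
    else:
        raise NumericalError(
            f"could not bracket CBF' = {cbf_prime} within J' in [1, {hi:g}]"
        )
    j = brentq(residual, lo, hi, xtol=_ROOT_XTOL, maxiter=_ROOT_MAXITER)
    if abs(residual(j)) > 1e-10:
        raise NumericalError(
            f"inverse solve residual {residual(j):.3g} exceeds tolerance "
            f"on [{lo:g}, {hi:g}]"
        )
    return j


def normalized_flux_ceiling(params: ModelParams) -> float:
    """Hard delivery ceiling ``J'_ceiling = (PO2^A - PO2^T_act) / (J_o/D_o)``.

    Capillary tension can never exceed arterial tension, so no flow
    increase can push ``J'`` past this value.
    """
    gradient = params.po2_a - params.po2_t_act
    if gradient <= 0:
        raise DomainError(
            f"arterial PO2 {params.po2_a} torr <= tissue PO2 "
            f"{params.po2_t_act} torr: no positive ceiling"
        )
    return gradient / params.jo_over_do


def j_prime_max(params: ModelParams) -> float:
    """Maximal sustainable ``J'`` at the model's normalized flow ceiling.

    Always strictly below the absolute capillary-to-arterial ceiling of
    :func:`normalized_flux_ceiling`.
    """
    return j_prime_from_cbf_prime(params.cbf_prime_max, params)


def default_j_grid(start: float = 0.4, stop: float = 1.8, step: float = 0.01) -> np.ndarray:
    """Default normalized-metabolism grid for curve tabulation."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def curve(params: ModelParams, j_grid: Sequence[float] | None = None) -> list[CurvePoint]:
    """Tabulate the state curve, attaching ``OEF = OEF_o * J' / CBF'``."""
    grid = default_j_grid() if j_grid is None else np.asarray(list(j_grid), dtype=float)
    if grid.size == 0:
        raise UsageError("empty J' grid")
    if np.any(grid <= 0):
        raise DomainError("J' grid values must be positive")
    if np.any(np.diff(grid) < 0):
        raise UsageError("J' grid must be sorted ascending")
    points = []
    for j in grid:
        cbf = cbf_prime_from_j_prime(float(j), params)
        points.append(CurvePoint(float(j), cbf, params.oef_o * float(j) / cbf))
    return points


def curve_family(
    base: ModelParams,
    sweep_param: str,
    values: Iterable[float],
    j_grid: Sequence[float] | None = None,
) -> dict[float, list[CurvePoint]]:
    """Family of state curves over a one-parameter sweep.

    ``sweep_param`` is either ``"oef_o"`` (each curve re-based so it passes
    through (1, 1): baseline tissue tension fixed, diffusivity recalibrated
    per extraction fraction) or ``"po2_t_act"`` (baseline calibration held
    at ``po2_t_base``; only the operating tissue tension moves, so curves
    with lower tension lie below -- less flow per unit flux).
    """
    if sweep_param not in ("oef_o", "po2_t_act"):
        raise UsageError(
            f"sweep parameter must be 'oef_o' or 'po2_t_act', got {sweep_param!r}"
        )
    family: dict[float, list[CurvePoint]] = {}
    for value in values:
        params = replace(base, **{sweep_param: float(value)})
        family[float(value)] = curve(params, j_grid)
    return family
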