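"""Hemoglobin Hill kinetics and lumped Krogh capillary oxygen-flux algebra.

The model treats a tissue volume as a bed of parallel capillaries.  Net
oxygen flux from capillary to tissue is driven by the gradient between the
mean capillary oxygen tension (obtained by inverting the Hill saturation
curve at the mean capillary saturation ``1 - OEF/2``) and the mean tissue
tension, scaled by an effective diffusivity ``D`` proportional to capillary
length density.  Baseline calibration fixes ``D_o`` so that the flux equals
the measured baseline oxygen consumption ``J_o = OEF_o * CBF_o * [O2^A]``.

Units: blood flow in ml.100g-1.min-1, oxygen rates in umol.100g-1.min-1,
tensions in torr, arterial oxygen content in umol per ml blood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import CalibrationError, DomainError

__all__ = [
    "HemoglobinParams",
    "ArterialInput",
    "CapillaryBed",
    "BaselineState",
    "ModelConstants",
    "hill_saturation",
    "hill_inverse",
    "mean_capillary_po2",
    "capillary_flux",
    "diffusivity_from_geometry",
    "flux_ceiling",
    "oef_from_rates",
    "calibrate_baseline",
    "do_over_cbf",
    "model_constants",
]

#: Adult human hemoglobin half-saturation tension (torr).
DEFAULT_P50 = 26.6
#: Hill cooperativity exponent for hemoglobin.
DEFAULT_HILL_H = 2.8
#: Typical arterial oxygen tension (torr).
DEFAULT_PO2_A = 100.0
#: Arterial oxygen content (umol O2 per ml blood); cancels out of all
#: baseline-normalized quantities.
DEFAULT_O2_CONTENT = 8.7


@dataclass(frozen=True)
class HemoglobinParams:
    """Oxygen-binding curve of hemoglobin.

    Parameters
    ----------
    p50
        Oxygen tension (torr) at which half of the hemoglobin binding
        sites are occupied.
    h
        Hill coefficient (dimensionless cooperativity exponent).
    """

    p50: float = DEFAULT_P50
    h: float = DEFAULT_HILL_H

    def __post_init__(self) -> None:
        if self.p50 <= 0:
            raise DomainError(f"p50 must be positive, got {self.p50}")
        if self.h < 1:
            raise DomainError(f"Hill coefficient must be >= 1, got {self.h}")


@dataclass(frozen=True)
class ArterialInput:
    """Arterial oxygen tension and content feeding the capillary bed."""

    po2_a: float = DEFAULT_PO2_A
    o2_content: float = DEFAULT_O2_CONTENT

    def __post_init__(self) -> None:
        if self.po2_a <= 0:
            raise DomainError(f"arterial PO2 must be positive, got {self.po2_a}")
        if self.o2_content <= 0:
            raise DomainError(
                f"arterial O2 content must be positive, got {self.o2_content}"
            )


@dataclass(frozen=True)
class CapillaryBed:
    """Geometry of the capillary bed within one tissue volume.

    The effective diffusivity is ``cd * n_capillaries * mean_length /
    tissue_volume``; the length density itself is always derived, never
    stored.
    """

    n_capillaries: float
    mean_length: float  # mm
    tissue_volume: float  # mm^3
    cd: float = 1.0  # dimensionless proportionality constant

    def __post_init__(self) -> None:
        for name in ("n_capillaries", "mean_length", "tissue_volume", "cd"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    @property
    def length_density(self) -> float:
        """Capillary length per unit tissue volume (mm per mm^3)."""
        return self.n_capillaries * self.mean_length / self.tissue_volume


@dataclass(frozen=True)
class BaselineState:
    """Calibrated undisturbed-awake baseline of one tissue region.

    ``j_o`` is the baseline oxygen consumption (= capillary flux at steady
    state) and ``d_o`` the effective diffusivity that reproduces it given
    the baseline capillary-to-tissue gradient.
    """

    cbf_o: float
    j_o: float
    oef_o: float
    po2_t_o: float
    d_o: float

    def __post_init__(self) -> None:
        if not 0 < self.oef_o < 1:
            raise DomainError(f"baseline OEF must lie in (0, 1), got {self.oef_o}")
        if self.d_o <= 0:
            raise DomainError(f"d_o must be positive, got {self.d_o}")


@dataclass(frozen=True)
class ModelConstants:
    """Dimensionless constants of the normalized flow-diffusion relation.

    ``k1 = [O2^A] / P50`` (after unit normalization) and
    ``k2 = PO2^T_avg / P50``.  Always recomputed from the physiology,
    never user-set.
    """

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise DomainError("k1 must be positive")
        if self.k2 < 0:
            raise DomainError("k2 must be non-negative")


def hill_saturation(po2: float, hb: HemoglobinParams) -> float:
    """Fractional hemoglobin O2 saturation at tension ``po2`` (torr)."""
    if po2 < 0:
        raise DomainError(f"PO2 must be non-negative, got {po2}")
    if po2 == 0:
        return 0.0
    r = (po2 / hb.p50) ** hb.h
    return r / (r + 1.0)


def hill_inverse(saturation: float, hb: HemoglobinParams) -> float:
    """Oxygen tension (torr) at which hemoglobin saturation equals ``saturation``."""
    if not 0 <= saturation < 1:
        raise DomainError(f"saturation must lie in [0, 1), got {saturation}")
    if saturation == 0:
        return 0.0
    return hb.p50 * (saturation / (1.0 - saturation)) ** (1.0 / hb.h)


def mean_capillary_po2(oef: float, hb: HemoglobinParams) -> float:
    """Mean capillary oxygen tension (torr) at extraction fraction ``oef``.

    Uses the linear-profile approximation in which mean capillary
    saturation is ``1 - oef/2``, giving ``P50 * (2/oef - 1)**(1/h)``.
    Values of ``oef`` in [1, 2) are mathematically valid but outside the
    physiological range and trigger a warning.
    """
    if not 0 < oef < 2:
        raise DomainError(
            f"OEF must lie in (0, 2) for a mean saturation in (0, 1), got {oef}"
        )
    if oef >= 1:
        warnings.warn(
            f"OEF {oef:.3g} is >= 1: mathematically valid but non-physiological",
            stacklevel=2,
        )
    return hb.p50 * (2.0 / oef - 1.0) ** (1.0 / hb.h)


def capillary_flux(d: float, po2c_avg: float, po2t: float) -> float:
    """Net capillary-to-tissue O2 flux ``J = D * (PO2^C_avg - PO2^T_avg)``.

    May be negative when the gradient is inverted; the caller decides
    whether that is meaningful.
    """
    if d <= 0:
        raise DomainError(f"diffusivity must be positive, got {d}")
    return d * (po2c_avg - po2t)


def diffusivity_from_geometry(bed: CapillaryBed) -> float:
    """Effective diffusivity ``D = C_d * N_C * L_C / V`` from bed geometry."""
    return bed.cd * bed.length_density


def flux_ceiling(d: float, arterial: ArterialInput, po2t: float) -> float:
    """Maximal capillary-to-tissue transfer rate ``J_max = D * (PO2^A - PO2^T)``.

    The mean capillary tension can never exceed the arterial tension, so
    this is the hard ceiling on oxygen delivery however high flow goes.
    """
    if d <= 0:
        raise DomainError(f"diffusivity must be positive, got {d}")
    if arterial.po2_a <= po2t:
        raise DomainError(
            "no positive flux ceiling: arterial PO2 "
            f"{arterial.po2_a} torr <= tissue PO2 {po2t} torr"
        )
    return d * (arterial.po2_a - po2t)


def oef_from_rates(cmro2: float, cbf: float, o2_content: float) -> float:
    """Oxygen extraction fraction ``CMRO2 / (CBF * [O2^A])``.

    Warns (does not raise) when the result falls outside (0, 1), since
    measurement noise can push individual records past the physical range.
    """
    if cbf == 0:
        raise ZeroDivisionError(
            "cannot compute OEF: CBF is zero (oxygen delivery rate vanishes)"
        )
    if cbf < 0:
        raise DomainError(f"CBF must be positive, got {cbf}")
    if o2_content <= 0:
        raise DomainError(f"O2 content must be positive, got {o2_content}")
    if cmro2 < 0:
        raise DomainError(f"CMRO2 must be non-negative, got {cmro2}")
    oef = cmro2 / (cbf * o2_content)
    if not 0 < oef < 1 and cmro2 > 0:
        warnings.warn(
            f"OEF {oef:.3g} outside the physiological range (0, 1)", stacklevel=2
        )
    return oef


def calibrate_baseline(
    oef_o: float,
    cbf_o: float,
    arterial: ArterialInput,
    po2t_o: float,
    hb: HemoglobinParams,
) -> BaselineState:
    """Fix the effective diffusivity ``D_o`` from the measured baseline.

    ``J_o = OEF_o * CBF_o * [O2^A]`` and ``D_o`` is chosen so that the flux
    across the baseline gradient reproduces ``J_o`` exactly.
    """
    if cbf_o <= 0:
        raise DomainError(f"baseline CBF must be positive, got {cbf_o}")
    po2c = mean_capillary_po2(oef_o, hb)
    gradient = po2c - po2t_o
    if gradient <= 0:
        raise CalibrationError(
            f"non-positive baseline gradient: mean capillary PO2 {po2c:.3f} torr "
            f"<= tissue PO2 {po2t_o:.3f} torr (OEF_o={oef_o}, p50={hb.p50}, h={hb.h})"
        )
    j_o = oef_o * cbf_o * arterial.o2_content
    d_o = j_o / gradient
    return BaselineState(cbf_o=cbf_o, j_o=j_o, oef_o=oef_o, po2_t_o=po2t_o, d_o=d_o)


def do_over_cbf(
    oef_o: float,
    arterial: ArterialInput,
    po2t: float,
    hb: HemoglobinParams,
) -> float:
    """Closed-form baseline ratio ``D_o / CBF_o`` (per torr).

    ``([O2^A]/P50) * OEF_o / ((2/OEF_o - 1)**(1/h) - PO2^T/P50)``; flow
    cancels, so the ratio depends only on extraction, tissue tension and
    the hemoglobin curve.  Algebraically identical to the
    :func:`calibrate_baseline` ratio ``d_o / cbf_o``.
    """
    if not 0 < oef_o < 2:
        raise DomainError(f"OEF must lie in (0, 2), got {oef_o}")
    denom = (2.0 / oef_o - 1.0) ** (1.0 / hb.h) - po2t / hb.p50
    if denom <= 0:
        raise DomainError(
            f"non-positive normalized gradient (denominator {denom:.4g}): "
            f"tissue PO2 {po2t} torr too high for OEF_o {oef_o}"
        )
    return (arterial.o2_content / hb.p50) * oef_o / denom


def model_constants(
    arterial: ArterialInput, po2t: float, hb: HemoglobinParams
) -> ModelConstants:
    """Dimensionless constants of the normalized baseline relation."""
    if po2t < 0:
        raise DomainError(f"tissue PO2 must be non-negative, got {po2t}")
    return ModelConstants(k1=arterial.o2_content / hb.p50, k2=po2t / hb.p50)
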