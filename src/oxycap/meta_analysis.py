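"""Cross-species meta-analytic computations.

Covers the statistical side of the framework: per-record oxygen extraction
fractions and their species/grand summaries, species-mean normalization of
flow/metabolism pairs, the fractional-change stimulation slope, linear
capillary-density regressions, and the measured-versus-predicted flow
regression that validates the state curve.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, NumericalError, UsageError
from .state_curve import ModelParams, cbf_prime_from_j_prime
from .transport_core import oef_from_rates

__all__ = [
    "RegionRecord",
    "StimulationRecord",
    "CapillaryDensityRecord",
    "SummaryStat",
    "FitResult",
    "group_summary",
    "summarize_by",
    "oef_table",
    "oef_summary",
    "normalize_by_species_mean",
    "fit_linear",
    "stimulation_slope",
    "predicted_vs_measured",
    "capillary_density_fits",
    "records_to_frame",
]

_TISSUE_CLASSES = ("gray", "white", "whole")
_STATES = ("awake", "anesthetized")
_CONDITIONS = ("stimulation", "sleep", "deprivation", "seizure")


@dataclass(frozen=True)
class RegionRecord:
    """One regional flow/metabolism measurement in one species and state."""

    species: str
    region: str
    tissue_class: str
    cbf: float  # ml.100g-1.min-1
    cmro2: float  # umol.100g-1.min-1
    o2_content: float  # umol/ml
    state: str = "awake"
    source: str = ""

    def __post_init__(self) -> None:
        if self.tissue_class not in _TISSUE_CLASSES:
            raise DomainError(
                f"tissue_class must be one of {_TISSUE_CLASSES}, got {self.tissue_class!r}"
            )
        if self.state not in _STATES:
            raise DomainError(f"state must be one of {_STATES}, got {self.state!r}")
        if self.cbf <= 0:
            raise DomainError(f"CBF must be positive, got {self.cbf}")
        if self.cmro2 < 0:
            raise DomainError(f"CMRO2 must be non-negative, got {self.cmro2}")
        if self.o2_content <= 0:
            raise DomainError(f"O2 content must be positive, got {self.o2_content}")


@dataclass(frozen=True)
class StimulationRecord:
    """Fractional flow/metabolism changes relative to the awake baseline."""

    species: str
    frac_dcbf: float  # dCBF / CBF_o
    frac_dcmro2: float  # dCMRO2 / CMRO2_o
    condition: str = "stimulation"

    def __post_init__(self) -> None:
        if self.condition not in _CONDITIONS:
            raise DomainError(
                f"condition must be one of {_CONDITIONS}, got {self.condition!r}"
            )
        if self.frac_dcbf <= -1 or self.frac_dcmro2 <= -1:
            raise DomainError("fractional changes must exceed -1")


@dataclass(frozen=True)
class CapillaryDensityRecord:
    """Regional capillary density with matching glucose-use and flow rates."""

    region: str
    capillary_density: float  # capillary sections per mm^2
    cmr_glc: float  # umol.100mg-1.min-1
    cbf: float  # ml.100mg-1.min-1

    def __post_init__(self) -> None:
        if self.capillary_density <= 0:
            raise DomainError(
                f"capillary density must be positive, got {self.capillary_density}"
            )


@dataclass(frozen=True)
class SummaryStat:
    """Group mean with sample SD (``sd`` is None for singleton groups)."""

    group: str
    n: int
    mean: float
    sd: float | None


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r2: float
    se_slope: float
    n: int
    through_origin: bool
    p_slope: float = float("nan")


def group_summary(values: Sequence[float], group: str) -> SummaryStat:
    """Mean and sample standard deviation (n-1 denominator) of one group.

    Full precision is kept internally; rounding is a presentation concern.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise UsageError(f"empty value list for group {group!r}")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return SummaryStat(group=group, n=int(arr.size), mean=float(np.mean(arr)), sd=sd)


def summarize_by(df: pd.DataFrame, value: str, by: str) -> list[SummaryStat]:
    """Per-group :func:`group_summary` over a DataFrame column."""
    return [
        group_summary(sub[value].to_numpy(), str(name))
        for name, sub in df.groupby(by, sort=True)
    ]


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Convert a list of record dataclasses into a DataFrame."""
    rows = [asdict(r) for r in records]
    if not rows:
        raise UsageError("no records supplied")
    return pd.DataFrame(rows)


def oef_table(records: Iterable[RegionRecord] | pd.DataFrame) -> pd.DataFrame:
    """Attach a per-record ``oef`` column: CMRO2 over delivered oxygen."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.copy()
    df["oef"] = [
        oef_from_rates(row.cmro2, row.cbf, row.o2_content)
        for row in df.itertuples(index=False)
    ]
    return df


def oef_summary(
    records: Iterable[RegionRecord] | pd.DataFrame, awake_only: bool = False
) -> dict:
    """Grand and per-species OEF summaries of a regional table.

    Anesthetized records are pooled by default (they cluster with awake
    values); ``awake_only`` restricts to awake measurements.
    """
    df = oef_table(records)
    if awake_only:
        df = df[df["state"] == "awake"]
        if df.empty:
            raise UsageError("no awake records after filtering")
    return {
        "grand": group_summary(df["oef"].to_numpy(), "all"),
        "by_species": summarize_by(df, value="oef", by="species"),
    }


def normalize_by_species_mean(
    records: Iterable[RegionRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Divide each CBF/CMRO2 value by its species mean.

    Makes regional values comparable across species spanning large
    absolute-rate differences; normalized species means are 1 by
    construction, and the operation is idempotent.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.copy()
    for col, out in (("cbf", "cbf_norm"), ("cmro2", "cmro2_norm")):
        df[out] = df[col] / df.groupby("species")[col].transform("mean")
    return df


def fit_linear(
    x: Sequence[float], y: Sequence[float], through_origin: bool = False
) -> FitResult:
    """Ordinary least squares of y on x, optionally forced through the origin.

    Returns slope, intercept, r-squared (uncentered for origin fits), the
    slope standard error and its two-sided t-test p-value.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise UsageError(f"x and y lengths differ: {x.size} vs {y.size}")
    if x.size < 2:
        raise UsageError(f"need at least 2 points to fit a line, got {x.size}")
    if np.ptp(x) == 0:
        raise NumericalError("degenerate predictor: x has zero variance")
    design = x[:, None] if through_origin else sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    slope = float(res.params[-1])
    intercept = 0.0 if through_origin else float(res.params[0])
    return FitResult(
        slope=slope,
        intercept=intercept,
        r2=float(np.clip(res.rsquared, 0.0, 1.0)),
        se_slope=float(res.bse[-1]),
        n=int(x.size),
        through_origin=through_origin,
        p_slope=float(res.pvalues[-1]),
    )


def stimulation_slope(
    records: Iterable[StimulationRecord],
    through_origin: bool = True,
    include_seizure: bool = False,
) -> FitResult:
    """Slope of fractional flow change on fractional metabolism change.

    Only stimulation records enter the fit; seizure points sit beyond the
    normophysiological ceiling and are excluded unless requested.  The
    through-origin form is the default since zero metabolic change implies
    zero flow change.
    """
    keep = {"stimulation"} | ({"seizure"} if include_seizure else set())
    recs = [r for r in records if r.condition in keep]
    if len(recs) < 2:
        raise UsageError(
            f"need at least 2 stimulation records to fit a slope, got {len(recs)}"
        )
    x = [r.frac_dcmro2 for r in recs]
    y = [r.frac_dcbf for r in recs]
    return fit_linear(x, y, through_origin=through_origin)


def predicted_vs_measured(
    points: Sequence[tuple[float, float]],
    params: ModelParams,
    through_origin: bool = False,
) -> FitResult:
    """Regress measured normalized flow on the model-predicted flow.

    ``points`` are ``(j_prime, cbf_prime_measured)`` pairs spanning any
    range of states (sleep through stimulation).  A slope near 1 with high
    r-squared indicates the supply-limited curve accounts for the data.
    """
    if not points:
        raise UsageError("no points supplied")
    predicted = [cbf_prime_from_j_prime(j, params) for j, _ in points]
    measured = [m for _, m in points]
    return fit_linear(predicted, measured, through_origin=through_origin)


def capillary_density_fits(
    records: Iterable[CapillaryDensityRecord],
) -> tuple[FitResult, FitResult]:
    """Linear fits of glucose use and blood flow against capillary density.

    Returns ``(cmr_glc ~ density, cbf ~ density)``, each with free
    intercept, r-squared and the slope's two-sided p-value.
    """
    recs = list(records)
    if len(recs) < 3:
        raise UsageError(
            f"need at least 3 capillary-density records, got {len(recs)}"
        )
    density = [r.capillary_density for r in recs]
    glc_fit = fit_linear(density, [r.cmr_glc for r in recs])
    cbf_fit = fit_linear(density, [r.cbf for r in recs])
    return glc_fit, cbf_fit
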