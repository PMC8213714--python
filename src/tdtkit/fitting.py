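"""Functional fitting interface.

Thin wrappers over the model classes in :mod:`tdtkit.models`, for callers
who prefer ``fit_static(obs)`` over ``StaticTDTModel(obs).fit()``.
"""

from __future__ import annotations

from .curves import RampObservation, StaticObservation
from .models import (
    DynamicTDTModel,
    SingleMeasurementModel,
    StaticTDTModel,
    TDTResults,
)

__all__ = ["fit_static", "fit_dynamic", "curve_from_single", "TDTResults"]


def fit_static(
    obs: list[StaticObservation],
    t_ref: float = 60.0,
    aggregate: str | None = None,
) -> TDTResults:
    """Fit a TDT curve by OLS of log10(time) on temperature."""
    return StaticTDTModel(obs).fit(t_ref=t_ref, aggregate=aggregate)


def fit_dynamic(
    obs: list[RampObservation],
    t_ref: float = 60.0,
    tc_star: float | None = None,
) -> TDTResults:
    """Fit a TDT curve from ramping assays (exact for two ramps, least
    squares in dCT_max for three or more)."""
    return DynamicTDTModel(obs, tc_star=tc_star).fit(t_ref=t_ref)


def curve_from_single(
    measurement: StaticObservation | RampObservation,
    assumed_z: float,
    t_ref: float = 60.0,
) -> TDTResults:
    """TDT curve from a single measurement and an assumed z (flagged
    extrapolation-sensitive)."""
    return SingleMeasurementModel(measurement, assumed_z).fit(t_ref=t_ref)
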