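"""Closed-form predictions from a TDT curve.

Four interconversions between tolerance metrics:

* ``predict_time`` — tolerance time at a constant temperature,
  ``t = t_ref * 10^((ct_ref - T)/z)``;
* ``predict_sctmax`` — its exact inverse, the static temperature tolerated
  for a given duration;
* ``predict_ramp_outcome`` — knockdown time and temperature (dCT_max) on a
  linear ramp ``T(t) = t0 + b*t``, from the integrated exponential rate law:

  .. math::

     t_{Ld} = \\frac{1}{kb}\\,\\ln\\!\\big[k\\,b\\,t_{ref}\\,
              e^{k(ct_{ref}-T_0)} + e^{k(T_{c*}-T_0)}\\big],
     \\qquad dCT_{max} = T_0 + b\\,t_{Ld};

* ``sctmax_from_ramp`` — the algebraic inverse, recovering the static
  anchor from an observed dCT_max.

The baseline T_c* enters only through the additive ``e^{k(T_c* - T0)}``
term; with the default T_c* = T0 that term is exactly 1 and the formulas
never degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .curves import TDTCurve, z_to_k
from .exceptions import (
    DegenerateRampError,
    InconsistentInputError,
    TDTValidationError,
)

__all__ = [
    "RampOutcome",
    "predict_time",
    "predict_sctmax",
    "predict_ramp_outcome",
    "sctmax_from_ramp",
]


@dataclass(frozen=True)
class RampOutcome:
    """Predicted knockdown on a linear ramp.

    ``dctmax == t0 + rate * t_ld`` holds exactly (the ramp is linear).
    """

    t_ld: float  # minutes from ramp start to knockdown
    dctmax: float  # knockdown temperature, °C
    t0: float
    rate: float
    tc_star: float


def predict_time(curve: TDTCurve, temp: float) -> float:
    """Tolerance time (minutes) at a constant temperature ``temp`` (°C).

    Strictly decreasing in temperature; log10-linear with slope -1/z.
    """
    return curve.t_ref * 10.0 ** ((curve.ct_ref - temp) / curve.z)


def predict_sctmax(curve: TDTCurve, duration: float) -> float:
    """Static temperature (°C) tolerated for exactly ``duration`` minutes.

    Exact inverse of :func:`predict_time`.
    """
    if not duration > 0:
        raise TDTValidationError(f"duration must be > 0, got {duration!r}")
    return curve.ct_ref - curve.z * math.log10(duration / curve.t_ref)


def predict_ramp_outcome(
    curve: TDTCurve,
    t0: float,
    rate: float,
    tc_star: float | None = None,
) -> RampOutcome:
    """Knockdown time and temperature on a linear ramp from ``t0`` at
    ``rate`` °C/min.

    ``tc_star`` defaults to the curve's own ``tc_star`` if set, else to
    ``t0`` (no injury booked below the ramp start).
    """
    if not rate > 0:
        raise TDTValidationError(f"rate must be > 0, got {rate!r}")
    tc = tc_star if tc_star is not None else (
        curve.tc_star if curve.tc_star is not None else t0
    )
    if not tc <= curve.ct_ref:
        raise TDTValidationError(
            f"tc_star ({tc!r}) must not exceed ct_ref ({curve.ct_ref!r})"
        )
    k = curve.k
    arg = k * rate * curve.t_ref * math.exp(k * (curve.ct_ref - t0)) + math.exp(
        k * (tc - t0)
    )
    if not arg > 0:
        raise DegenerateRampError(
            f"logarithm argument {arg!r} not positive for ramp "
            f"(t0={t0}, rate={rate}, tc_star={tc})"
        )
    t_ld = math.log(arg) / (k * rate)
    return RampOutcome(
        t_ld=t_ld, dctmax=t0 + rate * t_ld, t0=t0, rate=rate, tc_star=tc
    )


def sctmax_from_ramp(
    dctmax: float,
    t0: float,
    rate: float,
    z: float,
    t_ref: float = 60.0,
    tc_star: float | None = None,
) -> float:
    """Static anchor temperature implied by one ramp observation.

    Inverts the ramp closed form for ``ct_ref`` at the given thermal
    sensitivity ``z``: feeding the result back through
    :func:`predict_ramp_outcome` reproduces ``dctmax``.
    """
    if not rate > 0:
        raise TDTValidationError(f"rate must be > 0, got {rate!r}")
    if not dctmax > t0:
        raise TDTValidationError(
            f"dctmax ({dctmax!r}) must exceed t0 ({t0!r})"
        )
    if not t_ref > 0:
        raise TDTValidationError(f"t_ref must be > 0, got {t_ref!r}")
    tc = tc_star if tc_star is not None else t0
    k = z_to_k(z)
    diff = math.exp(k * (dctmax - t0)) - math.exp(k * (tc - t0))
    if not diff > 0:
        raise InconsistentInputError(
            f"ramp ends at {dctmax} °C, not above the injury baseline "
            f"tc_star={tc} °C: no net injury is accumulated"
        )
    return t0 + math.log(diff / (k * rate * t_ref)) / k
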