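"""Thermal death time (TDT) curve parameters and unit conversions.

A TDT curve summarises an ectotherm's heat tolerance as a straight line in
(temperature, log10 time) space: the time tolerated at a constant stressful
temperature drops tenfold for every ``z`` degrees Celsius of warming.  The
curve is parameterised here by the thermal sensitivity ``z`` (°C per decade
of time) and one anchor point — the temperature ``ct_ref`` tolerated for
exactly ``t_ref`` minutes.  With the default ``t_ref = 60`` the anchor is
the widely reported sCT_max(1 h), the static temperature causing heat
failure after a one-hour exposure.

The equivalent exponential rate constant ``k = ln(10)/z`` (per °C) and the
familiar Q10 factor ``10^(10/z)`` are derived quantities, never stored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from .exceptions import TDTValidationError

__all__ = [
    "TDTCurve",
    "z_to_k",
    "k_to_z",
    "z_to_q10",
    "reanchor",
]

LN10 = math.log(10.0)


def z_to_k(z: float) -> float:
    """Convert thermal sensitivity ``z`` (°C/decade) to the rate constant
    ``k = ln(10)/z`` (per °C) of the exponential injury-rate law."""
    if not z > 0:
        raise TDTValidationError(f"z must be > 0, got {z!r}")
    return LN10 / z


def k_to_z(k: float) -> float:
    """Inverse of :func:`z_to_k`."""
    if not k > 0:
        raise TDTValidationError(f"k must be > 0, got {k!r}")
    return LN10 / k


def z_to_q10(z: float) -> float:
    """Q10 of the injury accumulation rate implied by ``z``: ``10^(10/z)``.

    Heat injury rates are extraordinarily thermally sensitive; typical
    ectotherm values z ∈ [2, 5] correspond to Q10 between 100 and 100,000.
    """
    if not z > 0:
        raise TDTValidationError(f"z must be > 0, got {z!r}")
    return 10.0 ** (10.0 / z)


@dataclass(frozen=True)
class TDTCurve:
    """Parameters of one thermal death time curve (one endpoint, one line).

    Parameters
    ----------
    z : float
        Thermal sensitivity, °C per tenfold change of tolerance time. > 0.
    ct_ref : float
        Temperature (°C) tolerated for exactly ``t_ref`` minutes.
    t_ref : float, default 60
        Reference duration (minutes); 60 makes ``ct_ref`` = sCT_max(1 h).
    tc_star : float or None, default None
        Optional baseline temperature T_c* (°C) below which no injury is
        booked in the ramp closed forms.  When unset, ramp formulas use the
        ramp's own start temperature, making the baseline term exactly 1.
    provenance : str
        Free-text label of where the parameters came from.
    """

    z: float
    ct_ref: float
    t_ref: float = 60.0
    tc_star: float | None = None
    provenance: str = ""

    def __post_init__(self):
        if not self.z > 0:
            raise TDTValidationError(f"z must be > 0, got {self.z!r}")
        if not self.t_ref > 0:
            raise TDTValidationError(f"t_ref must be > 0, got {self.t_ref!r}")
        if self.tc_star is not None and not self.tc_star < self.ct_ref:
            raise TDTValidationError(
                f"tc_star ({self.tc_star!r}) must be strictly below "
                f"ct_ref ({self.ct_ref!r})"
            )

    @property
    def k(self) -> float:
        """Rate constant ln(10)/z, per °C (recomputed, never stored)."""
        return z_to_k(self.z)

    @property
    def q10(self) -> float:
        return z_to_q10(self.z)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "z_C": self.z,
            "ct_ref_C": self.ct_ref,
            "t_ref_min": self.t_ref,
            "tc_star_C": self.tc_star,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TDTCurve":
        try:
            return cls(
                z=float(d["z_C"]),
                ct_ref=float(d["ct_ref_C"]),
                t_ref=float(d.get("t_ref_min", 60.0)),
                tc_star=None if d.get("tc_star_C") is None else float(d["tc_star_C"]),
                provenance=str(d.get("provenance", "")),
            )
        except KeyError as e:
            raise TDTValidationError(f"curve JSON missing key {e}") from e

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TDTCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def reanchor(curve: TDTCurve, new_t_ref: float) -> TDTCurve:
    """Re-express the same TDT line through a different reference duration.

    The returned curve predicts identical tolerance times at every
    temperature; only the (t_ref, ct_ref) anchor pair moves along the line:
    ``ct_ref' = ct_ref - z * log10(new_t_ref / t_ref)``.
    """
    if not new_t_ref > 0:
        raise TDTValidationError(f"new_t_ref must be > 0, got {new_t_ref!r}")
    new_ct = curve.ct_ref - curve.z * math.log10(new_t_ref / curve.t_ref)
    return replace(curve, ct_ref=new_ct, t_ref=new_t_ref)


@dataclass(frozen=True)
class StaticObservation:
    """One constant-temperature assay: time to the endpoint at ``temp``."""

    temp: float  # °C
    time: float  # minutes to endpoint (t_coma)
    label: str | None = None

    def __post_init__(self):
        if not self.time > 0:
            raise TDTValidationError(f"time must be > 0, got {self.time!r}")


@dataclass(frozen=True)
class RampObservation:
    """One dynamic (ramping) assay: knockdown temperature reached on a
    linear ramp T(t) = t0 + rate * t."""

    t0: float  # ramp start temperature, °C
    rate: float  # ramping rate b, °C/min
    dctmax: float  # observed knockdown temperature, °C
    label: str | None = None

    def __post_init__(self):
        if not self.rate > 0:
            raise TDTValidationError(f"rate must be > 0, got {self.rate!r}")
        if not self.dctmax > self.t0:
            raise TDTValidationError(
                f"dctmax ({self.dctmax!r}) must exceed t0 ({self.t0!r})"
            )
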