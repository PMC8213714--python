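"""Heat-injury dose accumulation over arbitrary temperature exposures.

All injury bookkeeping is in normalized units: a dose of 1 is the lethal
(endpoint-evoking) amount, so the injury accumulation rate at a constant
temperature T is simply the reciprocal of the tolerance time there,

    rate(T) = 1 / predict_time(curve, T)   [fraction of lethal dose / min]

which is the exponential rate law of the TDT curve expressed per unit
lethal dose.  Fractions from sequential exposures add: 15 min at a
temperature tolerated for 50 min spends 0.3 of the budget, leaving 0.7 —
210 min at a temperature tolerated for 300 min.

For fluctuating profiles the dose integral is evaluated by first-order
quadrature with a default step of 10 s, the resolution at which validation
experiments have driven the model.

The model books no repair and no hardening: rates are non-negative
everywhere, and the simplified rate is (negligibly) positive even at benign
temperatures.  Supplying ``exact_tc`` switches to the exact rate law with a
hard floor at the incipient lethal temperature — a documented departure
from the default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import TDTCurve
from .exceptions import (
    BelowRangeWarning,
    DoseNotReached,
    RefinementWarning,
    TDTValidationError,
)
from .prediction import predict_time

__all__ = [
    "TemperatureProfile",
    "DoseTrajectory",
    "ExposureSegment",
    "SegmentReport",
    "injury_rate",
    "integrate_profile",
    "segment_fractions",
    "time_to_dose",
]

#: default integration step: 10 seconds, in minutes
DEFAULT_DT = 1.0 / 6.0


@dataclass(frozen=True)
class TemperatureProfile:
    """A time-ordered temperature trace (piecewise-linear between samples).

    ``times`` are minutes from the start of exposure, strictly increasing;
    ``temps`` are °C.
    """

    times: np.ndarray
    temps: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)
        if times.ndim != 1 or temps.ndim != 1 or len(times) != len(temps):
            raise TDTValidationError("times and temps must be 1-D, equal length")
        if len(times) < 2:
            raise TDTValidationError("profile needs at least 2 points")
        if not np.all(np.diff(times) > 0):
            raise TDTValidationError("profile times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def temp_at(self, t) -> np.ndarray:
        """Linear interpolation of temperature at time(s) ``t`` (minutes)."""
        return np.interp(t, self.times, self.temps)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TemperatureProfile":
        """Build from a table with ``temp_C`` and either ``time_min`` or
        ``time_s`` (converted to minutes)."""
        if "time_min" in df.columns:
            times = df["time_min"].to_numpy(dtype=float)
        elif "time_s" in df.columns:
            times = df["time_s"].to_numpy(dtype=float) / 60.0
        else:
            raise TDTValidationError(
                "profile table needs a time_min or time_s column"
            )
        if "temp_C" not in df.columns:
            raise TDTValidationError("profile table needs a temp_C column")
        return cls(times=times, temps=df["temp_C"].to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "temp_C": self.temps})


@dataclass(frozen=True)
class DoseTrajectory:
    """Cumulative injury (fraction of lethal dose) on an integration grid.

    ``t_failure`` is the first grid time at which the dose reaches 1
    (``None`` if never reached); :func:`time_to_dose` refines it by linear
    interpolation between grid points.
    """

    times: np.ndarray
    dose: np.ndarray
    t_failure: float | None
    dt: float

    @property
    def final_dose(self) -> float:
        return float(self.dose[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "dose": self.dose})


@dataclass(frozen=True)
class ExposureSegment:
    """A constant-temperature exposure of known or open-ended duration.

    ``duration=None`` marks the terminal segment: "hold here until the
    endpoint", whose predicted duration the additivity arithmetic returns.
    """

    temp: float  # °C
    duration: float | None = None  # minutes; None = until failure

    def __post_init__(self):
        if self.duration is not None and self.duration < 0:
            raise TDTValidationError(
                f"duration must be >= 0, got {self.duration!r}"
            )


def injury_rate(
    curve: TDTCurve, temp, exact_tc: float | None = None
):
    """Injury accumulation rate (fraction of lethal dose per minute).

    By default the simplified exponential law ``1 / predict_time``: a rate
    of 0.01 min⁻¹ means constant exposure would cause the endpoint in
    100 min.  With ``exact_tc`` set, the rate carries the exact law's
    ``(e^{k(T - T_c)} - 1)`` form — scaled by ``1 - e^{-k(T - T_c)}`` above
    the floor and exactly 0 at or below it.  The two differ by 1% at
    ``T - T_c = 2z`` and vanishingly above that.

    Accepts scalars or arrays of temperature.
    """
    temp = np.asarray(temp, dtype=float)
    rate = 1.0 / predict_time(curve, temp)
    if exact_tc is not None:
        k = curve.k
        scale = np.where(
            temp > exact_tc, -np.expm1(-k * (temp - exact_tc)), 0.0
        )
        rate = rate * scale
    return rate if rate.ndim else float(rate)


def integrate_profile(
    curve: TDTCurve,
    profile: TemperatureProfile,
    dt: float = DEFAULT_DT,
    exact_tc: float | None = None,
) -> DoseTrajectory:
    """Accumulate injury dose along a temperature profile.

    First-order quadrature: each step of width ``dt`` contributes
    ``rate(T_mid) * dt`` where ``T_mid`` is the linear interpolant of the
    profile at the step midpoint (midpoint sampling halves the bias the
    exponential rate induces at the step ends).  The trajectory is not
    truncated at dose 1 — supra-unity doses are meaningful and reported.
    """
    if not dt > 0:
        raise TDTValidationError(f"dt must be > 0, got {dt!r}")
    min_interval = float(np.min(np.diff(profile.times)))
    if dt > min_interval * (1 + 1e-12):
        warnings.warn(
            f"integration step {dt:g} min is coarser than the finest "
            f"profile interval {min_interval:g} min; consider refining dt",
            RefinementWarning,
            stacklevel=2,
        )
    if float(profile.temps.min()) < curve.ct_ref - 2 * curve.z:
        warnings.warn(
            "profile drops more than 2z below ct_ref; the TDT relation is "
            "unvalidated that far below the tolerated range (possible "
            "repair/hardening not modelled)",
            BelowRangeWarning,
            stacklevel=2,
        )

    t0, t1 = float(profile.times[0]), float(profile.times[-1])
    n_full = int(math.floor((t1 - t0) / dt + 1e-9))
    edges = t0 + dt * np.arange(n_full + 1)
    if edges[-1] < t1 - 1e-12:  # partial final step to the profile end
        edges = np.append(edges, t1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    rates = injury_rate(curve, profile.temp_at(mids), exact_tc=exact_tc)
    dose = np.concatenate([[0.0], np.cumsum(rates * widths)])

    crossed = np.nonzero(dose >= 1.0)[0]
    t_failure = float(edges[crossed[0]]) if crossed.size else None
    return DoseTrajectory(times=edges, dose=dose, t_failure=t_failure, dt=dt)


@dataclass(frozen=True)
class SegmentReport:
    """Additivity arithmetic over sequential constant exposures.

    ``fractions`` has one entry per closed segment (duration / tolerance
    time at that temperature).  If a terminal (open) segment was given,
    ``terminal_time`` is its predicted duration — the remaining dose budget
    times the tolerance time at the terminal temperature.  If the closed
    segments alone exceed a dose of 1, ``t_failure`` is the (exact) elapsed
    time at which the dose crossed 1.
    """

    fractions: tuple[float, ...]
    total_dose: float
    terminal_temp: float | None
    terminal_time: float | None
    t_failure: float | None


def segment_fractions(
    curve: TDTCurve, segments: list[ExposureSegment]
) -> SegmentReport:
    """Dose fractions of sequential constant-temperature exposures.

    At most one open-ended segment is allowed and it must come last; its
    predicted duration is ``(1 - sum of closed fractions) * tolerance time``
    at its temperature.  Closed segments pushing the dose past 1 are not an
    error — failure simply occurs mid-segment and the crossing time is
    reported.
    """
    if not segments:
        raise TDTValidationError("need at least one segment")
    open_idx = [i for i, s in enumerate(segments) if s.duration is None]
    if len(open_idx) > 1:
        raise TDTValidationError("at most one open (terminal) segment allowed")
    if open_idx and open_idx[0] != len(segments) - 1:
        raise TDTValidationError("the open segment must be last")
    terminal = segments[open_idx[0]] if open_idx else None
    closed = segments[: open_idx[0]] if open_idx else segments

    fractions = []
    elapsed = 0.0
    dose = 0.0
    t_failure = None
    for seg in closed:
        t_tol = predict_time(curve, seg.temp)
        frac = seg.duration / t_tol
        if t_failure is None and dose + frac >= 1.0:
            t_failure = elapsed + (1.0 - dose) * t_tol
        fractions.append(frac)
        dose += frac
        elapsed += seg.duration

    terminal_time = None
    if terminal is not None:
        if dose >= 1.0:
            raise TDTValidationError(
                f"closed segments already accumulate dose {dose:.4g} >= 1; "
                "no budget remains for the terminal segment"
            )
        t_tol = predict_time(curve, terminal.temp)
        terminal_time = (1.0 - dose) * t_tol

    return SegmentReport(
        fractions=tuple(fractions),
        total_dose=dose,
        terminal_temp=terminal.temp if terminal is not None else None,
        terminal_time=terminal_time,
        t_failure=t_failure,
    )


def time_to_dose(traj: DoseTrajectory, target: float = 1.0) -> float:
    """First time (minutes) the trajectory reaches ``target`` dose, linearly
    interpolated between grid points.

    Raises :class:`DoseNotReached` (carrying the final dose) if the
    trajectory never gets there.
    """
    if not target > 0:
        raise TDTValidationError(f"target must be > 0, got {target!r}")
    idx = np.nonzero(traj.dose >= target)[0]
    if idx.size == 0:
        raise DoseNotReached(target, traj.final_dose)
    i = int(idx[0])
    if i == 0:
        return float(traj.times[0])
    d0, d1 = traj.dose[i - 1], traj.dose[i]
    t0, t1 = traj.times[i - 1], traj.times[i]
    return float(t0 + (target - d0) / (d1 - d0) * (t1 - t0))
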