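"""Model classes estimating TDT-curve parameters from tolerance assays.

Three estimation routes, mirroring how heat-tolerance data actually arrive:

* :class:`StaticTDTModel` — knockdown times at two or more constant
  temperatures; ordinary least squares of log10(time) on temperature
  (the classical TDT regression), z = -1/slope.
* :class:`DynamicTDTModel` — knockdown temperatures (dCT_max) from two or
  more ramping assays; exact two-equation solution for two ramps, nonlinear
  least squares in dCT_max for three or more.
* :class:`SingleMeasurementModel` — one measurement of either kind plus an
  assumed thermal sensitivity z; produces a crude, extrapolation-sensitive
  curve.

Each ``fit()`` returns a :class:`TDTResults` carrying the fitted
:class:`~tdtkit.curves.TDTCurve`, fit diagnostics (R², residuals), the
time- and temperature-span of the input data (so predictions can warn when
they extrapolate beyond it), and a ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .curves import RampObservation, StaticObservation, TDTCurve
from .exceptions import (
    ConvergenceError,
    ExtrapolationWarning,
    FitInvalidError,
    InconsistentInputError,
    InsufficientDataError,
    TDTValidationError,
)
from .prediction import (
    RampOutcome,
    predict_ramp_outcome,
    predict_sctmax,
    predict_time,
    sctmax_from_ramp,
)

__all__ = [
    "TDTResults",
    "StaticTDTModel",
    "DynamicTDTModel",
    "SingleMeasurementModel",
    "HarmonizedValue",
    "harmonize_to_reference",
]

# physically plausible search interval for z (°C per decade of time)
_Z_BRACKET = (0.1, 50.0)


@dataclass
class TDTResults:
    """Fitted TDT curve plus diagnostics.

    Attributes
    ----------
    curve : TDTCurve
        The estimated parameters.
    method : str
        One of ``static-ols``, ``dynamic-nls``, ``dynamic-2pt``,
        ``assumed-z``.
    n_obs : int
    r_squared : float or None
        Coefficient of determination — in log10-time space for static
        fits, in dCT_max (°C) space for dynamic fits.  ``None`` for exact
        (two-point) and assumed-z fits, where it is undefined.
    residuals : ndarray
        Per-observation residuals in the fitting space.
    temp_span, time_span : tuple(float, float)
        The temperature (°C) and time (minutes) range covered by the input
        data; predictions outside either span trigger an
        :class:`ExtrapolationWarning`.
    flags : list of str
        Quality annotations, e.g. ``assumed-z`` or ``z-out-of-range``.
    """

    curve: TDTCurve
    method: str
    n_obs: int
    r_squared: float | None
    residuals: np.ndarray
    temp_span: tuple[float, float]
    time_span: tuple[float, float]
    flags: list[str] = field(default_factory=list)

    # -- predictions with extrapolation guards ---------------------------

    def _warn_if_outside(self, temp: float | None, time: float | None) -> None:
        lo_T, hi_T = self.temp_span
        lo_t, hi_t = self.time_span
        if temp is not None and not (lo_T <= temp <= hi_T):
            warnings.warn(
                f"temperature {temp:g} °C outside fitted span "
                f"[{lo_T:g}, {hi_T:g}] °C",
                ExtrapolationWarning,
                stacklevel=3,
            )
        if time is not None and not (lo_t <= time <= hi_t):
            warnings.warn(
                f"duration {time:g} min outside fitted span "
                f"[{lo_t:g}, {hi_t:g}] min",
                ExtrapolationWarning,
                stacklevel=3,
            )

    def predict_time(self, temp: float) -> float:
        """Tolerance time (min) at ``temp`` °C, warning on extrapolation."""
        t = predict_time(self.curve, temp)
        self._warn_if_outside(temp, t)
        return t

    def predict_sctmax(self, duration: float) -> float:
        """Tolerated static temperature (°C) for ``duration`` minutes."""
        T = predict_sctmax(self.curve, duration)
        self._warn_if_outside(T, duration)
        return T

    def predict_ramp_outcome(
        self, t0: float, rate: float, tc_star: float | None = None
    ) -> RampOutcome:
        out = predict_ramp_outcome(self.curve, t0, rate, tc_star)
        self._warn_if_outside(out.dctmax, None)
        return out

    def summary(self) -> str:
        """Plain-text parameter and diagnostics table."""
        c = self.curve
        lines = [
            "TDT curve fit",
            "=" * 46,
            f"method            {self.method}",
            f"n observations    {self.n_obs}",
            f"z                 {c.z:.6g} °C per decade",
            f"k = ln(10)/z      {c.k:.6g} per °C",
            f"Q10               {c.q10:.6g}",
            f"ct_ref            {c.ct_ref:.6g} °C at t_ref = {c.t_ref:g} min",
            f"tc_star           "
            + (f"{c.tc_star:.6g} °C" if c.tc_star is not None else "unset"),
            f"R²                "
            + (f"{self.r_squared:.6g}" if self.r_squared is not None else "n/a"),
            f"temp span         [{self.temp_span[0]:g}, {self.temp_span[1]:g}] °C",
            f"time span         [{self.time_span[0]:g}, {self.time_span[1]:g}] min",
        ]
        if self.flags:
            lines.append(f"flags             {', '.join(self.flags)}")
        return "\n".join(lines)


class StaticTDTModel:
    """TDT regression from constant-temperature (static) assays.

    Parameters
    ----------
    observations : sequence of StaticObservation
        Knockdown times at assay temperatures; at least two distinct
        temperatures are required to fit.
    """

    def __init__(self, observations):
        self.observations = list(observations)
        if not all(isinstance(o, StaticObservation) for o in self.observations):
            raise TDTValidationError("expected StaticObservation instances")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "StaticTDTModel":
        """Build from a table with columns ``temp_C``, ``time_min``
        and optional ``label``."""
        obs = [
            StaticObservation(
                temp=float(r.temp_C),
                time=float(r.time_min),
                label=str(r.label) if "label" in df.columns else None,
            )
            for r in df.itertuples()
        ]
        return cls(obs)

    def fit(self, t_ref: float = 60.0, aggregate: str | None = None) -> TDTResults:
        """Ordinary least squares of log10(time) on temperature.

        Parameters
        ----------
        t_ref : float
            Reference duration (min) at which the anchor ct_ref is read off.
        aggregate : {None, "median"}
            With ``"median"``, replicate times are collapsed to the median
            per temperature before regression (the conventional reduction
            when several individuals are assayed per temperature).
        """
        obs = self.observations
        if aggregate == "median":
            df = pd.DataFrame({"temp": [o.temp for o in obs],
                               "time": [o.time for o in obs]})
            med = df.groupby("temp", sort=True)["time"].median()
            temps = med.index.to_numpy(dtype=float)
            times = med.to_numpy(dtype=float)
        elif aggregate is None:
            temps = np.array([o.temp for o in obs], dtype=float)
            times = np.array([o.time for o in obs], dtype=float)
        else:
            raise TDTValidationError(f"unknown aggregate policy {aggregate!r}")

        if len(np.unique(temps)) < 2:
            raise InsufficientDataError(
                "static fit needs observations at >= 2 distinct temperatures"
            )
        y = np.log10(times)
        res = sm.OLS(y, sm.add_constant(temps)).fit()
        intercept, slope = res.params
        if slope >= 0:
            raise FitInvalidError(
                f"fitted slope {slope:.4g} is non-negative: tolerance time "
                "cannot increase with temperature under heat stress"
            )
        z = -1.0 / slope
        ct_ref = (math.log10(t_ref) - intercept) / slope
        n = len(temps)
        curve = TDTCurve(z=z, ct_ref=ct_ref, t_ref=t_ref,
                         provenance="static-ols fit")
        return TDTResults(
            curve=curve,
            method="static-ols",
            n_obs=n,
            r_squared=float(res.rsquared) if n > 2 else None,
            residuals=np.asarray(res.resid),
            temp_span=(float(temps.min()), float(temps.max())),
            time_span=(float(times.min()), float(times.max())),
        )


class DynamicTDTModel:
    """TDT parameters from ramping (dynamic) assays.

    Two distinct (start temperature, rate) conditions admit an exact
    solution of the two ramp equations for (z, ct_ref); three or more are
    fitted by least squares on predicted-minus-observed dCT_max.

    Parameters
    ----------
    observations : sequence of RampObservation
    tc_star : float or None
        Baseline temperature below which no injury is booked.  ``None``
        (default) uses each ramp's own start temperature — appropriate
        when ramps start near the threshold of net injury accumulation.
    """

    def __init__(self, observations, tc_star: float | None = None):
        self.observations = list(observations)
        if not all(isinstance(o, RampObservation) for o in self.observations):
            raise TDTValidationError("expected RampObservation instances")
        self.tc_star = tc_star

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, tc_star: float | None = None
    ) -> "DynamicTDTModel":
        """Build from a table with columns ``t0_C``, ``rate_C_per_min``,
        ``dctmax_C`` and optional ``label``."""
        obs = [
            RampObservation(
                t0=float(r.t0_C),
                rate=float(r.rate_C_per_min),
                dctmax=float(r.dctmax_C),
                label=str(r.label) if "label" in df.columns else None,
            )
            for r in df.itertuples()
        ]
        return cls(obs, tc_star=tc_star)

    # -- internals -------------------------------------------------------

    def _tc(self, obs: RampObservation) -> float:
        return self.tc_star if self.tc_star is not None else obs.t0

    def _implied_sct(self, obs: RampObservation, z: float, t_ref: float) -> float:
        return sctmax_from_ramp(
            obs.dctmax, obs.t0, obs.rate, z, t_ref, tc_star=self._tc(obs)
        )

    def _solve_pair(
        self, a: RampObservation, b: RampObservation, t_ref: float
    ) -> tuple[float, float]:
        """Exact (z, ct_ref) from two ramps: the z at which both ramps
        imply the same static anchor, found by bracketed root search."""

        def gap(z: float) -> float:
            return self._implied_sct(a, z, t_ref) - self._implied_sct(b, z, t_ref)

        zs = np.geomspace(_Z_BRACKET[0], _Z_BRACKET[1], 200)
        vals = []
        for z in zs:
            try:
                vals.append(gap(z))
            except (OverflowError, InconsistentInputError):
                vals.append(np.nan)
        vals = np.array(vals)
        ok = np.isfinite(vals)
        idx = None
        wz = np.where(ok)[0]
        for i, j in zip(wz[:-1], wz[1:]):
            if vals[i] == 0.0:
                idx = (i, i)
                break
            if np.sign(vals[i]) != np.sign(vals[j]):
                idx = (i, j)
                break
        if idx is None:
            raise ConvergenceError(
                "two-ramp solver found no sign change for z in "
                f"[{_Z_BRACKET[0]}, {_Z_BRACKET[1]}]",
                diagnostics={"gap_at_bracket": vals[ok][[0, -1]].tolist()},
            )
        if idx[0] == idx[1]:
            z = float(zs[idx[0]])
        else:
            z = float(
                optimize.brentq(gap, zs[idx[0]], zs[idx[1]], xtol=1e-12)
            )
        return z, self._implied_sct(a, z, t_ref)

    def fit(self, t_ref: float = 60.0) -> TDTResults:
        obs = self.observations
        pairs = {(o.t0, o.rate) for o in obs}
        if len(pairs) < 2:
            if (
                len(obs) == 2
                and len(pairs) == 1
                and obs[0].dctmax != obs[1].dctmax
            ):
                raise InconsistentInputError(
                    "two observations share a (t0, rate) condition with "
                    "conflicting dCT_max: the pair system is unsolvable"
                )
            raise InsufficientDataError(
                "dynamic fit needs >= 2 distinct (t0, rate) conditions"
            )

        if len(obs) == 2:
            z, ct_ref = self._solve_pair(obs[0], obs[1], t_ref)
            method = "dynamic-2pt"
        else:
            z, ct_ref = self._fit_nls(obs, t_ref)
            method = "dynamic-nls"

        curve = TDTCurve(
            z=z, ct_ref=ct_ref, t_ref=t_ref, tc_star=self.tc_star,
            provenance=f"{method} fit",
        )
        pred = np.array(
            [
                predict_ramp_outcome(curve, o.t0, o.rate, self._tc(o)).dctmax
                for o in obs
            ]
        )
        observed = np.array([o.dctmax for o in obs])
        resid = observed - pred
        if len(obs) > 2:
            ss_tot = float(np.sum((observed - observed.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else None
        else:
            r2 = None
        flags = []
        if not (_Z_BRACKET[0] <= z <= _Z_BRACKET[1]):
            flags.append("z-out-of-range")
        t_lds = np.array([(o.dctmax - o.t0) / o.rate for o in obs])
        return TDTResults(
            curve=curve,
            method=method,
            n_obs=len(obs),
            r_squared=r2,
            residuals=resid,
            temp_span=(float(min(o.t0 for o in obs)), float(observed.max())),
            time_span=(float(t_lds.min()), float(t_lds.max())),
            flags=flags,
        )

    def _fit_nls(self, obs, t_ref: float) -> tuple[float, float]:
        """Least squares on dCT_max over (z, ct_ref), initialized from the
        median of all pairwise exact solutions (deterministic)."""
        inits = []
        for i in range(len(obs)):
            for j in range(i + 1, len(obs)):
                if (obs[i].t0, obs[i].rate) == (obs[j].t0, obs[j].rate):
                    continue
                try:
                    inits.append(self._solve_pair(obs[i], obs[j], t_ref))
                except (ConvergenceError, InconsistentInputError):
                    continue
        if inits:
            z0 = float(np.median([p[0] for p in inits]))
            c0 = float(np.median([p[1] for p in inits]))
        else:
            z0, c0 = 4.0, float(np.median([o.dctmax for o in obs]))

        observed = np.array([o.dctmax for o in obs])

        def resid(theta):
            z, ct = theta
            curve = TDTCurve(z=z, ct_ref=ct, t_ref=t_ref)
            return (
                np.array(
                    [
                        predict_ramp_outcome(curve, o.t0, o.rate, self._tc(o)).dctmax
                        for o in obs
                    ]
                )
                - observed
            )

        sol = optimize.least_squares(
            resid,
            x0=[z0, c0],
            bounds=([1e-3, -100.0], [1e3, 200.0]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if not sol.success:
            raise ConvergenceError(
                f"dynamic least squares failed: {sol.message}",
                diagnostics={"x": sol.x.tolist(), "cost": float(sol.cost)},
            )
        return float(sol.x[0]), float(sol.x[1])


class SingleMeasurementModel:
    """Crude TDT curve from one measurement plus an assumed z.

    A single static or ramp measurement cannot identify the slope of the
    TDT line; supplying a thermal sensitivity borrowed from related taxa
    pins the line through the one observed point.  The resulting fit is
    flagged ``assumed-z`` and ``extrapolation-sensitive`` — errors in the
    assumed z amplify exponentially away from the anchor.
    """

    def __init__(
        self,
        measurement: StaticObservation | RampObservation,
        assumed_z: float,
    ):
        if not assumed_z > 0:
            raise TDTValidationError(f"assumed_z must be > 0, got {assumed_z!r}")
        self.measurement = measurement
        self.assumed_z = assumed_z

    def fit(self, t_ref: float = 60.0) -> TDTResults:
        m = self.measurement
        z = self.assumed_z
        if isinstance(m, StaticObservation):
            # line of slope -1/z through (temp, log10 time)
            ct_ref = m.temp + z * math.log10(m.time / t_ref)
            temp_span = (m.temp, m.temp)
            time_span = (m.time, m.time)
        elif isinstance(m, RampObservation):
            ct_ref = sctmax_from_ramp(m.dctmax, m.t0, m.rate, z, t_ref)
            t_ld = (m.dctmax - m.t0) / m.rate
            temp_span = (m.t0, m.dctmax)
            time_span = (t_ld, t_ld)
        else:
            raise TDTValidationError(
                "measurement must be a StaticObservation or RampObservation"
            )
        curve = TDTCurve(
            z=z, ct_ref=ct_ref, t_ref=t_ref,
            provenance=f"assumed-z ({z:g})",
        )
        return TDTResults(
            curve=curve,
            method="assumed-z",
            n_obs=1,
            r_squared=None,
            residuals=np.zeros(1),
            temp_span=temp_span,
            time_span=time_span,
            flags=["assumed-z", "extrapolation-sensitive"],
        )


@dataclass(frozen=True)
class HarmonizedValue:
    """An sCT_max estimate standardized to a common duration."""

    sctmax: float  # °C
    duration: float  # minutes
    method: str
    flags: tuple[str, ...]


def harmonize_to_reference(fit: TDTResults, duration: float = 60.0) -> HarmonizedValue:
    """Express a fit as the static temperature tolerated for ``duration``
    minutes (default: the common currency sCT_max(1 h)).

    Assumed-z fits keep their warning flags so downstream comparisons can
    distinguish properly fitted from assumed-slope values.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        sct = fit.predict_sctmax(duration)
    return HarmonizedValue(
        sctmax=sct,
        duration=duration,
        method=fit.method,
        flags=tuple(fit.flags),
    )
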