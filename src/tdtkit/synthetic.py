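"""Synthetic tolerance experiments from a known ground-truth curve.

Every fitting and integration path in the package can be exercised without
laboratory data by generating observations from a curve whose parameters
are known exactly:

* static assays — tolerance times on the curve, perturbed by log-normal
  noise (additive Gaussian noise on log10 time, the space in which the TDT
  regression operates);
* ramping assays — knockdown temperatures from the ramp closed form,
  perturbed by Gaussian noise in °C;
* fluctuating profiles — random heat/cool legs between bounds, emulating a
  water bath randomly programmed to warm or cool within a stressful band.

Inter-individual variation in real assays is not simply log-normal and the
noise here makes no claim to be a biological model; it is a stand-in
distribution chosen to live in the fitting space.  All generation is
bit-reproducible for a fixed seed (one named generator per call, no global
state).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import RampObservation, StaticObservation, TDTCurve
from .dose import TemperatureProfile
from .exceptions import TDTValidationError
from .prediction import predict_ramp_outcome, predict_time

__all__ = [
    "NoiseSpec",
    "gen_static_obs",
    "gen_ramp_obs",
    "gen_fluct_profile",
]

#: sampling interval of generated profiles: 10 s, in minutes
PROFILE_SAMPLE_DT = 1.0 / 6.0


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise magnitudes and the seed that fixes them.

    ``log10_time_sd`` perturbs static tolerance times (additive on log10
    minutes); ``dctmax_sd`` perturbs ramp knockdown temperatures (°C).
    """

    log10_time_sd: float = 0.0
    dctmax_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.log10_time_sd < 0 or self.dctmax_sd < 0:
            raise TDTValidationError("noise standard deviations must be >= 0")


def gen_static_obs(
    truth: TDTCurve,
    temps,
    n_per_temp: int = 1,
    noise: NoiseSpec = NoiseSpec(),
) -> list[StaticObservation]:
    """Static assay times drawn from ``truth`` at the given temperatures.

    ``time = predict_time(truth, T) * 10^eps`` with
    ``eps ~ N(0, log10_time_sd)``; zero sd puts times exactly on the curve.
    """
    if n_per_temp < 1:
        raise TDTValidationError("n_per_temp must be >= 1")
    rng = np.random.default_rng(noise.seed)
    out = []
    for T in temps:
        base = predict_time(truth, float(T))
        eps = rng.normal(0.0, noise.log10_time_sd, size=n_per_temp)
        for e in eps:
            out.append(StaticObservation(temp=float(T), time=base * 10.0**e))
    return out


def gen_ramp_obs(
    truth: TDTCurve,
    ramps,
    noise: NoiseSpec = NoiseSpec(),
) -> list[RampObservation]:
    """Ramp assay outcomes from ``truth`` for (t0, rate) pairs.

    ``dctmax`` is the closed-form prediction plus N(0, dctmax_sd) °C.
    """
    rng = np.random.default_rng(noise.seed)
    out = []
    for t0, rate in ramps:
        dct = predict_ramp_outcome(truth, float(t0), float(rate)).dctmax
        dct += rng.normal(0.0, noise.dctmax_sd)
        out.append(RampObservation(t0=float(t0), rate=float(rate), dctmax=dct))
    return out


def gen_fluct_profile(
    t_min: float,
    t_max: float,
    duration: float,
    switch_mean: float = 10.0,
    rate_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
) -> TemperatureProfile:
    """Randomly fluctuating temperature profile between two bounds.

    Alternating heating and cooling legs: leg durations are exponentially
    distributed (mean ``switch_mean`` minutes), leg rates drawn uniformly
    from ``rate_range`` (°C/min), and the trace reflects at the bounds so
    every sample stays in [t_min, t_max].  Sampled every 10 s; the starting
    temperature is the midpoint of the band and the first leg heats.
    """
    if t_min > t_max:
        raise TDTValidationError("t_min must not exceed t_max")
    if not duration > 0:
        raise TDTValidationError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration / PROFILE_SAMPLE_DT))
    times = PROFILE_SAMPLE_DT * np.arange(n + 1)
    if t_min == t_max:
        return TemperatureProfile(times=times, temps=np.full(n + 1, t_min))

    temps = np.empty(n + 1)
    temps[0] = 0.5 * (t_min + t_max)
    direction = 1.0
    leg_left = rng.exponential(switch_mean)
    rate = rng.uniform(*rate_range)
    for i in range(1, n + 1):
        step = PROFILE_SAMPLE_DT
        T = temps[i - 1] + direction * rate * step
        # reflect at the band edges
        if T > t_max:
            T = t_max - (T - t_max)
            direction = -1.0
        elif T < t_min:
            T = t_min + (t_min - T)
            direction = 1.0
        temps[i] = min(max(T, t_min), t_max)
        leg_left -= step
        if leg_left <= 0:
            direction = -direction
            leg_left = rng.exponential(switch_mean)
            rate = rng.uniform(*rate_range)
    return TemperatureProfile(times=times, temps=temps)
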