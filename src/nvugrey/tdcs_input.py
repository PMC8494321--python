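"""tDCS stimulus construction and the first-order vasoactive filter.

The scalp current is a trapezoid (ramp up, plateau, ramp down).  Each
perturbation pathway sees it through a first-order low-pass

    v_i(s) = K_i / (s tau + 1) * I_tdcs(s)

with unit DC gain shaped by the lead-field gain ``K_i`` and a passive
membrane time constant ``tau`` (default 20 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass
class StimulusWaveform:
    """Trapezoidal tDCS current waveform sampled uniformly.

    ``amplitude`` is in mA unless ``normalized`` is set, in which case the
    peak is scaled to 1.
    """

    amplitude: float = 2.0
    ramp_up: float = 30.0
    plateau: float = 540.0
    ramp_down: float = 30.0
    onset: float = 0.0
    sampling_rate: float = 10.0
    normalized: bool = False

    def __post_init__(self):
        if min(self.ramp_up, self.plateau, self.ramp_down) < 0:
            raise ValidationError("ramps and plateau must be non-negative")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return self.onset + self.ramp_up + self.plateau + self.ramp_down

    @property
    def area(self) -> float:
        """Analytic current-time integral in mA*s (trapezoid area)."""
        a = 1.0 if self.normalized else self.amplitude
        return a * (self.plateau + 0.5 * (self.ramp_up + self.ramp_down))

    def sample(self, t_end: float | None = None):
        """Return (t, I) sampled at ``sampling_rate`` up to ``t_end``."""
        t_end = self.duration if t_end is None else t_end
        t = np.arange(0.0, t_end + 0.5 / self.sampling_rate, 1.0 / self.sampling_rate)
        return t, self.value(t)

    def value(self, t) -> np.ndarray:
        """Piecewise-linear waveform value at arbitrary times."""
        t = np.asarray(t, dtype=float)
        a = 1.0 if self.normalized else self.amplitude
        u = t - self.onset
        out = np.zeros_like(u)
        if self.ramp_up > 0:
            out = np.where((u >= 0) & (u < self.ramp_up), a * u / self.ramp_up, out)
        t1 = self.ramp_up
        t2 = t1 + self.plateau
        t3 = t2 + self.ramp_down
        out = np.where((u >= t1) & (u < t2), a, out)
        if self.ramp_down > 0:
            out = np.where((u >= t2) & (u < t3),
                           a * (t3 - u) / self.ramp_down, out)
        # closed ends: exactly at the plateau edges the value is a
        out = np.where(u == t2, a, out)
        return out

    def normalize(self) -> "StimulusWaveform":
        return StimulusWaveform(1.0, self.ramp_up, self.plateau, self.ramp_down,
                                self.onset, self.sampling_rate, normalized=True)


def trapezoid(amplitude: float, ramp_up: float, plateau: float,
              ramp_down: float, onset: float = 0.0,
              rate: float = 10.0) -> StimulusWaveform:
    """Build a trapezoidal stimulus; validates durations and rate."""
    return StimulusWaveform(amplitude, ramp_up, plateau, ramp_down, onset, rate)


@dataclass
class VasoactiveFilter:
    """First-order low-pass mapping scalp current to a pathway perturbation."""

    K_i: float = 1.0      # lead-field gain (dimensionless, absorbed by PEM)
    tau: float = 0.02     # passive membrane time constant (s)

    def __post_init__(self):
        if self.tau <= 0:
            raise ValidationError("tau must be positive")

    def pole(self) -> float:
        return -1.0 / self.tau

    def tf(self):
        """Continuous transfer function coefficients (num, den)."""
        return [self.K_i / self.tau], [1.0, 1.0 / self.tau]


def vasoactive_signal(stimulus: StimulusWaveform, filt: VasoactiveFilter,
                      t_end: float | None = None):
    """Filter the stimulus through the first-order vasoactive transfer function.

    Uses the exact first-order-hold discretization at the stimulus sampling
    rate (the input is piecewise linear, so this is exact at the sample
    instants regardless of how tau compares with the sample period).

    Returns
    -------
    (t, v) : uniformly sampled times and perturbation series
    """
    t, u = stimulus.sample(t_end)
    dt = 1.0 / stimulus.sampling_rate
    a = math.exp(-dt / filt.tau)
    # exact response to a linear segment u(s) = u_k + (u_{k+1}-u_k) s/dt:
    #   y_{k+1} = a y_k + K (1-a) u_k + K (dt - tau(1-a))/dt (u_{k+1}-u_k)
    c0 = filt.K_i * (1.0 - a)
    c1 = filt.K_i * (dt - filt.tau * (1.0 - a)) / dt
    v = np.empty_like(u)
    v[0] = 0.0
    for i in range(len(u) - 1):
        v[i + 1] = a * v[i] + c0 * u[i] + c1 * (u[i + 1] - u[i])
    return t, v
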