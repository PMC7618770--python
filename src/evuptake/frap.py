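"""Single-exponential FRAP (fluorescence recovery after photobleaching) fitting.

After bleaching a small region, fluorescence recovers as mobile fluorophore
diffuses back in: F(t) = F0 + A*(1 - exp(-(t - t0)/tau)).  The mobile fraction
is the recovered amplitude A relative to the bleached span (baseline - F0); the
remainder is immobile emitter (anchored molecules or signal confined to
organellar structures).  A single time constant is fitted, consistent with
recovery of a small freely diffusing protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FRAPTrace", "FRAPFit", "FitError", "fit_recovery"]


class FitError(RuntimeError):
    """Raised when the recovery fit fails to converge."""


@dataclass
class FRAPTrace:
    """A bleach time series: times in seconds, intensities in arbitrary units.

    ``bleach_index`` is the index of the first post-bleach sample.
    """

    time: np.ndarray
    intensity: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape or self.time.ndim != 1:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time points must be strictly increasing")
        if not 0 < self.bleach_index < self.time.size:
            raise ValueError("bleach_index out of range (need >=1 pre-bleach sample)")
        if self.time.size - self.bleach_index < 5:
            raise ValueError("need at least 5 post-bleach samples")

    @property
    def pre(self) -> tuple[np.ndarray, np.ndarray]:
        return self.time[: self.bleach_index], self.intensity[: self.bleach_index]

    @property
    def post(self) -> tuple[np.ndarray, np.ndarray]:
        return self.time[self.bleach_index :], self.intensity[self.bleach_index :]


@dataclass
class FRAPFit:
    tau: float  # seconds
    mobile_fraction: float
    baseline: float
    bleach_floor: float  # fitted F0
    residual_rms: float

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.mobile_fraction


def _model(t, f0, a, tau, t0):
    return f0 + a * (1.0 - np.exp(-(t - t0) / tau))


def fit_recovery(trace: FRAPTrace) -> FRAPFit:
    """Least-squares single-exponential fit of the post-bleach recovery.

    The baseline is the mean of all pre-bleach samples.  Initial guesses come
    from curve geometry: F0 from the first post-bleach sample, amplitude from
    the last, and tau from the time to half of the observed recovery divided
    by ln 2.
    """
    t_post, y_post = trace.post
    baseline = float(np.mean(trace.pre[1]))
    t0 = float(t_post[0])

    f0_guess = float(y_post[0])
    a_guess = float(y_post[-1] - y_post[0])
    tau_guess = (t_post[-1] - t0) / 3.0
    if a_guess > 0:
        half = f0_guess + a_guess / 2.0
        above = np.nonzero(y_post >= half)[0]
        if above.size and above[0] > 0:
            tau_guess = max((t_post[above[0]] - t0) / np.log(2.0), 1e-6)

    try:
        popt, _ = curve_fit(
            lambda t, f0, a, tau: _model(t, f0, a, tau, t0),
            t_post,
            y_post,
            p0=[f0_guess, a_guess, max(tau_guess, 1e-6)],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - depends on optimizer path
        raise FitError(f"recovery fit did not converge: {exc}") from exc

    f0, a, tau = (float(v) for v in popt)
    span = baseline - f0
    if a < 0:
        warnings.warn("fitted recovery amplitude is negative; mobile fraction clamped to 0")
        mobile = 0.0
    elif span <= 0:
        warnings.warn("bleach floor not below baseline; mobile fraction undefined, set to 0")
        mobile = 0.0
    else:
        mobile = float(np.clip(a / span, 0.0, 1.0))
    resid = y_post - _model(t_post, f0, a, tau, t0)
    return FRAPFit(
        tau=tau,
        mobile_fraction=mobile,
        baseline=baseline,
        bleach_floor=f0,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
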