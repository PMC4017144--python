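"""Hemodynamic response function (HRF) kernels and the BOLD convolution model.

The BOLD fMRI signal is modelled as a causal convolution of the neuronal
time series with a region-specific hemodynamic response function,

    y_i(t) = sum_{k=1}^{L} h_i(k) z_i(t - k + 1) + noise,

where ``h_i`` is a sampled kernel of length ``L``.  Kernels are double-gamma
shapes: a positive response lobe followed by a smaller negative undershoot.
The canonical kernel peaks at 5 s with a post-peak minimum at 15.75 s; the
randomized variant draws the time-to-peak uniformly on [2.5, 6.5] s while
holding the undershoot-delay parameter at 16 s, which places the negative
peak in [15, 16.7] s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HRFKernel", "canonical_hrf", "random_hrf", "convolve_hrf"]

#: peak-to-undershoot amplitude ratio of the conventional double-gamma shape
UNDERSHOOT_RATIO = 6.0
#: response-delay parameter of the canonical kernel (gamma shape, unit rate);
#: a unit-rate gamma density with shape a peaks at t = a - 1, hence 5 s
CANONICAL_RESPONSE_DELAY = 6.0
#: undershoot-delay parameter, held fixed also for randomized kernels
UNDERSHOOT_DELAY = 16.0
DEFAULT_DURATION = 30.0

#: range of the randomized time-to-positive-peak, in seconds
RANDOM_PEAK_RANGE = (2.5, 6.5)


@dataclass(frozen=True, eq=False)
class HRFKernel:
    """A sampled hemodynamic response function.

    Attributes
    ----------
    samples : ndarray, shape (L,)
        Kernel amplitudes on a regular grid, normalized to unit positive peak.
    dt : float
        Seconds per sample.
    peak_time : float
        Grid time of the global (positive) maximum, seconds.
    undershoot_time : float
        Grid time of the post-peak (negative) minimum, seconds.
    """

    samples: np.ndarray
    dt: float
    peak_time: float
    undershoot_time: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("kernel samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return len(self) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt


def _double_gamma(
    dt: float,
    duration: float,
    response_delay: float,
    undershoot_delay: float = UNDERSHOOT_DELAY,
    ratio: float = UNDERSHOOT_RATIO,
) -> HRFKernel:
    """Amplitude-normalized difference of two unit-rate gamma densities."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least dt")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    h = stats.gamma.pdf(t, a=response_delay) - stats.gamma.pdf(
        t, a=undershoot_delay
    ) / ratio
    h = h / h.max()
    ipeak = int(np.argmax(h))
    imin = ipeak + int(np.argmin(h[ipeak:]))
    return HRFKernel(
        samples=h,
        dt=dt,
        peak_time=t[ipeak],
        undershoot_time=t[imin],
    )


def canonical_hrf(dt: float, duration: float = DEFAULT_DURATION) -> HRFKernel:
    """Canonical double-gamma HRF: peak at 5 s, undershoot minimum at 15.75 s.

    Parameters
    ----------
    dt : float
        Sampling interval in seconds (the TR of the data grid).
    duration : float
        Total kernel length in seconds; ``L = round(duration / dt)`` samples.
    """
    return _double_gamma(dt, duration, CANONICAL_RESPONSE_DELAY)


def random_hrf(
    rng: np.random.Generator | int | None,
    dt: float,
    duration: float = DEFAULT_DURATION,
    peak_range: tuple[float, float] = RANDOM_PEAK_RANGE,
) -> HRFKernel:
    """Draw a double-gamma HRF with randomized time-to-peak.

    The time of the positive peak is uniform on ``peak_range`` (default
    [2.5, 6.5] s, the range of peak positions reported across cortical
    regions); the undershoot-delay parameter stays at 16 s, so the negative
    peak lands between 15 and 16.7 s depending on the response delay.
    """
    rng = np.random.default_rng(rng)
    low, high = peak_range
    time_to_peak = rng.uniform(low, high)
    # unit-rate gamma density peaks at (shape - 1)
    return _double_gamma(dt, duration, response_delay=time_to_peak + 1.0)


def convolve_hrf(series: np.ndarray, kernel: HRFKernel, dt: float | None = None) -> np.ndarray:
    """Causal convolution of a neuronal series with an HRF kernel.

    ``out(t) = sum_{k=1}^{L} h(k) series(t - k + 1)`` with out-of-range input
    treated as zero; ``h(1)`` multiplies the current sample.  Output has the
    same length as the input.  Accepts a 1-D series of length T or an (N, T)
    array (convolved along the last axis).

    Parameters
    ----------
    dt : float, optional
        Sampling interval of ``series``; if given it must match ``kernel.dt``.
    """
    if dt is not None and not np.isclose(dt, kernel.dt, rtol=1e-9, atol=1e-12):
        raise ValueError(
            f"series sampling interval {dt} does not match kernel dt {kernel.dt}"
        )
    series = np.asarray(series, dtype=float)
    h = kernel.samples
    if series.ndim == 1:
        return np.convolve(series, h)[: series.shape[0]]
    if series.ndim == 2:
        T = series.shape[1]
        return np.stack([np.convolve(row, h)[:T] for row in series])
    raise ValueError("series must be 1-D or 2-D")
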