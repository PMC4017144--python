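"""Synthetic fMRI benchmark generators.

Two families of datasets are produced:

* random sparse networks: a VAR(P) process on N regions where ceil(N/2)
  unidirectional connections are activated with lag coefficients drawn
  N(0, 0.05); each region is convolved with the canonical HRF on a 1 Hz grid
  and i.i.d. Gaussian noise is added at a requested SNR;
* two-node delay/TR sweeps: a two-region process simulated at 1 kHz for
  240 s with self-coefficients 0.95 at lag 1 and a single cross coefficient
  of magnitude Uniform[0.4, 0.9] at a lag equal to the neuronal delay in
  milliseconds, convolved with fixed or randomized HRFs, decimated to a
  target TR, and degraded with noise at a requested SNR.

The SNR convention is SNR_dB = 10 log10( sum_t ||y(t) - ybar||^2 / (N T sigma^2) )
with ybar the per-region temporal mean of the noiseless series; the noise
variance solving that identity is returned alongside the data, since the
estimator treats it as the known noise level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, lfilter

from .hrf import HRFKernel, canonical_hrf, _double_gamma
from .var import VARParameters, simulate_var, spectral_radius, STABILITY_THRESHOLD

__all__ = [
    "SyntheticDataset",
    "generate_random_network",
    "random_network_dataset",
    "rescale_rms",
    "add_noise_snr",
    "downsample",
    "two_node_dataset",
]

#: variance of the activated VAR coefficients in random networks
COEFF_VARIANCE = 0.05
#: default RMS normalization target (mean squared amplitude)
RMS_TARGET = 6.0

HRF_MODES = ("fixed", "random", "return_true_hrf")


@dataclass
class SyntheticDataset:
    """A ground-truth neuronal series with its simulated fMRI observation.

    ``truth_directed`` holds ordered (source, target) pairs; an edge (j, i)
    corresponds to nonzero coefficients a_ij across lags (influence j -> i).
    ``hrfs`` are the kernels on the observation grid that an estimator should
    assume (for randomized-HRF modes these may deliberately differ from the
    kernels used to generate the data).
    """

    neuronal: np.ndarray
    observed: np.ndarray
    tr: float
    hrfs: list[HRFKernel]
    truth_directed: set[tuple[int, int]]
    truth_params: VARParameters
    noise_variance: float
    meta: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return self.observed.shape[0]


def rescale_rms(Y: np.ndarray, target: float = RMS_TARGET) -> tuple[np.ndarray, float]:
    """Scale a series so its mean squared amplitude equals ``target``.

    The normalization constant is sum_t ||y(t)||^2 / (N T), i.e. the mean of
    squared sample norms; returns the scaled series and the applied factor.
    """
    Y = np.asarray(Y, dtype=float)
    power = float(np.mean(Y**2))
    if power == 0.0:
        raise ValueError("cannot rescale an all-zero series")
    factor = math.sqrt(target / power)
    return Y * factor, factor


def add_noise_snr(
    Y: np.ndarray, snr_db: float, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, float]:
    """Add i.i.d. Gaussian noise at the requested SNR; returns (noisy, sigma^2)."""
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("series must be finite")
    centered = Y - Y.mean(axis=-1, keepdims=True)
    power = float(np.mean(centered**2))
    if power == 0.0:
        raise ValueError("constant series has zero signal power; SNR undefined")
    sigma2 = power / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(rng)
    noisy = Y + rng.normal(scale=math.sqrt(sigma2), size=Y.shape)
    return noisy, sigma2


def downsample(series: np.ndarray, k: int) -> np.ndarray:
    """Pure decimation by integer factor k (no anti-alias filter)."""
    series = np.asarray(series)
    if k < 1:
        raise ValueError("decimation factor must be >= 1")
    T = series.shape[-1]
    if k > T:
        raise ValueError(f"decimation factor {k} exceeds series length {T}")
    m = T // k
    return series[..., : m * k : k]


def _sample_unidirectional_edges(
    n: int, n_edges: int, rng: np.random.Generator
) -> set[tuple[int, int]]:
    """Draw distinct unordered pairs and orient each at random."""
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    idx = rng.choice(len(pairs), size=n_edges, replace=False)
    edges = set()
    for m in idx:
        i, j = pairs[m]
        if rng.random() < 0.5:
            edges.add((i, j))  # i -> j
        else:
            edges.add((j, i))
    return edges


def generate_random_network(
    N: int,
    P: int = 2,
    T: int = 500,
    rng: np.random.Generator | int | None = None,
    coeff_variance: float = COEFF_VARIANCE,
    max_tries: int = 100,
) -> SyntheticDataset:
    """Random sparse network with ceil(N/2) unidirectional connections (pre-noise).

    For each activated ordered pair (j, i) all P lag coefficients a_ij^(p)
    are drawn zero-mean Gaussian with variance ``coeff_variance``; all other
    coefficients are exactly zero and the innovation precision is identity.
    Unstable draws (companion spectral radius >= 0.999) are rejected and
    resampled.  The neuronal series is convolved per region with the
    canonical HRF on a 1 Hz grid (L = 30) to form the noiseless observation.
    """
    if N < 2:
        raise ValueError("a network needs at least 2 regions")
    if P < 1:
        raise ValueError("VAR order must be >= 1")
    rng = np.random.default_rng(rng)
    n_edges = math.ceil(N / 2)
    std = math.sqrt(coeff_variance)
    for attempt in range(1, max_tries + 1):
        edges = _sample_unidirectional_edges(N, n_edges, rng)
        coeffs = np.zeros((P, N, N))
        for (j, i) in edges:
            coeffs[:, i, j] = rng.normal(scale=std, size=P)
        params = VARParameters(coeffs=coeffs, innovation_precision=np.eye(N))
        if spectral_radius(params) < STABILITY_THRESHOLD:
            break
    else:
        raise RuntimeError(f"no stable network found in {max_tries} draws")
    neuronal = simulate_var(params, T, rng)
    kernel = canonical_hrf(dt=1.0, duration=30.0)
    observed = np.stack([np.convolve(row, kernel.samples)[:T] for row in neuronal])
    return SyntheticDataset(
        neuronal=neuronal,
        observed=observed,
        tr=1.0,
        hrfs=[kernel] * N,
        truth_directed=edges,
        truth_params=params,
        noise_variance=0.0,
        meta={"stability_attempts": attempt, "P": P},
    )


def random_network_dataset(
    N: int,
    P: int = 2,
    T: int = 500,
    snr_db: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> SyntheticDataset:
    """Random network with additive noise at ``snr_db``; the full generator."""
    rng = np.random.default_rng(rng)
    ds = generate_random_network(N, P=P, T=T, rng=rng)
    ds.observed, ds.noise_variance = add_noise_snr(ds.observed, snr_db, rng)
    ds.meta["snr_db"] = snr_db
    return ds


def two_node_dataset(
    delay_ms: float,
    tr_s: float,
    hrf_mode: str = "fixed",
    snr_db: float = 0.0,
    rng: np.random.Generator | int | None = None,
    duration_s: float = 240.0,
    self_coeff: float = 0.95,
    coupling_range: tuple[float, float] = (0.4, 0.9),
    burn_in: int = 2000,
) -> SyntheticDataset:
    """Two-region dataset probing downsampling and HRF-variability effects.

    The neuronal process runs at 1 kHz for ``duration_s`` seconds; both
    regions have self-coefficient ``self_coeff`` at lag 1 and one cross
    coefficient of magnitude Uniform over ``coupling_range`` sits at lag
    ``d = delay_ms`` in a randomly chosen direction.  Innovations are unit
    variance i.i.d. Gaussian.  Each region is convolved with its HRF at
    1 kHz, decimated to ``tr_s``, and noise is added at ``snr_db``.
    """
    fs = 1000.0
    if delay_ms < 1:
        raise ValueError("delay must be at least 1 ms")
    d = int(round(delay_ms))
    if abs(delay_ms - d) > 1e-9:
        warnings.warn("delay rounded to the nearest millisecond", stacklevel=2)
    k = int(round(tr_s * fs))
    if abs(tr_s * fs - k) > 1e-6 or k < 1:
        raise ValueError("TR must be a positive multiple of 1 ms")
    T_n = int(round(duration_s * fs))
    if d >= T_n:
        raise ValueError("delay exceeds the simulation length")
    if hrf_mode not in HRF_MODES:
        raise ValueError(f"hrf_mode must be one of {HRF_MODES}")
    rng = np.random.default_rng(rng)

    source = int(rng.integers(2))  # region exerting the influence
    target = 1 - source
    coupling = float(rng.uniform(*coupling_range))

    total = T_n + burn_in
    innov = rng.standard_normal((2, total))
    ar = [1.0, -self_coeff]
    s_src = lfilter([1.0], ar, innov[source])
    drive = np.zeros(total)
    drive[d:] = coupling * s_src[:-d]
    s_tgt = lfilter([1.0], ar, innov[target] + drive)
    neuronal = np.empty((2, total))
    neuronal[source] = s_src
    neuronal[target] = s_tgt
    neuronal = neuronal[:, burn_in:]

    sim_dt = 1.0 / fs
    if hrf_mode == "fixed":
        sim_kernels = [canonical_hrf(sim_dt)] * 2
        fit_kernels = [canonical_hrf(tr_s)] * 2
    else:
        peaks = rng.uniform(2.5, 6.5, size=2)
        sim_kernels = [_double_gamma(sim_dt, 30.0, tp + 1.0) for tp in peaks]
        if hrf_mode == "return_true_hrf":
            fit_kernels = [_double_gamma(tr_s, 30.0, tp + 1.0) for tp in peaks]
        else:
            fit_kernels = [canonical_hrf(tr_s)] * 2

    bold = np.stack(
        [
            fftconvolve(row, kern.samples)[:T_n]
            for row, kern in zip(neuronal, sim_kernels)
        ]
    )
    observed = downsample(bold, k)
    observed, sigma2 = add_noise_snr(observed, snr_db, rng)

    coeffs = np.zeros((d, 2, 2))
    coeffs[0, 0, 0] = coeffs[0, 1, 1] = self_coeff
    coeffs[d - 1, target, source] = coupling
    params = VARParameters(coeffs=coeffs, innovation_precision=np.eye(2))

    return SyntheticDataset(
        neuronal=neuronal,
        observed=observed,
        tr=tr_s,
        hrfs=fit_kernels,
        truth_directed={(source, target)},
        truth_params=params,
        noise_variance=sigma2,
        meta={
            "delay_ms": float(d),
            "snr_db": snr_db,
            "hrf_mode": hrf_mode,
            "coupling": coupling,
            "decimation": k,
        },
    )
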