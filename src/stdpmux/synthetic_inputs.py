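"""Synthetic pre-synaptic input generation.

Each pre-synaptic population is a ring of ``N`` inhomogeneous Poisson neurons
with evenly spaced preferred phases ``phi_k = 2*pi*k/N`` and instantaneous
rate ``D(t) * (1 + gamma * cos(nu*t - phi_k))``, where the stimulus intensity
``D(t)`` is piecewise constant, resampled independently per population every
``refresh_period`` (default 1 s).  Spikes are drawn per 1 ms bin as a
Bernoulli approximation with ``p = rate * bin``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationSpec",
    "IntensityTrace",
    "SpikeRaster",
    "sample_intensities",
    "rate_profile",
    "generate_spike_raster",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One rhythmic pre-synaptic population.

    Parameters
    ----------
    size
        Number of neurons ``N`` on the ring.
    freq_hz
        Oscillation frequency ``nu/(2*pi)`` in Hz.
    gamma
        Modulation-to-mean ratio in ``[0, 1]``.
    intensity_mean
        Mean stimulus intensity ``D`` in Hz.
    intensity_model
        ``"uniform_offset"`` — ``D_min + U(0, D_range)`` resampled each refresh
        period (the default reproduces 7 + U(0,6) Hz); ``"fixed"`` — constant
        ``intensity_mean``.
    sigma
        Relative intensity SD used by *analytic* routines (mean-field /
        stability).  Kept independent of the sampling model on purpose; use
        :meth:`implied_sigma` to get the value the uniform_offset model
        actually realizes.
    """

    size: int
    freq_hz: float
    gamma: float = 1.0
    intensity_mean: float = 10.0
    intensity_model: str = "uniform_offset"
    intensity_min: float = 7.0
    intensity_range: float = 6.0
    sigma: float = 0.6

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if self.intensity_mean <= 0:
            raise ValueError("intensity_mean must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.intensity_model not in ("uniform_offset", "fixed"):
            raise ValueError("intensity_model must be 'uniform_offset' or 'fixed'")

    @property
    def nu(self) -> float:
        """Angular frequency in rad/s."""
        return 2.0 * math.pi * self.freq_hz

    @property
    def phases(self) -> np.ndarray:
        """Preferred phases ``2*pi*k/size`` for ``k = 0..size-1``."""
        return 2.0 * math.pi * np.arange(self.size) / self.size

    def implied_sigma(self) -> float:
        """Relative intensity SD realized by the sampling model.

        ``uniform_offset`` gives ``sqrt(range**2/12) / (min + range/2)``;
        ``fixed`` gives 0.  This generally differs from :attr:`sigma`, which
        is the analytic knob.
        """
        if self.intensity_model == "fixed":
            return 0.0
        mean = self.intensity_min + self.intensity_range / 2.0
        return (self.intensity_range / math.sqrt(12.0)) / mean


@dataclass
class IntensityTrace:
    """Piecewise-constant intensity processes, one column per population."""

    times: np.ndarray  # refresh instants, shape (n_periods,)
    values: np.ndarray  # Hz, shape (n_periods, n_populations)
    refresh_period: float = 1.0

    def value_at(self, t: float, population: int = 0) -> float:
        idx = min(int(t / self.refresh_period), len(self.times) - 1)
        return float(self.values[idx, population])

    def column(self, population: int) -> np.ndarray:
        return self.values[:, population]


@dataclass
class SpikeRaster:
    """Spike times of one population; ``spikes[k]`` is neuron k's sorted times (s)."""

    spikes: list
    population_id: int
    duration: float
    bin_width: float = 1e-3

    @property
    def size(self) -> int:
        return len(self.spikes)

    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spikes])


def sample_intensities(
    specs, duration: float, rng, refresh_period: float = 1.0
) -> IntensityTrace:
    """Draw independent piecewise-constant intensities for each population.

    One draw per population per refresh period; the uniform_offset model has
    mean ``min + range/2`` and variance ``range**2/12``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(specs, PopulationSpec):
        specs = [specs]
    rng = np.random.default_rng(rng)
    n = int(math.ceil(duration / refresh_period))
    times = np.arange(n) * refresh_period
    cols = []
    for spec in specs:
        if spec.intensity_model == "fixed":
            cols.append(np.full(n, spec.intensity_mean))
        else:
            cols.append(spec.intensity_min + rng.uniform(0.0, spec.intensity_range, n))
    return IntensityTrace(times=times, values=np.column_stack(cols), refresh_period=refresh_period)


def rate_profile(spec: PopulationSpec, intensity: float, t, k: int):
    """Instantaneous rate ``D*(1 + gamma*cos(nu*t - phi_k))`` in Hz."""
    if not 0 <= k < spec.size:
        raise ValueError(f"neuron index {k} outside [0, {spec.size})")
    t = np.asarray(t, dtype=float)
    out = intensity * (1.0 + spec.gamma * np.cos(spec.nu * t - spec.phases[k]))
    return float(out) if out.ndim == 0 else out


def _bin_rates(spec: PopulationSpec, intensity: IntensityTrace, population: int,
               duration: float, bin_s: float) -> np.ndarray:
    """Per-bin rates, shape (n_bins, N).  Rate evaluated at bin centers."""
    n_bins = int(round(duration / bin_s))
    t = (np.arange(n_bins) + 0.5) * bin_s
    idx = np.minimum((t / intensity.refresh_period).astype(int), len(intensity.times) - 1)
    d = intensity.values[idx, population]
    # rates(t, k) = D(t) * (1 + gamma cos(nu t - phi_k))
    mod = 1.0 + spec.gamma * np.cos(spec.nu * t[:, None] - spec.phases[None, :])
    return d[:, None] * mod


def generate_spike_raster(
    spec: PopulationSpec,
    intensity: IntensityTrace,
    duration: float,
    bin_s: float = 1e-3,
    rng=None,
    population: int = 0,
) -> SpikeRaster:
    """Bernoulli-approximated inhomogeneous Poisson raster.

    One independent draw per neuron per bin with ``p = rate * bin_s``; raises
    if any ``p >= 1`` (no silent thinning).  Deterministic for a fixed ``rng``
    seed.
    """
    rng = np.random.default_rng(rng)
    rates = _bin_rates(spec, intensity, population, duration, bin_s)
    p = rates * bin_s
    if np.any(p >= 1.0):
        bad = np.argwhere(p >= 1.0)[0]
        raise ValueError(
            f"spike probability >= 1 in bin {int(bad[0])} (t={bad[0] * bin_s:.3f}s), "
            f"neuron {int(bad[1])}: decrease bin_s"
        )
    hits = rng.random(p.shape) < p
    centers = (np.arange(p.shape[0]) + 0.5) * bin_s
    spikes = [centers[hits[:, k]] for k in range(spec.size)]
    return SpikeRaster(spikes=spikes, population_id=population, duration=duration, bin_width=bin_s)
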