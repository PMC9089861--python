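"""Stimulus generators: DC steps, EPSP-shaped currents, Ornstein-Uhlenbeck
background current, and Poisson burst trains of presynaptic spikes.

All stochastic generators are pure functions of their parameters and seed.
Currents are in nA, times in ms unless stated otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "DCStep",
    "EPSPCurrent",
    "OUCurrent",
    "BurstTrain",
    "epsp_waveform",
    "sample_ou",
    "sample_burst_train",
    "calibrate_ou_to_rate",
    "realize_stimuli",
]


@dataclass
class DCStep:
    """Constant current step: ``amplitude`` nA within [delay, delay+duration]."""

    amplitude: float  # nA
    delay: float = 250.0  # ms
    duration: float = 500.0  # ms
    comp: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    def waveform(self, n_steps: int, dt: float) -> np.ndarray:
        t = np.arange(n_steps) * dt
        out = np.zeros(n_steps)
        out[(t >= self.delay) & (t < self.delay + self.duration)] = self.amplitude
        return out


def epsp_waveform(t, amplitude: float, tau_rise: float = 1.0,
                  tau_decay: float = 10.0) -> np.ndarray:
    """Normalized double-exponential current, zero for t < 0.

    The difference exp(-t/τd) - exp(-t/τr) is rescaled so its maximum equals
    ``amplitude``; the peak occurs at t* = τr τd / (τd - τr) · ln(τd/τr).
    """
    if not tau_decay > tau_rise > 0:
        raise ValueError("need tau_decay > tau_rise > 0")
    t = np.asarray(t, dtype=float)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    norm = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    out = np.where(
        t >= 0.0,
        (np.exp(-np.maximum(t, 0.0) / tau_decay) - np.exp(-np.maximum(t, 0.0) / tau_rise))
        / norm * amplitude,
        0.0,
    )
    return out


@dataclass
class EPSPCurrent:
    """EPSP-shaped injected current (double exponential, 1/10 ms by default)."""

    amplitude: float  # nA, peak
    onset: float = 0.0  # ms
    tau_rise: float = 1.0
    tau_decay: float = 10.0
    comp: int = 0

    def waveform(self, n_steps: int, dt: float) -> np.ndarray:
        t = np.arange(n_steps) * dt - self.onset
        return epsp_waveform(t, self.amplitude, self.tau_rise, self.tau_decay)


def sample_ou(mean: float, sigma: float, tau: float, duration: float, dt: float,
              seed: Optional[int] = None, x0: Optional[float] = None) -> np.ndarray:
    """Sample an OU process by its exact discretization (AR(1)).

    x_{n+1} = mean + (x_n - mean) e^{-dt/τ} + σ √(1 - e^{-2dt/τ}) ξ_n.
    The stationary law has the requested mean and SD; the initial value is
    drawn from it unless ``x0`` is given.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if dt >= tau:
        warnings.warn("dt >= tau: OU discretization is biased", stacklevel=2)
    n = int(round(duration / dt))
    rho = math.exp(-dt / tau)
    sqrt_term = sigma * math.sqrt(1.0 - rho * rho)
    rng = np.random.default_rng(seed)
    x = mean + sigma * rng.standard_normal() if x0 is None else x0
    if sigma == 0.0:
        return np.full(n, mean)
    # AR(1) recursion as an IIR filter: y_n = rho y_{n-1} + sqrt_term ξ_n
    from scipy.signal import lfilter

    noise = sqrt_term * rng.standard_normal(n)
    noise[0] = x - mean  # start from the (possibly stationary) initial value
    y, _ = lfilter([1.0], [1.0, -rho], noise, zi=[0.0])
    return mean + y


@dataclass
class OUCurrent:
    """Ornstein-Uhlenbeck background current mimicking in-vivo synaptic drive."""

    mean: float  # nA
    sigma: float  # nA
    tau: float = 3.0  # ms
    comp: int = 0
    seed: Optional[int] = None

    def waveform(self, n_steps: int, dt: float, seed: Optional[int] = None) -> np.ndarray:
        use = self.seed if self.seed is not None else seed
        return sample_ou(self.mean, self.sigma, self.tau, n_steps * dt, dt, seed=use)


def sample_burst_train(burst_rate: float = 2.0, intra_rate: float = 100.0,
                       duration: float = 10.0,
                       spikes_per_burst_law: Optional[Callable] = None,
                       seed: Optional[int] = None,
                       merge_overlaps: bool = True) -> dict:
    """Poisson bursts of Poisson spikes (times in seconds).

    Burst onsets follow a homogeneous Poisson process at ``burst_rate`` Hz;
    each burst contains a number of spikes drawn from ``spikes_per_burst_law``
    (default: uniform integer 2..8) whose inter-spike gaps are
    Exponential(``intra_rate``); the onset is the first spike of the burst.
    Overlapping bursts are merged (their spikes pooled under the earlier
    onset) unless ``merge_overlaps`` is False, in which case they are kept
    and flagged in the returned dict.
    """
    if burst_rate <= 0 or intra_rate <= 0 or duration <= 0:
        raise ValueError("rates and duration must be > 0")
    rng = np.random.default_rng(seed)
    if spikes_per_burst_law is None:
        spikes_per_burst_law = lambda r: int(r.integers(2, 9))

    onsets = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / burst_rate)
        if t >= duration:
            break
        onsets.append(t)

    bursts = []
    for onset in onsets:
        n_sp = max(1, spikes_per_burst_law(rng))
        gaps = rng.exponential(1.0 / intra_rate, size=n_sp - 1)
        times = onset + np.concatenate([[0.0], np.cumsum(gaps)])
        bursts.append(times[times < duration])

    overlaps = 0
    if merge_overlaps and len(bursts) > 1:
        merged = [bursts[0]]
        for b in bursts[1:]:
            if b[0] <= merged[-1][-1]:
                merged[-1] = np.sort(np.concatenate([merged[-1], b]))
                overlaps += 1
            else:
                merged.append(b)
        bursts = merged

    burst_onsets = np.array([b[0] for b in bursts])
    spike_times = np.sort(np.concatenate(bursts)) if bursts else np.empty(0)
    return {
        "burst_onsets": burst_onsets,
        "spike_times": spike_times,
        "bursts": bursts,
        "n_merged": overlaps,
    }


def calibrate_ou_to_rate(run_rate: Callable[[float, float], float],
                         target_rate: float = 5.0, tolerance: float = 0.5,
                         mean_bounds: tuple[float, float] = (0.0, 1.5),
                         sigma_ratio: float = 0.3,
                         max_iter: int = 20) -> dict:
    """Bisection on the OU mean until the measured firing rate hits target.

    ``run_rate(mean, sigma)`` must return the measured somatic rate (spikes/s)
    for an OU drive with those parameters; ``sigma`` is held at
    ``sigma_ratio``×mean.  Returns {"mean", "sigma", "rate", "iterations"}.
    Raises ValueError if the bounds do not bracket the target.
    """
    lo, hi = mean_bounds
    r_lo = run_rate(lo, sigma_ratio * lo)
    if abs(r_lo - target_rate) <= tolerance:
        return {"mean": lo, "sigma": sigma_ratio * lo, "rate": r_lo, "iterations": 0}
    r_hi = run_rate(hi, sigma_ratio * hi)
    if abs(r_hi - target_rate) <= tolerance:
        return {"mean": hi, "sigma": sigma_ratio * hi, "rate": r_hi, "iterations": 0}
    if not (min(r_lo, r_hi) < target_rate < max(r_lo, r_hi)):
        raise ValueError(
            f"bounds do not bracket the target rate: f({lo})={r_lo}, f({hi})={r_hi}"
        )
    # the rate may increase or decrease with drive across the bracket (the
    # bursting phenotype's rate falls as tonic drive engages SK); bisection
    # only needs the bracket and the local direction
    increasing = r_hi > r_lo
    mid, rate = lo, r_lo
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        rate = run_rate(mid, sigma_ratio * mid)
        if abs(rate - target_rate) <= tolerance:
            break
        if (rate < target_rate) == increasing:
            lo = mid
        else:
            hi = mid
    return {"mean": mid, "sigma": sigma_ratio * mid, "rate": rate, "iterations": it}


def realize_stimuli(stimuli, model, n_steps: int, dt: float,
                    seed: Optional[int] = None):
    """Materialize stimulus specs into per-compartment injected currents.

    Returns (inj_comp, inj) where ``inj`` is (n_stim, n_steps) in nA.  Specs
    with their own seed use it; otherwise the run seed is combined with the
    stimulus index so distinct stimuli get independent streams.
    """
    comps, rows = [], []
    for k, stim in enumerate(stimuli):
        if stim.comp < 0 or stim.comp >= model.n_comp:
            raise ValueError(f"stimulus target compartment {stim.comp} does not exist")
        if isinstance(stim, OUCurrent):
            sub = None if seed is None else (seed * 1000 + k) % (2**31 - 1)
            rows.append(stim.waveform(n_steps, dt, seed=sub))
        else:
            rows.append(stim.waveform(n_steps, dt))
        comps.append(stim.comp)
    if not rows:
        return np.zeros(0, dtype=np.int64), np.zeros((0, n_steps))
    return np.asarray(comps, dtype=np.int64), np.vstack(rows)
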