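"""Spike detection and electrophysiological feature extraction.

The 12 features used as optimization objectives for DC-step protocols:
resting Vm, AP amplitude, threshold, half-width, rise and fall rates, ISI
coefficient of variation, spike count in the stimulation window, inverse of
the first ISI, after-hyperpolarization Vm, and times to first and last AP.
Conventions (stated here because the features are defined operationally):

* spike time: upward interpolated crossing of 0 mV, 1 ms minimum separation;
* AP threshold: Vm at the first instant dV/dt >= 20 V/s before the peak;
* AP amplitude: peak - threshold;
* half-width: time spent above threshold + amplitude/2;
* rise/fall rate: max/min dV/dt within the spike;
* AHP: minimum Vm in the 50 ms after a spike (or until the next spike);
* resting Vm: mean over the final 100 ms before stimulus onset.

Spike-dependent features are reported as missing (None) when too few spikes
occur; the fitness computation maps missing features to a large finite
penalty so candidate models are still ordered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd

from .traces import SpikeTrain, VoltageTrace

__all__ = [
    "FeatureVector",
    "FeatureTargets",
    "FEATURE_NAMES",
    "detect_spikes",
    "extract_features",
    "feature_errors",
    "MISSING_PENALTY",
]

SPIKE_THRESHOLD_MV = 0.0
REFRACTORY_MS = 1.0
DVDT_THRESHOLD = 20.0  # V/s, AP threshold criterion
MISSING_PENALTY = 250.0  # SD units per missing feature

FEATURE_NAMES = (
    "resting_vm",
    "ap_amplitude",
    "ap_threshold",
    "ap_half_width",
    "ap_rise_rate",
    "ap_fall_rate",
    "isi_cv",
    "spike_count",
    "inv_first_isi",
    "ahp_vm",
    "time_to_first_spike",
    "time_to_last_spike",
)


@dataclass
class FeatureVector:
    """The 12 features of one DC-step protocol; None marks undefined entries."""

    resting_vm: Optional[float] = None  # mV
    ap_amplitude: Optional[float] = None  # mV
    ap_threshold: Optional[float] = None  # mV
    ap_half_width: Optional[float] = None  # ms
    ap_rise_rate: Optional[float] = None  # V/s
    ap_fall_rate: Optional[float] = None  # V/s
    isi_cv: Optional[float] = None
    spike_count: Optional[float] = None
    inv_first_isi: Optional[float] = None  # Hz
    ahp_vm: Optional[float] = None  # mV
    time_to_first_spike: Optional[float] = None  # ms
    time_to_last_spike: Optional[float] = None  # ms
    protocol: str = ""

    def as_dict(self) -> dict[str, Optional[float]]:
        return {n: getattr(self, n) for n in FEATURE_NAMES}


@dataclass
class FeatureTargets:
    """Per-protocol feature means and SDs (the optimization targets).

    ``mean`` and ``sd`` map protocol id -> {feature -> value}; every SD must
    be positive.
    """

    mean: dict[str, dict[str, float]]
    sd: dict[str, dict[str, float]]

    def __post_init__(self):
        for proto, sds in self.sd.items():
            for f, s in sds.items():
                if not s > 0:
                    raise ValueError(f"SD for {proto}/{f} must be > 0, got {s}")

    @property
    def protocols(self) -> tuple[str, ...]:
        return tuple(self.mean)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for proto in self.protocols:
            for f in self.mean[proto]:
                rows.append(
                    {"protocol": proto, "feature": f,
                     "mean": self.mean[proto][f], "sd": self.sd[proto][f]}
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTargets":
        mean: dict[str, dict[str, float]] = {}
        sd: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            mean.setdefault(row["protocol"], {})[row["feature"]] = float(row["mean"])
            sd.setdefault(row["protocol"], {})[row["feature"]] = float(row["sd"])
        return cls(mean, sd)


def detect_spikes(trace: VoltageTrace, duration: Optional[float] = None,
                  site: Optional[str] = None,
                  threshold: float = SPIKE_THRESHOLD_MV,
                  refractory: float = REFRACTORY_MS) -> SpikeTrain:
    """Upward threshold crossings (linearly interpolated) with a refractory rule."""
    site = site or trace.sites[0]
    v = trace[site]
    t = trace.time
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    times = []
    last = -np.inf
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= refractory:
            times.append(tc)
            last = tc
    return SpikeTrain(np.asarray(times), duration=duration or float(t[-1]), site=site)


def _spike_shape(t: np.ndarray, v: np.ndarray, spike_t: float, next_t: float):
    """Threshold, amplitude, half-width, rise/fall rates of one AP."""
    dt = t[1] - t[0]
    i0 = max(0, int(np.searchsorted(t, spike_t - 10.0)))
    i1 = min(len(t), int(np.searchsorted(t, min(spike_t + 10.0, next_t))))
    if i1 - i0 < 4:
        return None
    seg_t = t[i0:i1]
    seg_v = v[i0:i1]
    dvdt = np.gradient(seg_v, seg_t)  # mV/ms == V/s
    pk = int(np.argmax(seg_v))
    # threshold: onset of the rising phase — walk back from the steepest
    # point of the upstroke to where dV/dt first drops below the criterion
    rise = int(np.argmax(dvdt[: pk + 1]))
    thr_idx = 0
    for j in range(rise, -1, -1):
        if dvdt[j] < DVDT_THRESHOLD:
            thr_idx = j
            break
    threshold = float(seg_v[thr_idx])
    amplitude = float(seg_v[pk] - threshold)
    if amplitude <= 0:
        return None
    half = threshold + amplitude / 2.0
    above = seg_v >= half
    # width of the contiguous above-half region containing the peak
    a = pk
    while a > 0 and above[a - 1]:
        a -= 1
    b = pk
    while b < len(above) - 1 and above[b + 1]:
        b += 1
    half_width = float((b - a + 1) * dt)
    rise = float(np.max(dvdt[: pk + 1]))
    fall = float(np.min(dvdt[pk:]))
    return threshold, amplitude, half_width, rise, fall


def extract_features(trace: VoltageTrace, stim, site: Optional[str] = None) -> FeatureVector:
    """Extract the 12 features for one DC-step protocol.

    ``stim`` must expose ``delay`` and ``duration`` (ms); spike-derived
    quantities are restricted to the stimulation window and timed from its
    onset.  Undefined features stay None rather than being fabricated.
    """
    site = site or trace.sites[0]
    v = trace[site]
    t = trace.time
    onset, offset = stim.delay, stim.delay + stim.duration

    fv = FeatureVector(protocol=getattr(stim, "protocol", "") or f"dc_{stim.amplitude:g}nA")

    pre = (t >= onset - 100.0) & (t < onset)
    fv.resting_vm = float(np.mean(v[pre])) if pre.any() else float(v[0])

    train = detect_spikes(trace, site=site)
    in_win = train.times[(train.times >= onset) & (train.times < offset)]
    fv.spike_count = float(len(in_win))
    if len(in_win) == 0:
        return fv

    fv.time_to_first_spike = float(in_win[0] - onset)
    fv.time_to_last_spike = float(in_win[-1] - onset)
    if len(in_win) >= 2:
        isis = np.diff(in_win)
        fv.inv_first_isi = float(1000.0 / isis[0])
        if len(in_win) >= 3:
            fv.isi_cv = float(np.std(isis) / np.mean(isis))

    # AP shape averaged over the spikes in the window
    shapes = []
    all_times = np.concatenate([in_win, [offset + 50.0]])
    for k, st in enumerate(in_win):
        s = _spike_shape(t, v, st, all_times[k + 1])
        if s is not None:
            shapes.append(s)
    if shapes:
        arr = np.asarray(shapes)
        fv.ap_threshold = float(arr[:, 0].mean())
        fv.ap_amplitude = float(arr[:, 1].mean())
        fv.ap_half_width = float(arr[:, 2].mean())
        fv.ap_rise_rate = float(arr[:, 3].mean())
        fv.ap_fall_rate = float(arr[:, 4].mean())

    # AHP: minimum Vm within 50 ms after each spike (or until the next one)
    ahps = []
    for k, st in enumerate(in_win):
        t_end = min(st + 50.0, all_times[k + 1], float(t[-1]))
        m = (t > st) & (t <= t_end)
        if m.any():
            ahps.append(np.min(v[m]))
    if ahps:
        fv.ahp_vm = float(np.mean(ahps))
    return fv


def feature_errors(fv: FeatureVector, targets: FeatureTargets,
                   protocol: Optional[str] = None,
                   penalty: float = MISSING_PENALTY) -> dict[str, float]:
    """Per-feature |f - μ|/σ errors in SD units; missing features get ``penalty``."""
    proto = protocol or fv.protocol
    if proto not in targets.mean:
        raise KeyError(f"protocol {proto!r} not in targets")
    means = targets.mean[proto]
    sds = targets.sd[proto]
    errors = {}
    for name in means:
        val = getattr(fv, name)
        if val is None or not math.isfinite(val):
            errors[name] = penalty
        else:
            errors[name] = abs(val - means[name]) / sds[name]
    return errors
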