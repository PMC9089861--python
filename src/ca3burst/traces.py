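"""Time-series containers: voltages, per-species currents and spike trains."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["VoltageTrace", "CurrentTraces", "SpikeTrain"]


@dataclass
class VoltageTrace:
    """Membrane potential at one or more named recording sites.

    ``vm`` has shape (n_samples, n_sites); time is in ms, voltage in mV.
    """

    time: np.ndarray
    vm: np.ndarray
    sites: tuple[str, ...]

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        if self.vm.ndim == 1:
            self.vm = self.vm[:, None]
        if self.vm.shape[0] != self.time.shape[0]:
            raise ValueError("time and vm length mismatch")
        if self.vm.shape[1] != len(self.sites):
            raise ValueError("site labels do not match vm columns")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.isnan(self.vm).any():
            raise ValueError("vm contains NaN")

    def __getitem__(self, site: str) -> np.ndarray:
        return self.vm[:, self.sites.index(site)]

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def window(self, t0: float, t1: float) -> "VoltageTrace":
        m = (self.time >= t0) & (self.time <= t1)
        return VoltageTrace(self.time[m], self.vm[m], self.sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vm, index=pd.Index(self.time, name="time_ms"),
                            columns=list(self.sites))


@dataclass
class CurrentTraces:
    """Per channel-species membrane current densities at one site.

    ``currents`` maps species name -> mA/cm² array aligned with ``time``
    (positive = outward).
    """

    time: np.ndarray
    currents: dict[str, np.ndarray]
    site: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.shape[0]
        for name, arr in self.currents.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"current {name!r} not aligned with time grid")
            self.currents[name] = arr

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.currents)

    def matrix(self) -> np.ndarray:
        """(n_species, n_samples) matrix in the order of ``species``."""
        return np.vstack([self.currents[s] for s in self.species])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.currents, index=pd.Index(self.time, name="time_ms"))


@dataclass
class SpikeTrain:
    """Ordered spike times (ms) at a recording site."""

    times: np.ndarray
    duration: float
    site: str = "soma"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean firing rate in spikes/s."""
        return len(self) / (self.duration * 1e-3) if self.duration > 0 else 0.0

    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    def isi_cv(self) -> float:
        """Coefficient of variation of the inter-spike intervals."""
        isis = self.isis()
        if isis.size < 2:
            return float("nan")
        return float(np.std(isis) / np.mean(isis))

    def restrict(self, t0: float, t1: float) -> "SpikeTrain":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeTrain(self.times[m] - t0, duration=t1 - t0, site=self.site)
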