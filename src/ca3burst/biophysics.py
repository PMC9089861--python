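"""Ion channels, calcium dynamics and the 24-dimensional parameter space.

The channel inventory covers the mechanism families of CA3 pyramidal-cell
models: transient and persistent sodium, delayed-rectifier / A-type / M-type
/ Ca-activated potassium, T/L/N-type calcium, the hyperpolarization-activated
mixed-cation current (Ih) and leak.  Kinetics are expressed in a parametric
Hodgkin-Huxley form — Boltzmann steady states and bell-shaped voltage-
dependent time constants — so that alternative published rate functions can
be dropped in through the registry without touching the integrator.

Units follow the NEURON conventions: voltages in mV, time in ms, maximal
conductances in S/cm², current densities in mA/cm² (positive = outward),
intracellular calcium in mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .morphology import APICAL_REGIONS, DENDRITIC_REGIONS, Morphology, Section

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "CHANNELS",
    "CHANNEL_ORDER",
    "ParameterSet",
    "ParameterBounds",
    "channel_current",
    "update_calcium",
    "distribute_channels",
    "na_gradient_factor",
    "CA_REST",
    "CM",
    "TEMPERATURE",
    "FARADAY",
    "CA_SHELL_DEPTH",
]

# fixed biophysical constants
CM = 1.0  # µF/cm², membrane capacitance
TEMPERATURE = 34.0  # °C
CA_REST = 50e-6  # mM (50 nM), resting intracellular calcium
FARADAY = 96485.332  # C/mol
CA_SHELL_DEPTH = 0.1  # µm, submembrane shell for calcium accumulation

E_NA = 50.0  # mV
E_K = -90.0  # mV
E_CA = 130.0  # mV
E_H = -30.0  # mV, mixed-cation reversal of Ih


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley gate.

    ``kind == "v"``: voltage-dependent gate with
        x_inf(V)  = 1 / (1 + exp(-(V - v_half) / k))          (k < 0: inactivation)
        tau_x(V)  = tau_min + tau_amp / (exp((V - v_tau)/k_tau1)
                                         + exp(-(V - v_tau)/k_tau2))

    ``kind == "ca"``: calcium-dependent gate (SK-like) with
        x_inf(ca) = ca^h / (ca^h + kd^h),  tau_x = tau_min (constant).
    """

    name: str
    power: int = 1
    kind: str = "v"
    v_half: float = 0.0  # mV (or kd in mM for kind="ca")
    k: float = 1.0  # mV slope (or Hill coefficient for kind="ca")
    tau_min: float = 0.1  # ms
    tau_amp: float = 0.0  # ms
    v_tau: float = 0.0  # mV
    k_tau1: float = 20.0  # mV
    k_tau2: float = 20.0  # mV

    def steady_state(self, x):
        if self.kind == "ca":
            xh = np.asarray(x, dtype=float) ** self.k
            return xh / (xh + self.v_half**self.k)
        return 1.0 / (1.0 + np.exp(-(np.asarray(x, dtype=float) - self.v_half) / self.k))

    def time_constant(self, x, tadj: float = 1.0):
        if self.kind == "ca":
            return np.full_like(np.asarray(x, dtype=float), self.tau_min) / tadj
        v = np.asarray(x, dtype=float)
        tau = self.tau_min + self.tau_amp / (
            np.exp((v - self.v_tau) / self.k_tau1)
            + np.exp(-(v - self.v_tau) / self.k_tau2)
        )
        return tau / tadj


@dataclass(frozen=True)
class ChannelSpec:
    """A conductance mechanism: gates, ion selectivity and reversal."""

    name: str
    ion: str  # {"na", "k", "ca", "nonspecific", "leak"}
    reversal: Optional[float]  # mV; None for leak (uses the free EL parameter)
    gates: tuple[GateSpec, ...] = ()
    q10: float = 2.3
    t_ref: float = 34.0  # °C at which the tau parameters are stated

    def tadj(self, temperature: float = TEMPERATURE) -> float:
        """Q10 factor applied as a divisor on the time constants."""
        return self.q10 ** ((temperature - self.t_ref) / 10.0)


def channel_current(spec: ChannelSpec, gmax: float, gate_states, vm: float,
                    el: float = -70.0) -> float:
    """Ohmic current density, mA/cm², positive = outward.

    ``gate_states`` supplies one open fraction in [0, 1] per gate, in the
    order of ``spec.gates``.
    """
    g = gmax
    for gate, x in zip(spec.gates, gate_states):
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"gate {gate.name} state {x} outside [0, 1]")
        g *= x**gate.power
    e = el if spec.reversal is None else spec.reversal
    return g * (vm - e)


# ---------------------------------------------------------------------------
# Channel registry
# ---------------------------------------------------------------------------
# Parameter values are standard hippocampal-model formulations stated at
# 34 °C (tadj = 1 by default); the registry is data so alternative kinetics
# can be substituted wholesale.

CHANNELS: dict[str, ChannelSpec] = {
    # transient Na: fast activation m^3, inactivation h
    "nat": ChannelSpec(
        "nat", "na", E_NA,
        gates=(
            GateSpec("m", 3, "v", v_half=-38.0, k=6.0,
                     tau_min=0.04, tau_amp=0.2, v_tau=-38.0, k_tau1=12.0, k_tau2=12.0),
            GateSpec("h", 1, "v", v_half=-53.0, k=-7.0,
                     tau_min=0.4, tau_amp=8.0, v_tau=-55.0, k_tau1=14.0, k_tau2=14.0),
        ),
    ),
    # persistent Na: non-inactivating, activates slightly below spike threshold
    "nap": ChannelSpec(
        "nap", "na", E_NA,
        gates=(
            GateSpec("m", 1, "v", v_half=-52.0, k=4.6,
                     tau_min=1.0, tau_amp=0.0),
        ),
    ),
    # delayed-rectifier K
    "kdr": ChannelSpec(
        "kdr", "k", E_K,
        gates=(
            GateSpec("n", 2, "v", v_half=-28.0, k=9.0,
                     tau_min=0.5, tau_amp=3.0, v_tau=-30.0, k_tau1=22.0, k_tau2=22.0),
        ),
    ),
    # A-type K: fast activation, slower inactivation; the activation midpoint
    # is kept depolarized so the window current vanishes at rest
    "ka": ChannelSpec(
        "ka", "k", E_K,
        gates=(
            GateSpec("a", 1, "v", v_half=-22.0, k=9.0,
                     tau_min=0.5, tau_amp=1.0, v_tau=-40.0, k_tau1=20.0, k_tau2=20.0),
            GateSpec("b", 1, "v", v_half=-68.0, k=-7.0,
                     tau_min=8.0, tau_amp=30.0, v_tau=-60.0, k_tau1=20.0, k_tau2=20.0),
        ),
    ),
    # M-type K: slow, non-inactivating, sub-threshold
    "km": ChannelSpec(
        "km", "k", E_K,
        gates=(
            GateSpec("m", 1, "v", v_half=-32.0, k=8.0,
                     tau_min=25.0, tau_amp=80.0, v_tau=-40.0, k_tau1=25.0, k_tau2=25.0),
        ),
    ),
    # Ca-activated K (SK-like): steeply gated by submembrane [Ca] with a
    # half-activation well above rest, so it engages only on Ca influx
    "kca": ChannelSpec(
        "kca", "k", E_K,
        gates=(
            GateSpec("z", 1, "ca", v_half=6.0e-4, k=4.0, tau_min=20.0),
        ),
    ),
    # T-type Ca: low-threshold, inactivating
    "cat": ChannelSpec(
        "cat", "ca", E_CA,
        gates=(
            GateSpec("m", 2, "v", v_half=-47.0, k=6.2,
                     tau_min=2.0, tau_amp=6.0, v_tau=-45.0, k_tau1=16.0, k_tau2=16.0),
            GateSpec("h", 1, "v", v_half=-72.0, k=-5.5,
                     tau_min=12.0, tau_amp=40.0, v_tau=-60.0, k_tau1=18.0, k_tau2=18.0),
        ),
    ),
    # L-type Ca: high-threshold, non-inactivating
    "cal": ChannelSpec(
        "cal", "ca", E_CA,
        gates=(
            GateSpec("m", 2, "v", v_half=-18.0, k=6.5,
                     tau_min=1.5, tau_amp=0.0),
        ),
    ),
    # N-type Ca: high-threshold with slow inactivation
    "can": ChannelSpec(
        "can", "ca", E_CA,
        gates=(
            GateSpec("m", 2, "v", v_half=-22.0, k=7.0,
                     tau_min=1.0, tau_amp=2.0, v_tau=-25.0, k_tau1=20.0, k_tau2=20.0),
            GateSpec("h", 1, "v", v_half=-60.0, k=-9.0,
                     tau_min=40.0, tau_amp=80.0, v_tau=-55.0, k_tau1=25.0, k_tau2=25.0),
        ),
    ),
    # hyperpolarization-activated mixed cation current
    "ih": ChannelSpec(
        "ih", "nonspecific", E_H,
        gates=(
            GateSpec("q", 1, "v", v_half=-82.0, k=-7.0,
                     tau_min=25.0, tau_amp=60.0, v_tau=-75.0, k_tau1=20.0, k_tau2=20.0),
        ),
    ),
    # passive leak; reversal is the free EL parameter
    "leak": ChannelSpec("leak", "leak", None, gates=()),
}

#: fixed channel ordering used to pack conductances into arrays
CHANNEL_ORDER: tuple[str, ...] = (
    "nat", "nap", "kdr", "ka", "km", "kca", "cat", "cal", "can", "ih", "leak",
)

#: channels whose current feeds the calcium shell
CA_CHANNELS: tuple[str, ...] = ("cat", "cal", "can")


# ---------------------------------------------------------------------------
# Free parameters
# ---------------------------------------------------------------------------
# The 18 maximal-conductance entries are channel×region pairs; together with
# the axon/rest leak reversals and axial resistivities and the two calcium
# parameters the free vector has 24 entries.

#: (parameter name, channel, region group) for the 18 conductances, in S/cm²
GMAX_PARTITION: tuple[tuple[str, str, str], ...] = (
    ("gbar_nat_somatic", "nat", "somatic"),
    ("gbar_nat_axonal", "nat", "axonal"),
    ("gbar_nat_dendritic", "nat", "dendritic"),
    ("gbar_nap_somatic", "nap", "somatic"),
    ("gbar_kdr_somatic", "kdr", "somatic"),
    ("gbar_kdr_axonal", "kdr", "axonal"),
    ("gbar_kdr_dendritic", "kdr", "dendritic"),
    ("gbar_ka_somatic", "ka", "somatic"),
    ("gbar_ka_dendritic", "ka", "dendritic"),
    ("gbar_km_somatic", "km", "somatic"),
    ("gbar_kca_somatic", "kca", "somatic"),
    ("gbar_kca_dendritic", "kca", "dendritic"),
    ("gbar_cat_somatodendritic", "cat", "somatodendritic"),
    ("gbar_cal_somatodendritic", "cal", "somatodendritic"),
    ("gbar_can_somatodendritic", "can", "somatodendritic"),
    ("gbar_ih_somatodendritic", "ih", "somatodendritic"),
    ("gbar_leak_somatodendritic", "leak", "somatodendritic"),
    ("gbar_leak_axonal", "leak", "axonal"),
)

GMAX_NAMES: tuple[str, ...] = tuple(n for n, _, _ in GMAX_PARTITION)

SCALAR_NAMES: tuple[str, ...] = (
    "el_axonal",  # mV
    "el_somatodendritic",  # mV
    "ra_axonal",  # Ω·cm
    "ra_somatodendritic",  # Ω·cm
    "tau_ca_decay",  # ms
    "gamma_free_ca",  # dimensionless
)

PARAMETER_NAMES: tuple[str, ...] = GMAX_NAMES + SCALAR_NAMES

_REGION_GROUPS = {
    "somatic": ("soma",),
    "axonal": ("axon",),
    "dendritic": DENDRITIC_REGIONS,
    "somatodendritic": ("soma",) + DENDRITIC_REGIONS,
}


class ParameterError(ValueError):
    """Invalid parameter value or missing entry."""


@dataclass
class ParameterSet:
    """The 24 free model parameters.

    ``gmax`` maps the 18 canonical conductance names to densities in S/cm²;
    the remaining six scalars are the leak reversals and axial resistivities
    (axon vs rest of the cell) and the two intracellular-calcium parameters.
    """

    gmax: dict[str, float]
    el_axonal: float = -70.0
    el_somatodendritic: float = -70.0
    ra_axonal: float = 150.0
    ra_somatodendritic: float = 150.0
    tau_ca_decay: float = 80.0
    gamma_free_ca: float = 0.05

    def __post_init__(self):
        missing = set(GMAX_NAMES) - set(self.gmax)
        if missing:
            raise ParameterError(f"missing conductances: {sorted(missing)}")
        extra = set(self.gmax) - set(GMAX_NAMES)
        if extra:
            raise ParameterError(f"unknown conductances: {sorted(extra)}")
        for k, v in self.gmax.items():
            if v < 0:
                raise ParameterError(f"{k} must be >= 0, got {v}")
        if self.ra_axonal <= 0 or self.ra_somatodendritic <= 0:
            raise ParameterError("axial resistivities must be > 0")
        if self.tau_ca_decay <= 0:
            raise ParameterError("tau_ca_decay must be > 0")
        if not (0 < self.gamma_free_ca <= 1):
            raise ParameterError("gamma_free_ca must be in (0, 1]")

    # -- vector interface (for the optimizer) ------------------------------
    def to_vector(self) -> np.ndarray:
        vals = [self.gmax[n] for n in GMAX_NAMES]
        vals += [getattr(self, n) for n in SCALAR_NAMES]
        return np.asarray(vals, dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "ParameterSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAMETER_NAMES),):
            raise ParameterError(
                f"expected vector of length {len(PARAMETER_NAMES)}, got {vec.shape}"
            )
        gmax = dict(zip(GMAX_NAMES, vec[: len(GMAX_NAMES)]))
        scalars = dict(zip(SCALAR_NAMES, vec[len(GMAX_NAMES):]))
        return cls(gmax=gmax, **scalars)

    def to_dict(self) -> dict[str, float]:
        d = dict(self.gmax)
        for n in SCALAR_NAMES:
            d[n] = getattr(self, n)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        gmax = {n: float(d[n]) for n in GMAX_NAMES}
        scalars = {n: float(d[n]) for n in SCALAR_NAMES}
        return cls(gmax=gmax, **scalars)

    def ra(self, region: str) -> float:
        return self.ra_axonal if region == "axon" else self.ra_somatodendritic

    def el(self, region: str) -> float:
        return self.el_axonal if region == "axon" else self.el_somatodendritic

    def copy(self) -> "ParameterSet":
        return ParameterSet.from_dict(self.to_dict())


@dataclass
class ParameterBounds:
    """Per-parameter [lower, upper) bounds, same units as ParameterSet."""

    lower: dict[str, float]
    upper: dict[str, float]

    def __post_init__(self):
        for n in PARAMETER_NAMES:
            if n not in self.lower or n not in self.upper:
                raise ParameterError(f"missing bounds for {n}")
            if not self.lower[n] < self.upper[n]:
                raise ParameterError(f"bounds for {n} must satisfy lower < upper")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.lower[n] for n in PARAMETER_NAMES])
        hi = np.array([self.upper[n] for n in PARAMETER_NAMES])
        return lo, hi

    def contains(self, params: ParameterSet) -> bool:
        vec = params.to_vector()
        lo, hi = self.as_arrays()
        return bool(np.all(vec >= lo) and np.all(vec <= hi))

    def validate(self, params: ParameterSet) -> None:
        vec = params.to_vector()
        lo, hi = self.as_arrays()
        bad = [
            f"{n}={v:g} not in [{l:g}, {u:g}]"
            for n, v, l, u in zip(PARAMETER_NAMES, vec, lo, hi)
            if not (l <= v <= u)
        ]
        if bad:
            raise ParameterError("; ".join(bad))

    @classmethod
    def around(cls, params: ParameterSet, factor: float = 4.0,
               scalar_margin: float = 0.5) -> "ParameterBounds":
        """Multiplicative box around a reference set (for recovery studies).

        Conductances get [v/factor, v*factor] (zero entries get a small
        absolute window); voltages get ±10 mV; the remaining scalars get
        ±``scalar_margin`` fractional windows.
        """
        lower, upper = {}, {}
        for n, v in params.gmax.items():
            if v > 0:
                lower[n], upper[n] = v / factor, v * factor
            else:
                lower[n], upper[n] = 0.0, 1e-4
        for n in ("el_axonal", "el_somatodendritic"):
            v = getattr(params, n)
            lower[n], upper[n] = v - 10.0, v + 10.0
        for n in ("ra_axonal", "ra_somatodendritic", "tau_ca_decay"):
            v = getattr(params, n)
            lower[n], upper[n] = v * (1 - scalar_margin), v * (1 + scalar_margin)
        v = params.gamma_free_ca
        lower["gamma_free_ca"] = max(1e-4, v * (1 - scalar_margin))
        upper["gamma_free_ca"] = min(1.0, v * (1 + scalar_margin))
        return cls(lower, upper)


# ---------------------------------------------------------------------------
# Calcium dynamics
# ---------------------------------------------------------------------------

def update_calcium(ca_i: float, i_ca_total: float, params: ParameterSet,
                   dt: float, depth: float = CA_SHELL_DEPTH) -> float:
    """Advance submembrane [Ca]i by one step of the shell model.

    Inward calcium current (negative ``i_ca_total``, mA/cm²) raises [Ca]i in
    a shell of the given depth, scaled by the free-calcium fraction
    ``gamma_free_ca``; [Ca]i relaxes toward the 50 nM resting level with time
    constant ``tau_ca_decay``.  The update is the exact solution for constant
    flux over the step:

        ca(t+dt) = ca_inf + (ca - ca_inf) * exp(-dt/tau),
        ca_inf   = CA_REST + flux * tau,
        flux     = -1e-3 * gamma * I_Ca / (2 F depth)   [mM/ms]
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if ca_i <= 0:
        raise ValueError("ca_i must be > 0")
    depth_cm = depth * 1e-4
    flux = -1e-3 * params.gamma_free_ca * i_ca_total / (2.0 * FARADAY * depth_cm)
    flux = max(flux, 0.0)  # the shell only accumulates from influx
    tau = params.tau_ca_decay
    ca_inf = CA_REST + flux * tau
    return ca_inf + (ca_i - ca_inf) * math.exp(-dt / tau)


# ---------------------------------------------------------------------------
# Channel distribution over a morphology
# ---------------------------------------------------------------------------

def na_gradient_factor(path_distance: float, length_constant: float = 100.0) -> float:
    """Apical fast-Na density multiplier: 100% at the soma decaying to 50%.

    g(x) = g_soma * (0.5 + 0.5 * exp(-x / length_constant)); continuous at
    the soma boundary (factor 1 at x = 0).
    """
    return 0.5 + 0.5 * math.exp(-path_distance / length_constant)


def distribute_channels(morphology: Morphology, params: ParameterSet,
                        na_gradient: bool = False) -> dict[int, dict[str, float]]:
    """Assign per-section maximal conductances (S/cm²) from the free vector.

    Each section receives the gmax entries whose region group contains its
    region label.  With ``na_gradient`` enabled (spine experiments), the
    fast-Na density on apical sections decays exponentially with path
    distance from 100% to 50% of the somatic value (length constant 100 µm).
    """
    out: dict[int, dict[str, float]] = {}
    for sec in morphology.sections:
        g = {name: 0.0 for name in CHANNEL_ORDER}
        for pname, channel, group in GMAX_PARTITION:
            if sec.region in _REGION_GROUPS[group]:
                g[channel] += params.gmax[pname]
        if na_gradient and sec.region in APICAL_REGIONS:
            # gradient anchored to the somatic density, not the dendritic one
            x = sec.path_distance_from_soma - sec.length / 2.0  # section midpoint
            g["nat"] = params.gmax["gbar_nat_somatic"] * na_gradient_factor(max(x, 0.0))
        out[sec.id] = g
    return out
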