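"""Two-compartment dendritic spines and AMPA/NMDA synapses.

A spine is a neck + head pair of cylinders attached to a dendritic branch;
the default geometry (neck 1.58 × 0.077 µm, head 0.5 × 0.5 µm — the cylinder
with the surface of a 0.5 µm sphere) gives a neck resistance of several
hundred MΩ at typical axial resistivities, which is what electrically
isolates the synapse.  Spines carry only passive membrane matching the
parent branch; the membrane capacitance elsewhere is left unmodified because
at most a handful of spines are attached at a time.

Synapses are bi-exponential AMPA (0.1/1 ms) and NMDA conductances (1/50 ms
for the thorny cell, 1/100 ms for the a-thorny one, matching its slower
EPSP decay), with the NMDA conductance multiplied by a voltage-dependent
magnesium-unblock coefficient

    B(V) = 1 / (1 + ([Mg]o / Kd) · exp(γ (sh - V)))

with [Mg]o = 1 mM, Kd = 9.888 mM and sh = -7.778 mV; the default slope
γ = 0.1 mV⁻¹ puts half-unblock near -31 mV with ~2% of the conductance
available at -70 mV, inside the canonical range for the electro-diffusive
magnesium block.  The excitatory reversal potential is 0 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .simulator import CompartmentalModel, SpineRecord, Synapse, simulate
from .stimuli import EPSPCurrent

__all__ = [
    "SpineSpec",
    "MgParams",
    "SynapseSpec",
    "mg_block_coefficient",
    "synaptic_current",
    "attach_spines",
    "calibrate_synaptic_weights",
    "spine_neck_resistance",
]


@dataclass(frozen=True)
class SpineSpec:
    """Spine geometry, µm; axial resistivity is inherited from the parent."""

    neck_length: float = 1.58
    neck_diameter: float = 0.077
    head_length: float = 0.5
    head_diameter: float = 0.5

    def __post_init__(self):
        for f in ("neck_length", "neck_diameter", "head_length", "head_diameter"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


@dataclass(frozen=True)
class MgParams:
    """Voltage dependence of NMDA magnesium unblock.

    ``gamma`` is the Boltzmann slope of the unblock in mV⁻¹; the default
    0.1 mV⁻¹ (e-fold per 10 mV) puts half-unblock near -31 mV at 1 mM
    external magnesium with this Kd and shift.
    """

    conc: float = 1.0  # mM, external magnesium
    kd: float = 9.888  # mM
    sh: float = -7.778  # mV
    gamma: float = 0.1  # mV^-1

    def __post_init__(self):
        if self.conc <= 0 or self.kd <= 0 or self.gamma <= 0:
            raise ValueError("mg parameters (except sh) must be positive")


@dataclass
class SynapseSpec:
    """AMPA + NMDA kinetics and weights for one synapse."""

    ampa_tau_rise: float = 0.1  # ms
    ampa_tau_decay: float = 1.0  # ms
    ampa_weight: float = 0.0003  # µS
    nmda_tau_rise: float = 1.0  # ms
    nmda_tau_decay: float = 50.0  # ms (100 for the a-thorny cell type)
    nmda_weight: float = 0.0006  # µS; NMDA-dominant 2:1 ratio by default
    mg: MgParams = field(default_factory=MgParams)

    def __post_init__(self):
        if not self.ampa_tau_decay > self.ampa_tau_rise > 0:
            raise ValueError("AMPA decay must exceed rise")
        if not self.nmda_tau_decay > self.nmda_tau_rise > 0:
            raise ValueError("NMDA decay must exceed rise")
        if self.ampa_weight < 0 or self.nmda_weight < 0:
            raise ValueError("weights must be >= 0")

    @classmethod
    def for_cell_type(cls, cell_type: str, **overrides) -> "SynapseSpec":
        kw = dict(nmda_tau_decay=100.0 if cell_type == "athorny" else 50.0)
        kw.update(overrides)
        return cls(**kw)

    def scaled(self, factor: float) -> "SynapseSpec":
        return replace(self, ampa_weight=self.ampa_weight * factor,
                       nmda_weight=self.nmda_weight * factor)


def mg_block_coefficient(vm, mg: MgParams = MgParams()):
    """Fraction of NMDA conductance unblocked at Vm (mV); in (0, 1].

    B(V) = 1 / (1 + ([Mg]o/Kd) · exp(γ (sh − Vm))), strictly increasing in
    Vm with limits 0 and 1 at ∓∞; at Vm = sh the value is 1/(1 + [Mg]o/Kd)
    independently of the slope.
    """
    vm = np.asarray(vm, dtype=float)
    out = 1.0 / (1.0 + (mg.conc / mg.kd) * np.exp(mg.gamma * (mg.sh - vm)))
    return out if out.ndim else float(out)


def _biexp_g(t, tau_rise, tau_decay):
    t = np.asarray(t, dtype=float)
    tp = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    norm = math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)
    g = np.where(t >= 0, (np.exp(-np.maximum(t, 0) / tau_decay)
                          - np.exp(-np.maximum(t, 0) / tau_rise)) / norm, 0.0)
    return g


def synaptic_current(spec: SynapseSpec, vm: float, t_since_events) -> float:
    """Total synaptic current (nA, positive = outward) at voltage ``vm``.

    ``t_since_events`` lists the elapsed times (ms) since each presynaptic
    event; conductances sum linearly over events.  The NMDA component is
    scaled by the magnesium-unblock coefficient at ``vm``; both receptors
    revert at 0 mV.
    """
    t = np.asarray(t_since_events, dtype=float)
    if t.size == 0:
        return 0.0
    g_ampa = spec.ampa_weight * _biexp_g(t, spec.ampa_tau_rise, spec.ampa_tau_decay).sum()
    g_nmda = spec.nmda_weight * _biexp_g(t, spec.nmda_tau_rise, spec.nmda_tau_decay).sum()
    g_nmda *= mg_block_coefficient(vm, spec.mg)
    return float((g_ampa + g_nmda) * (vm - 0.0))


def branch_chain(morphology, root_sec: int) -> list:
    """The unbranched-or-first-child chain of same-region sections from
    ``root_sec`` to the branch tip (how a long branch is stored as a chain
    of shorter sections)."""
    sec = morphology.section(root_sec)
    chain = [sec]
    while True:
        children = [c for c in morphology.children(chain[-1].id)
                    if c.region == sec.region]
        if not children:
            return chain
        chain.append(children[0])


def attach_spines(model: CompartmentalModel, branch_sec: int, n: int,
                  spacing: float = 5.0, start_position: float = 0.5,
                  spine: SpineSpec = SpineSpec(),
                  synapse: Optional[SynapseSpec] = None) -> list[SpineRecord]:
    """Attach ``n`` evenly spaced spines along a dendritic branch.

    The branch is the chain of same-region sections starting at
    ``branch_sec``; spines are placed from ``start_position`` (fraction of
    the whole chain) advancing ``spacing`` µm per spine toward the tip.
    Each spine adds a neck and a head compartment; if ``synapse`` is given,
    an AMPA+NMDA synapse is created on each spine head (events set later).
    Returns the spine records in placement order.
    """
    chain = branch_chain(model.morphology, branch_sec)
    total = sum(s.length for s in chain)
    span = (n - 1) * spacing
    if start_position * total + span > total:
        raise ValueError(
            f"branch at section {branch_sec} ({total:.0f} µm) too short for "
            f"{n} spines at {spacing} µm spacing from position {start_position}"
        )

    def locate_on_chain(arc: float) -> int:
        acc = 0.0
        for s in chain:
            if arc <= acc + s.length or s is chain[-1]:
                return model.locate(s.id, min((arc - acc) / s.length, 1.0))
            acc += s.length
        raise AssertionError("unreachable")

    records = []
    for k in range(n):
        arc = start_position * total + k * spacing
        parent_comp = locate_on_chain(arc)
        base = model.path_dist[parent_comp]
        neck = model._add_comp(parent_comp, -1, "spine", spine.neck_length,
                               spine.neck_diameter, base, spine=True)
        head = model._add_comp(neck, -1, "spine", spine.head_length,
                               spine.head_diameter, base + spine.neck_length,
                               spine=True)
        rec = SpineRecord(neck_comp=neck, head_comp=head, parent_comp=parent_comp,
                          branch_sec=branch_sec, position=arc / total)
        model.spines.append(rec)
        records.append(rec)
        if synapse is not None:
            model.synapses.append(Synapse(
                comp=head,
                ampa_weight=synapse.ampa_weight,
                nmda_weight=synapse.nmda_weight,
                ampa_tau_rise=synapse.ampa_tau_rise,
                ampa_tau_decay=synapse.ampa_tau_decay,
                nmda_tau_rise=synapse.nmda_tau_rise,
                nmda_tau_decay=synapse.nmda_tau_decay,
                mg_conc=synapse.mg.conc,
                mg_kd=synapse.mg.kd,
                mg_sh=synapse.mg.sh,
                mg_gamma=synapse.mg.gamma,
            ))
    return records


def spine_neck_resistance(spine: SpineSpec, ra: float) -> float:
    """Analytic neck resistance in MΩ for axial resistivity ``ra`` (Ω·cm)."""
    L_cm = spine.neck_length * 1e-4
    r_cm = spine.neck_diameter / 2.0 * 1e-4
    return ra * L_cm / (math.pi * r_cm**2) * 1e-6


def calibrate_synaptic_weights(model: CompartmentalModel, params, spine: SpineRecord,
                               synapse: SynapseSpec,
                               target_deflection: float = 20.0,
                               tolerance: float = 1.0,
                               max_iter: int = 12,
                               zero_na: bool = False,
                               na_gradient: bool = False,
                               settle: float = 200.0) -> SynapseSpec:
    """Scale AMPA+NMDA weights until a single event deflects the spine head
    by ``target_deflection`` mV.

    The AMPA:NMDA conductance ratio is preserved (both weights scale by the
    same factor).  Uses secant-style rescaling on the peak deflection, which
    converges in a couple of iterations because the response is close to
    linear below ~20 mV.  Raises RuntimeError if it fails to converge.
    """
    spec = synapse
    syn_idx = [k for k, s in enumerate(model.synapses)
               if s.comp == spine.head_comp]
    if not syn_idx:
        raise ValueError("spine has no synapse to calibrate")
    k0 = syn_idx[0]
    for _ in range(max_iter):
        model.synapses[k0].ampa_weight = spec.ampa_weight
        model.synapses[k0].nmda_weight = spec.nmda_weight
        saved_events = [np.asarray(s.events).copy() for s in model.synapses]
        for s in model.synapses:
            s.set_events([])
        model.synapses[k0].set_events([settle])
        res = simulate(model, params, recordings=(spine.head_comp,),
                       duration=settle + 150.0, zero_na=zero_na,
                       na_gradient=na_gradient)
        for s, ev in zip(model.synapses, saved_events):
            s.set_events(ev)
        vm = res.voltage.vm[:, 0]
        t = res.voltage.time
        base = vm[(t > settle - 20.0) & (t < settle)].mean()
        peak = vm[t >= settle].max() - base
        if abs(peak - target_deflection) <= tolerance:
            return spec
        if peak <= 0:
            raise RuntimeError("no depolarization at the spine head")
        factor = min(max(target_deflection / peak, 0.2), 5.0)
        spec = spec.scaled(factor)
    raise RuntimeError(
        f"weight calibration did not converge (last peak {peak:.2f} mV)"
    )
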