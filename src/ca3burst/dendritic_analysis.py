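"""Dendritic integration experiments: input-resistance maps, spine amplitude
ratios, neck-resistance estimates, synaptic cooperativity and burst counts.

All protocols follow the same conventions: input resistance is measured with
500 ms hyperpolarizing -50 pA steps with sodium conductances removed
(mimicking TTX); the amplitude ratio AR = EPSP_spine / EPSP_dend is obtained
either by injecting an EPSP-shaped current into the spine head or by
activating a calibrated synapse; the spine-neck resistance follows from
Rneck = (AR - 1) · Rdend.  Cooperativity activates 1..n neighbouring spines
(5 µm apart, 0.3 ms stagger) and compares measured peak EPSPs with the
linear prediction n × (single-input EPSP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biophysics import ParameterSet
from .morphology import Morphology
from .simulator import CompartmentalModel, discretize, simulate
from .spines_synapses import (
    SpineSpec,
    SynapseSpec,
    attach_spines,
    calibrate_synaptic_weights,
)
from .stimuli import DCStep, EPSPCurrent

__all__ = [
    "RinMap",
    "CooperativityCurve",
    "rin_map",
    "amplitude_ratio",
    "rneck_estimate",
    "cooperativity_curve",
    "burst_count_sweep",
]


@dataclass
class RinMap:
    """Per-compartment input resistance with location metadata."""

    comp: np.ndarray
    path_distance: np.ndarray  # µm
    diameter: np.ndarray  # µm
    region: list[str]
    rin: np.ndarray  # MΩ

    def __post_init__(self):
        if np.any(self.rin <= 0):
            raise ValueError("input resistances must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "comp": self.comp,
            "path_distance_um": self.path_distance,
            "diameter_um": self.diameter,
            "region": self.region,
            "rin_mohm": self.rin,
        })

    def at(self, comp: int) -> float:
        return float(self.rin[list(self.comp).index(comp)])


@dataclass
class CooperativityCurve:
    """Measured vs linearly predicted peak EPSPs for 1..n inputs."""

    n_inputs: np.ndarray
    soma_epsp: np.ndarray  # mV
    dend_epsp: np.ndarray  # mV
    soma_linear: np.ndarray  # mV
    dend_linear: np.ndarray  # mV
    supralinearity_threshold: Optional[int] = None  # smallest n above margin
    spiking_in_ttx: bool = False  # flagged if spikes occur with Na removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_inputs": self.n_inputs,
            "soma_epsp_mv": self.soma_epsp,
            "dend_epsp_mv": self.dend_epsp,
            "soma_linear_mv": self.soma_linear,
            "dend_linear_mv": self.dend_linear,
        })


def rin_map(model: CompartmentalModel, params: ParameterSet,
            amplitude: float = -0.05, duration: float = 500.0,
            settle: float = 300.0, comps: Optional[Sequence[int]] = None,
            zero_na: bool = True, dt: float = 0.025) -> RinMap:
    """Input resistance of every (non-spine) compartment.

    Each compartment receives its own hyperpolarizing step; Rin is the
    steady-state voltage deflection at the end of the pulse divided by the
    injected current.  Sodium conductances are zeroed by default (TTX
    condition), matching how the dendritic maps are constructed.
    """
    if comps is None:
        comps = [i for i in range(model.n_comp) if not model.is_spine[i]]
    rins, dists, diams, regions = [], [], [], []
    for comp in comps:
        stim = DCStep(amplitude=amplitude, delay=settle, duration=duration, comp=comp)
        res = simulate(model, params, stimuli=[stim], recordings=(comp,),
                       duration=settle + duration + 20.0, dt=dt, zero_na=zero_na)
        v = res.voltage.vm[:, 0]
        t = res.voltage.time
        base = v[(t > settle - 50.0) & (t < settle)].mean()
        end = v[(t > settle + duration - 25.0) & (t < settle + duration)].mean()
        rin = abs(end - base) / abs(amplitude)  # mV / nA = MΩ
        rins.append(rin)
        dists.append(model.path_dist[comp])
        diams.append(model.diam[comp])
        regions.append(model.region[comp])
    return RinMap(
        comp=np.asarray(list(comps)),
        path_distance=np.asarray(dists),
        diameter=np.asarray(diams),
        region=regions,
        rin=np.asarray(rins),
    )


def _peak_deflection(res, settle: float, col: int) -> float:
    v = res.voltage.vm[:, col]
    t = res.voltage.time
    base = v[(t > settle - 20.0) & (t < settle)].mean()
    return float(v[t >= settle].max() - base)


def amplitude_ratio(model: CompartmentalModel, params: ParameterSet,
                    spine, mode: str = "current_injection",
                    target_deflection: float = 20.0,
                    synapse: Optional[SynapseSpec] = None,
                    zero_na: bool = True, na_gradient: bool = False,
                    settle: float = 300.0, dt: float = 0.025,
                    max_iter: int = 8) -> dict:
    """Spine-to-dendrite amplitude ratio for one spine.

    ``mode="current_injection"``: an EPSP-shaped current (1/10 ms) is
    injected into the spine head, its amplitude dynamically adjusted until
    the spine-head deflection reaches ~``target_deflection``.
    ``mode="synaptic"``: the spine's synapse is calibrated to the same
    deflection and activated once.  Returns AR, both EPSPs and the injected
    amplitude or weights used.
    """
    head, parent = spine.head_comp, spine.parent_comp
    if mode == "current_injection":
        amp = 0.05  # nA starting guess
        for _ in range(max_iter):
            stim = EPSPCurrent(amplitude=amp, onset=settle, comp=head)
            res = simulate(model, params, stimuli=[stim], recordings=(head, parent),
                           duration=settle + 150.0, dt=dt, zero_na=zero_na,
                           na_gradient=na_gradient)
            peak = _peak_deflection(res, settle, 0)
            if abs(peak - target_deflection) <= 0.05 * target_deflection:
                break
            amp *= min(max(target_deflection / max(peak, 1e-9), 0.2), 5.0)
        epsp_spine = _peak_deflection(res, settle, 0)
        epsp_dend = _peak_deflection(res, settle, 1)
        used = {"amplitude_nA": amp}
    elif mode == "synaptic":
        spec = synapse or SynapseSpec()
        spec = calibrate_synaptic_weights(
            model, params, spine, spec, target_deflection=target_deflection,
            tolerance=0.05 * target_deflection, zero_na=zero_na,
            na_gradient=na_gradient, settle=settle,
        )
        syn = [s for s in model.synapses if s.comp == head][0]
        saved = [np.asarray(s.events).copy() for s in model.synapses]
        for s in model.synapses:
            s.set_events([])
        syn.set_events([settle])
        res = simulate(model, params, recordings=(head, parent),
                       duration=settle + 150.0, dt=dt, zero_na=zero_na,
                       na_gradient=na_gradient)
        for s, ev in zip(model.synapses, saved):
            s.set_events(ev)
        epsp_spine = _peak_deflection(res, settle, 0)
        epsp_dend = _peak_deflection(res, settle, 1)
        used = {"ampa_weight_uS": spec.ampa_weight, "nmda_weight_uS": spec.nmda_weight}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if epsp_dend <= 0:
        raise ValueError("degenerate configuration: no dendritic EPSP")
    return {"AR": epsp_spine / epsp_dend, "EPSP_spine": epsp_spine,
            "EPSP_dend": epsp_dend, **used}


def rneck_estimate(ar: float, rdend: float) -> float:
    """Spine neck resistance (MΩ) from the amplitude ratio: (AR - 1)·Rdend."""
    if ar < 1.0:
        raise ValueError("amplitude ratio must be >= 1")
    if rdend <= 0:
        raise ValueError("dendritic input resistance must be > 0")
    return (ar - 1.0) * rdend


def cooperativity_curve(morphology: Morphology, params: ParameterSet,
                        branch_sec: Optional[int] = None, n_max: int = 9,
                        spacing: float = 5.0, interval: float = 0.3,
                        na_mode: str = "zero",
                        synapse: Optional[SynapseSpec] = None,
                        target_deflection: float = 20.0,
                        supra_margin: float = 1.1,
                        start_position: float = 0.2,
                        max_seg_length: float = 20.0,
                        settle: float = 300.0, dt: float = 0.025) -> CooperativityCurve:
    """Activate 1..n_max neighbouring spines and measure summation.

    Spines sit ``spacing`` µm apart on ``branch_sec`` (a representative
    distal apical branch by default); each carries a calibrated AMPA+NMDA
    synapse and the first n are activated sequentially with a 0.3 ms
    stagger.  ``na_mode="zero"`` removes sodium conductances (the TTX
    condition); ``na_mode="optimized"`` keeps them and enables the apical
    fast-Na gradient.  The supralinearity threshold is the smallest n whose
    measured somatic EPSP exceeds ``supra_margin`` × the linear prediction.
    """
    if na_mode not in ("zero", "optimized"):
        raise ValueError(f"unknown na_mode {na_mode!r}")
    if branch_sec is None:
        branch_sec = default_apical_branch(morphology)
    zero_na = na_mode == "zero"
    na_gradient = na_mode == "optimized"
    model = discretize(morphology, max_seg_length)
    spec = synapse or SynapseSpec.for_cell_type(morphology.cell_type)
    spines = attach_spines(model, branch_sec, n_max, spacing=spacing,
                           start_position=start_position, synapse=spec)
    spec = calibrate_synaptic_weights(
        model, params, spines[0], spec, target_deflection=target_deflection,
        tolerance=0.05 * target_deflection, zero_na=zero_na,
        na_gradient=na_gradient, settle=settle,
    )
    for syn in model.synapses:
        syn.ampa_weight = spec.ampa_weight
        syn.nmda_weight = spec.nmda_weight

    parent = spines[0].parent_comp
    soma_peaks, dend_peaks = [], []
    spiking_flagged = False
    for n in range(1, n_max + 1):
        for k, syn in enumerate(model.synapses):
            syn.set_events([settle + k * interval] if k < n else [])
        res = simulate(model, params, recordings=(0, parent),
                       duration=settle + 200.0, dt=dt, zero_na=zero_na,
                       na_gradient=na_gradient)
        if zero_na and len(res.soma_spikes) > 0:
            spiking_flagged = True
        soma_peaks.append(_peak_deflection(res, settle, 0))
        dend_peaks.append(_peak_deflection(res, settle, 1))
    soma_peaks = np.asarray(soma_peaks)
    dend_peaks = np.asarray(dend_peaks)
    ns = np.arange(1, n_max + 1)
    soma_lin = soma_peaks[0] * ns
    dend_lin = dend_peaks[0] * ns
    above = np.flatnonzero(soma_peaks > supra_margin * soma_lin)
    threshold = int(ns[above[0]]) if above.size else None
    return CooperativityCurve(
        n_inputs=ns, soma_epsp=soma_peaks, dend_epsp=dend_peaks,
        soma_linear=soma_lin, dend_linear=dend_lin,
        supralinearity_threshold=threshold,
        spiking_in_ttx=spiking_flagged,
    )


def burst_count_sweep(morphology: Morphology, params: ParameterSet,
                      n_inputs: int = 6,
                      isi_grid: Sequence[float] = (1.0, 2.0, 5.0, 10.0),
                      distance_grid: Sequence[float] = (0.2, 0.5, 0.8),
                      synapse: Optional[SynapseSpec] = None,
                      branch_sec: Optional[int] = None,
                      target_deflection: float = 20.0,
                      response_window: float = 200.0,
                      burst_grouping_isi: float = 25.0,
                      max_seg_length: float = 20.0,
                      settle: float = 300.0, dt: float = 0.025) -> pd.DataFrame:
    """Spikes per synaptic volley over a presynaptic-ISI × spine-position grid.

    For each grid cell, ``n_inputs`` spines are placed starting at the given
    fractional position along the branch; a single volley is delivered with
    the given presynaptic inter-spike interval (one event per spine) and
    somatic spikes inside the response window are counted, where consecutive
    spikes closer than ``burst_grouping_isi`` belong to the same response
    burst.  Active (optimized) sodium conductances and the apical Na
    gradient are used; synaptic weights are calibrated once at the middle
    grid position under the TTX condition.
    """
    if branch_sec is None:
        branch_sec = default_apical_branch(morphology)
    spec0 = synapse or SynapseSpec.for_cell_type(morphology.cell_type)

    model0 = discretize(morphology, max_seg_length)
    mid_pos = float(np.median(np.asarray(distance_grid)))
    spines0 = attach_spines(model0, branch_sec, 1, start_position=mid_pos,
                            synapse=spec0)
    spec = calibrate_synaptic_weights(
        model0, params, spines0[0], spec0, target_deflection=target_deflection,
        tolerance=0.05 * target_deflection, zero_na=True, settle=settle,
    )

    rows = []
    for pos in distance_grid:
        model = discretize(morphology, max_seg_length)
        spines = attach_spines(model, branch_sec, n_inputs,
                               start_position=pos, synapse=spec)
        dist_um = model.path_dist[spines[0].parent_comp]
        for isi in isi_grid:
            for k, syn in enumerate(model.synapses):
                syn.set_events([settle + k * isi])
            res = simulate(model, params, recordings=(0,),
                           duration=settle + response_window + 50.0, dt=dt,
                           na_gradient=True)
            times = res.soma_spikes.times
            times = times[(times >= settle) & (times < settle + response_window)]
            if times.size == 0:
                count = 0
            else:
                count = 1
                for a, b in zip(times[:-1], times[1:]):
                    if b - a <= burst_grouping_isi:
                        count += 1
                    else:
                        break
            rows.append({"position": pos, "distance_um": dist_um,
                         "isi_ms": isi, "n_inputs": n_inputs, "spikes": count})
    return pd.DataFrame(rows)


def default_apical_branch(morphology: Morphology) -> int:
    """A representative distal apical branch root: the longest oblique chain
    if present (thorny cells), else the longest terminal chain (a-thorny)."""
    from .spines_synapses import branch_chain

    for region in ("oblique", "terminal"):
        roots = [
            s for s in morphology.by_region(region)
            if morphology.section(s.parent_id).region != region
        ]
        if roots:
            return max(
                roots,
                key=lambda s: sum(c.length for c in branch_chain(morphology, s.id)),
            ).id
    raise ValueError("morphology has no oblique or terminal branches")
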