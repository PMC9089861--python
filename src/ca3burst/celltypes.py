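"""Reference models of the two CA3 principal-cell phenotypes.

These hand-tuned parameter sets are the package's stand-ins for optimized
individuals: a regular-spiking "thorny" cell and an intrinsically bursting
"a-thorny" cell on matched reduced morphologies.  Relative to the thorny
set, the a-thorny set down-regulates the potassium conductances (delayed
rectifier, A-type and M-type), up-regulates fast and persistent sodium, and
slows intracellular calcium clearance — the burster's spikes recruit
high-threshold calcium influx whose slow SK-mediated after-hyperpolarization
terminates each burst and spaces them out.

The DC amplitudes span each phenotype's f-I range (the bursting cell has a
much lower rheobase), and the OU calibration brackets are chosen on a branch
of the rate-vs-drive curve that crosses the 5 spikes/s operating point.
"""

from __future__ import annotations

from .biophysics import GMAX_NAMES, ParameterBounds, ParameterSet
from .morphology import MorphoSpec, athorny_spec, thorny_spec

__all__ = [
    "thorny_reference",
    "athorny_reference",
    "reference_parameters",
    "reference_morphospec",
    "reference_dc_amplitudes",
    "reference_ou_bracket",
    "default_bounds",
]


def _pset(**kw) -> ParameterSet:
    gmax = {n: 0.0 for n in GMAX_NAMES}
    scalars = {}
    for k, v in kw.items():
        if "gbar_" + k in GMAX_NAMES:
            gmax["gbar_" + k] = v
        else:
            scalars[k] = v
    return ParameterSet(gmax=gmax, **scalars)


def thorny_reference() -> ParameterSet:
    """Regular-spiking reference cell (rheobase ≈ 0.15–0.2 nA)."""
    return _pset(
        nat_somatic=0.12, nat_axonal=0.8, nat_dendritic=0.03,
        nap_somatic=0.00005,
        kdr_somatic=0.015, kdr_axonal=0.1, kdr_dendritic=0.004,
        ka_somatic=0.01, ka_dendritic=0.01,
        km_somatic=0.004,
        kca_somatic=0.008, kca_dendritic=0.002,
        cat_somatodendritic=0.0003,
        cal_somatodendritic=0.001,
        can_somatodendritic=0.001,
        ih_somatodendritic=0.00005,
        leak_somatodendritic=4e-5, leak_axonal=4e-5,
        el_somatodendritic=-62.0, el_axonal=-62.0,
        ra_somatodendritic=150.0, ra_axonal=150.0,
        tau_ca_decay=120.0, gamma_free_ca=0.15,
    )


def athorny_reference() -> ParameterSet:
    """Intrinsically bursting reference cell (bursts of 3-4 APs at rheobase)."""
    return _pset(
        nat_somatic=0.15, nat_axonal=0.9, nat_dendritic=0.04,
        nap_somatic=0.00007,
        kdr_somatic=0.009, kdr_axonal=0.08, kdr_dendritic=0.002,
        ka_somatic=0.003, ka_dendritic=0.003,
        km_somatic=0.0008,
        kca_somatic=0.06, kca_dendritic=0.012,
        cat_somatodendritic=0.0002,
        cal_somatodendritic=0.001,
        can_somatodendritic=0.002,
        ih_somatodendritic=0.00005,
        leak_somatodendritic=4e-5, leak_axonal=4e-5,
        el_somatodendritic=-62.0, el_axonal=-62.0,
        ra_somatodendritic=340.0, ra_axonal=340.0,
        tau_ca_decay=350.0, gamma_free_ca=0.18,
    )


def reference_parameters(cell_type: str) -> ParameterSet:
    if cell_type == "thorny":
        return thorny_reference()
    if cell_type == "athorny":
        return athorny_reference()
    raise ValueError(f"unknown cell type {cell_type!r}")


def reference_morphospec(cell_type: str, seed: int = 0) -> MorphoSpec:
    """Matched reduced morphology for each phenotype."""
    if cell_type == "thorny":
        return thorny_spec(seed=seed)
    if cell_type == "athorny":
        return athorny_spec(seed=seed)
    raise ValueError(f"unknown cell type {cell_type!r}")


def reference_dc_amplitudes(cell_type: str) -> tuple[float, float, float]:
    """Three DC amplitudes (nA) spanning each phenotype's f-I range."""
    if cell_type == "thorny":
        return (0.2, 0.3, 0.4)
    if cell_type == "athorny":
        return (0.05, 0.1, 0.15)
    raise ValueError(f"unknown cell type {cell_type!r}")


def reference_ou_bracket(cell_type: str) -> tuple[float, float]:
    """OU-mean bracket (nA) around the ~5 spikes/s operating point.

    The regular-spiking cell's rate increases with drive over its bracket;
    the burster's decreases (tonic calcium/SK engagement converts clustered
    bursting into sparse firing), so the bracket is chosen on that branch.
    """
    if cell_type == "thorny":
        return (0.08, 0.16)
    if cell_type == "athorny":
        return (0.04, 0.10)
    raise ValueError(f"unknown cell type {cell_type!r}")


def default_bounds(cell_type: str, factor: float = 4.0) -> ParameterBounds:
    """Optimization box around the reference set (documented default)."""
    return ParameterBounds.around(reference_parameters(cell_type), factor=factor)
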