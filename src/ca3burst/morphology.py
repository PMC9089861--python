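"""Neuronal morphologies as labeled trees of cylindrical sections.

A morphology is stored as an abstract cylinder tree: every section has a
length, proximal/distal diameters and a region label, and is attached to a
parent section.  3D coordinates, when present in an SWC file, are kept only
so that files can be round-tripped; every downstream computation uses path
lengths and diameters exclusively, because only the electrotonic structure
matters for the cable equations.

Two kinds of morphologies are supported:

* reconstructions loaded from standard 7-column SWC files
  (:func:`read_swc` / :func:`write_swc`);
* parametric reduced morphologies (:func:`generate_reduced_morphology`)
  emulating the structural contrast between CA3 thorny cells (apical trunk
  carrying oblique side branches) and a-thorny cells (apical trunk ending in
  terminal branches, no obliques, slightly thicker dendrites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Region",
    "Section",
    "Morphology",
    "MorphoSpec",
    "MorphologyError",
    "SWCParseError",
    "read_swc",
    "write_swc",
    "generate_reduced_morphology",
    "replace_axon",
]

REGIONS = ("soma", "axon", "basal", "apical_trunk", "oblique", "terminal")
Region = str

#: SWC structure-type codes <-> coarse region labels
_SWC_TO_REGION = {1: "soma", 2: "axon", 3: "basal", 4: "apical_trunk"}
_REGION_TO_SWC = {
    "soma": 1,
    "axon": 2,
    "basal": 3,
    "apical_trunk": 4,
    "oblique": 4,
    "terminal": 4,
}

#: regions treated as dendritic when distributing channels
DENDRITIC_REGIONS = ("basal", "apical_trunk", "oblique", "terminal")
APICAL_REGIONS = ("apical_trunk", "oblique", "terminal")


class MorphologyError(ValueError):
    """Invalid morphology structure or geometry."""


class SWCParseError(MorphologyError):
    """Malformed SWC content; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class Section:
    """One cylindrical (possibly tapering) cable section.

    ``path_distance_from_soma`` is the path length from the soma centre to
    the *distal* end of the section; it is filled in by
    :meth:`Morphology.validate`.
    """

    id: int
    parent_id: Optional[int]
    region: Region
    length: float  # µm
    diameter_proximal: float  # µm
    diameter_distal: float  # µm
    path_distance_from_soma: float = 0.0  # µm, at the distal end
    xyz: Optional[tuple[float, float, float]] = None  # distal point, SWC only

    @property
    def diameter(self) -> float:
        """Mean diameter of the (tapering) cylinder, µm."""
        return 0.5 * (self.diameter_proximal + self.diameter_distal)

    @property
    def area(self) -> float:
        """Lateral membrane area, µm²."""
        return math.pi * self.diameter * self.length

    def check(self) -> None:
        if self.region not in REGIONS:
            raise MorphologyError(f"unknown region {self.region!r}")
        if not self.length > 0:
            raise MorphologyError(f"section {self.id}: length must be > 0")
        if not (self.diameter_proximal > 0 and self.diameter_distal > 0):
            raise MorphologyError(f"section {self.id}: diameters must be > 0")


@dataclass
class Morphology:
    """A connected tree of :class:`Section` objects rooted at the soma."""

    sections: list[Section]
    cell_type: str = "thorny"  # {"thorny", "athorny"}
    provenance: str = "synthetic"  # {"swc_file", "synthetic"}

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> Section:
        return self.sections[0]

    def section(self, sec_id: int) -> Section:
        return self._by_id[sec_id]

    def children(self, sec_id: int) -> list[Section]:
        return [s for s in self.sections if s.parent_id == sec_id]

    def by_region(self, *regions: Region) -> list[Section]:
        return [s for s in self.sections if s.region in regions]

    def validate(self) -> None:
        """Check tree structure and geometry; recompute path distances."""
        if not self.sections:
            raise MorphologyError("morphology has no sections")
        self._by_id = {}
        for s in self.sections:
            if s.id in self._by_id:
                raise MorphologyError(f"duplicate section id {s.id}")
            self._by_id[s.id] = s
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        if roots[0].region != "soma":
            raise MorphologyError("root section must be the soma")
        if roots[0] is not self.sections[0]:
            raise MorphologyError("root must come first in topological order")
        seen = set()
        for s in self.sections:
            s.check()
            if s.parent_id is None:
                seen.add(s.id)
                # reference point: soma centre
                s.path_distance_from_soma = s.length / 2.0
                continue
            if s.parent_id not in seen:
                raise MorphologyError(
                    f"section {s.id}: parent {s.parent_id} does not precede it"
                )
            parent = self._by_id[s.parent_id]
            base = 0.0 if parent.region == "soma" else parent.path_distance_from_soma
            s.path_distance_from_soma = base + s.length
            seen.add(s.id)
        if any(s.region == "axon" for s in self.sections):
            # the axon initial segment must hang off the soma
            axon_roots = [
                s
                for s in self.sections
                if s.region == "axon" and self._by_id[s.parent_id].region != "axon"
            ]
            for s in axon_roots:
                if self._by_id[s.parent_id].region != "soma":
                    raise MorphologyError("axon must attach to the soma")

    def copy(self) -> "Morphology":
        return Morphology(
            [replace(s) for s in self.sections],
            cell_type=self.cell_type,
            provenance=self.provenance,
        )

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.sections)


# ---------------------------------------------------------------------------
# SWC input/output
# ---------------------------------------------------------------------------

def read_swc(path) -> Morphology:
    """Read a standard 7-column SWC file into a :class:`Morphology`.

    Each non-root sample becomes one section whose length is the Euclidean
    distance to its parent sample and whose proximal/distal diameters are the
    parent's and its own diameter.  The root sample becomes a soma section of
    length and diameter ``2 r`` (the cylinder with the surface of the sphere
    of radius *r*).  SWC type 4 (apical) samples are sub-labelled by a branch
    rule: trunk until the first bifurcation, side branches off the trunk are
    obliques, post-bifurcation paths ending at a tip are terminals.
    """
    samples: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            txt = raw.strip()
            if not txt or txt.startswith("#"):
                continue
            parts = txt.split()
            if len(parts) != 7:
                raise SWCParseError(f"expected 7 columns, got {len(parts)}", lineno)
            try:
                idx = int(parts[0])
                typ = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(str(exc), lineno) from None
            if idx in samples:
                raise SWCParseError(f"duplicate sample index {idx}", lineno)
            if parent != -1 and parent not in samples:
                raise SWCParseError(
                    f"parent {parent} of sample {idx} not defined yet", lineno
                )
            if r <= 0:
                raise SWCParseError(f"non-positive radius {r}", lineno)
            samples[idx] = (typ, x, y, z, r, parent)
            order.append(idx)
    if not order:
        raise SWCParseError("empty SWC file")
    roots = [i for i in order if samples[i][5] == -1]
    if len(roots) != 1:
        raise SWCParseError(f"expected one root sample, found {len(roots)}")
    root = roots[0]
    if samples[root][0] != 1:
        raise SWCParseError("root sample must have type 1 (soma)")

    children: dict[int, list[int]] = {i: [] for i in order}
    for i in order:
        p = samples[i][5]
        if p != -1:
            children[p].append(i)

    # branch order of apical samples: number of bifurcations on the path
    # from the soma, used to sub-label type-4 samples
    branch_order: dict[int, int] = {root: 0}
    for i in order:
        if i == root:
            continue
        p = samples[i][5]
        branch_order[i] = branch_order[p] + (1 if len(children[p]) > 1 else 0)

    def _is_terminal_path(i: int) -> bool:
        # unbranched path from i to a tip
        while True:
            ch = children[i]
            if not ch:
                return True
            if len(ch) > 1:
                return False
            i = ch[0]

    sections: list[Section] = []
    for i in order:
        typ, x, y, z, r, parent = samples[i]
        if parent == -1:
            sections.append(
                Section(
                    id=i,
                    parent_id=None,
                    region="soma",
                    length=2 * r,
                    diameter_proximal=2 * r,
                    diameter_distal=2 * r,
                    xyz=(x, y, z),
                )
            )
            continue
        ptyp, px, py, pz, pr, _ = samples[parent]
        length = math.dist((x, y, z), (px, py, pz))
        if length <= 0:
            raise SWCParseError(f"sample {i} coincides with its parent")
        if typ == 4:
            if branch_order[i] == 0:
                region = "apical_trunk"
            elif _is_terminal_path(i):
                region = "terminal"
            else:
                region = "oblique"
        else:
            region = _SWC_TO_REGION.get(typ, "basal")
        sections.append(
            Section(
                id=i,
                parent_id=parent,
                region=region,
                length=length,
                diameter_proximal=2 * pr,
                diameter_distal=2 * r,
                xyz=(x, y, z),
            )
        )
    return Morphology(sections, provenance="swc_file")


def write_swc(morphology: Morphology, path) -> None:
    """Write a morphology as a 7-column SWC file (re-readable by read_swc).

    Sections loaded from SWC carry their original 3D sample points and are
    written back verbatim; synthetic sections are laid out along straight
    lines in a deterministic direction per subtree.
    """
    lines = []
    coords: dict[int, tuple[float, float, float]] = {}
    # deterministic fake directions per region for synthetic morphologies
    direction = {
        "soma": (0.0, 0.0, 0.0),
        "axon": (0.0, -1.0, 0.0),
        "basal": (0.7, -0.7, 0.0),
        "apical_trunk": (0.0, 1.0, 0.0),
        "oblique": (1.0, 0.3, 0.0),
        "terminal": (0.3, 1.0, 0.0),
    }
    for s in morphology.sections:
        if s.parent_id is None:
            xyz = s.xyz if s.xyz is not None else (0.0, 0.0, 0.0)
            coords[s.id] = xyz
            r = s.diameter_distal / 2.0
            lines.append(
                f"{s.id} 1 {xyz[0]:.6g} {xyz[1]:.6g} {xyz[2]:.6g} {r:.6g} -1"
            )
            continue
        if s.xyz is not None:
            xyz = s.xyz
        else:
            px, py, pz = coords[s.parent_id]
            dx, dy, dz = direction[s.region]
            norm = math.sqrt(dx * dx + dy * dy + dz * dz) or 1.0
            xyz = (
                px + s.length * dx / norm,
                py + s.length * dy / norm,
                pz + s.length * dz / norm,
            )
        coords[s.id] = xyz
        typ = _REGION_TO_SWC[s.region]
        r = s.diameter_distal / 2.0
        lines.append(
            f"{s.id} {typ} {xyz[0]:.6g} {xyz[1]:.6g} {xyz[2]:.6g} {r:.6g} {s.parent_id}"
        )
    with open(path, "w") as fh:
        fh.write("# SWC export\n")
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic reduced morphologies
# ---------------------------------------------------------------------------

@dataclass
class MorphoSpec:
    """Parameters of a reduced CA3-like morphology.

    Defaults land dendritic input resistances in the hundreds-of-MΩ range
    typical of thin hippocampal dendrites.  Thorny cells get oblique side
    branches along the apical trunk; a-thorny cells get none, their trunk
    instead ends in terminal branches, and their default dendritic diameters
    are slightly thicker.
    """

    cell_type: str = "thorny"
    n_basal: int = 3
    n_oblique_or_terminal: int = 4
    trunk_length: float = 400.0  # µm
    trunk_diameter: float = 3.0  # µm, proximal
    trunk_taper: float = 1.0  # µm, distal diameter
    branch_length: float = 200.0  # µm (mean; jittered per branch)
    branch_diameter: float = 0.8  # µm, proximal
    branch_taper: float = 0.5  # µm, distal
    basal_length: float = 180.0  # µm
    basal_diameter: float = 1.0  # µm
    soma_length: float = 20.0  # µm
    soma_diameter: float = 20.0  # µm
    section_length: float = 50.0  # µm, max length of one Section
    length_jitter: float = 0.15  # fractional sd of branch lengths
    seed: int = 0

    def __post_init__(self):
        if self.cell_type not in ("thorny", "athorny"):
            raise MorphologyError(f"unknown cell_type {self.cell_type!r}")
        for name in (
            "trunk_length", "trunk_diameter", "trunk_taper", "branch_length",
            "branch_diameter", "branch_taper", "basal_length", "basal_diameter",
            "soma_length", "soma_diameter", "section_length",
        ):
            if getattr(self, name) <= 0:
                raise MorphologyError(f"{name} must be positive")
        if self.n_basal < 1 or self.n_oblique_or_terminal < 1:
            raise MorphologyError("at least one basal and one apical branch required")


def athorny_spec(**overrides) -> MorphoSpec:
    """Default a-thorny reduced morphology: no obliques, thicker dendrites."""
    kw = dict(
        cell_type="athorny",
        branch_diameter=1.1,
        branch_taper=0.7,
        basal_diameter=1.3,
    )
    kw.update(overrides)
    return MorphoSpec(**kw)


def thorny_spec(**overrides) -> MorphoSpec:
    kw = dict(cell_type="thorny")
    kw.update(overrides)
    return MorphoSpec(**kw)


def generate_reduced_morphology(spec: MorphoSpec) -> Morphology:
    """Generate a reduced soma + trunk + branches + axon-stub morphology.

    Deterministic for a fixed ``spec.seed``.  Thorny morphologies attach
    ``n_oblique_or_terminal`` oblique branches at evenly spaced points along
    the apical trunk; a-thorny morphologies attach the same number of
    terminal branches at the distal end of the trunk.
    """
    rng = np.random.default_rng(spec.seed)
    sections: list[Section] = []
    next_id = [1]

    def add(parent_id, region, length, d_prox, d_dist):
        sec = Section(
            id=next_id[0],
            parent_id=parent_id,
            region=region,
            length=float(length),
            diameter_proximal=float(d_prox),
            diameter_distal=float(d_dist),
        )
        sections.append(sec)
        next_id[0] += 1
        return sec.id

    def add_cable(parent_id, region, total_length, d_prox, d_dist):
        """Chain of sections (<= section_length each) with linear taper."""
        n = max(1, int(math.ceil(total_length / spec.section_length)))
        seg = total_length / n
        last = parent_id
        for k in range(n):
            a = d_prox + (d_dist - d_prox) * k / n
            b = d_prox + (d_dist - d_prox) * (k + 1) / n
            last = add(last, region, seg, a, b)
        return last

    soma = add(None, "soma", spec.soma_length, spec.soma_diameter, spec.soma_diameter)

    # axon stub: two 30 µm sections in series
    aix = add(soma, "axon", 30.0, 1.5, 1.0)
    add(aix, "axon", 30.0, 1.0, 1.0)

    # basal dendrites
    for _ in range(spec.n_basal):
        L = spec.basal_length * (1 + spec.length_jitter * rng.standard_normal())
        L = max(20.0, L)
        add_cable(soma, "basal", L, spec.basal_diameter, 0.6 * spec.basal_diameter)

    # apical trunk as a chain, remembering attachment points
    n_trunk = max(2, int(math.ceil(spec.trunk_length / spec.section_length)))
    seg = spec.trunk_length / n_trunk
    trunk_ids = []
    last = soma
    for k in range(n_trunk):
        a = spec.trunk_diameter + (spec.trunk_taper - spec.trunk_diameter) * k / n_trunk
        b = spec.trunk_diameter + (spec.trunk_taper - spec.trunk_diameter) * (k + 1) / n_trunk
        last = add(last, "apical_trunk", seg, a, b)
        trunk_ids.append(last)

    nb = spec.n_oblique_or_terminal
    if spec.cell_type == "thorny":
        # obliques branch off evenly spaced trunk positions
        at = np.linspace(0, n_trunk - 1, nb).astype(int)
        for k in range(nb):
            L = spec.branch_length * (1 + spec.length_jitter * rng.standard_normal())
            L = max(30.0, L)
            add_cable(
                trunk_ids[at[k]], "oblique", L, spec.branch_diameter, spec.branch_taper
            )
    else:
        # terminal branches fan out from the distal trunk
        for k in range(nb):
            L = spec.branch_length * (1 + spec.length_jitter * rng.standard_normal())
            L = max(30.0, L)
            add_cable(
                trunk_ids[-1], "terminal", L, spec.branch_diameter, spec.branch_taper
            )

    return Morphology(sections, cell_type=spec.cell_type, provenance="synthetic")


def replace_axon(morphology: Morphology) -> Morphology:
    """Replace any existing axon with a stereotypical two-section stub.

    The stub consists of two 30 µm-long sections attached in series to the
    soma, standing in for the axon initial segment; all other sections are
    left untouched.  Axonless input is valid — the stub is simply added.
    """
    kept = [replace(s) for s in morphology.sections if s.region != "axon"]
    old_ids = {s.id for s in kept}
    soma_id = kept[0].id
    nid = max(old_ids) + 1
    stub = [
        Section(nid, soma_id, "axon", 30.0, 1.5, 1.0),
        Section(nid + 1, nid, "axon", 30.0, 1.0, 1.0),
    ]
    return Morphology(
        kept + stub, cell_type=morphology.cell_type, provenance=morphology.provenance
    )
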