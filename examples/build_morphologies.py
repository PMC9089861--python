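"""Generate the two reduced CA3 morphologies and write them as SWC.

The thorny (regular-spiking) template carries oblique side branches along
its apical trunk; the a-thorny (bursting) template has none — its trunk ends
in terminal branches — and its dendrites are slightly thicker.  Printed
below: section counts per region and total cable length, then each
morphology is exported to a standard SWC file that `read_swc` can reload.
"""

from collections import Counter

from ca3burst.morphology import (
    athorny_spec,
    generate_reduced_morphology,
    thorny_spec,
    write_swc,
)

for spec in (thorny_spec(seed=0), athorny_spec(seed=0)):
    morph = generate_reduced_morphology(spec)
    counts = Counter(s.region for s in morph.sections)
    print(f"{morph.cell_type}: {len(morph.sections)} sections, "
          f"total length {morph.total_length:.0f} µm")
    for region in ("soma", "axon", "basal", "apical_trunk", "oblique", "terminal"):
        print(f"  {region:13s} {counts.get(region, 0):3d}")
    path = f"{morph.cell_type}_reduced.swc"
    write_swc(morph, path)
    print(f"  written to {path}\n")

# the oblique/terminal contrast is the structural fingerprint of the two
# cell types: thorny cells have obliques, a-thorny cells have none
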