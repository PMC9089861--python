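"""f-I curves of the two reference cells.

Injects 500 ms DC steps at the soma and prints, per amplitude, the overall
firing rate (spikes during the step / 0.5 s) and the initial rate (inverse
of the first inter-spike interval).  The regular-spiking cell needs ~4x more
current to fire (higher rheobase) and its rate grows steeply with drive; the
bursting cell fires a short high-frequency burst already at low amplitudes
and its overall rate barely changes with the injected current.
"""

import numpy as np

from ca3burst.celltypes import reference_dc_amplitudes, reference_parameters
from ca3burst.pipeline import build_reference_cell
from ca3burst.simulator import simulate
from ca3burst.stimuli import DCStep

for cell in ("thorny", "athorny"):
    _, model, params = build_reference_cell(cell)
    print(f"{cell}:")
    print("  I (pA)   rate (Hz)   initial rate (Hz)")
    amps = dict.fromkeys((0.05,) + reference_dc_amplitudes(cell))
    for amp in amps:
        stim = DCStep(amplitude=amp, delay=200.0, duration=500.0)
        res = simulate(model, params, stimuli=[stim], duration=750.0)
        train = res.soma_spikes.restrict(200.0, 700.0)
        isis = train.isis()
        init = 1000.0 / isis[0] if isis.size else 0.0
        print(f"  {amp * 1000:6.0f}   {len(train) / 0.5:9.1f}   {init:17.1f}")
    print()
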