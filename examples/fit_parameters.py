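"""Closed-loop parameter fitting with IBEA (tiny demonstration run).

Feature targets are generated from a known ground-truth parameter set
(mean = simulated value, SD = 10% of the mean), so recovery can be verified
without external data.  A small evolutionary run (population 16, 10
generations) then searches the 24-dimensional space; printed: the best
fitness per generation (sum of per-feature errors in SD units) and how many
final individuals pass the 6-SD-per-feature acceptance rule.
"""

from ca3burst.biophysics import ParameterBounds
from ca3burst.celltypes import thorny_reference
from ca3burst.morphology import generate_reduced_morphology, thorny_spec
from ca3burst.optimize import dc_protocols, ibea_run, select_individuals
from ca3burst.pipeline import make_reference_targets
from ca3burst.simulator import discretize

truth = thorny_reference()
morph = generate_reduced_morphology(
    thorny_spec(n_basal=2, n_oblique_or_terminal=2, seed=1)
)
model = discretize(morph, 40.0)
protocols = dc_protocols((0.2, 0.3, 0.4), delay=150.0)
targets = make_reference_targets(truth, model, protocols, dt=0.05)
bounds = ParameterBounds.around(truth, factor=3.0)

run = ibea_run(targets, bounds, model, protocols,
               pop_size=16, n_gen=10, seed=3, dt=0.05)
print("generation   best fitness (SD units)")
for g, h in enumerate(run.history):
    print(f"{g:10d}   {h['best']:10.1f}")
accepted = select_individuals(run.population)
print(f"\naccepted individuals (every feature error < 6 SD): "
      f"{len(accepted)} / {len(run.population)}")
if accepted:
    champ = min(accepted, key=lambda ind: ind.fitness)
    print(f"best accepted: fitness {champ.fitness:.1f}, "
          f"worst feature {champ.max_error:.2f} SD")
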