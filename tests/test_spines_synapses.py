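"""Spine attachment, magnesium block and synaptic conductances."""

import math

import numpy as np
import pytest

from ca3burst.simulator import discretize, simulate
from ca3burst.spines_synapses import (
    MgParams,
    SpineSpec,
    SynapseSpec,
    attach_spines,
    calibrate_synaptic_weights,
    mg_block_coefficient,
    spine_neck_resistance,
    synaptic_current,
)


class TestMgBlock:
    def test_value_at_shift_point(self):
        # at Vm = sh the coefficient is 1/(1 + [Mg]o/Kd) for any slope
        mg = MgParams()
        assert mg_block_coefficient(mg.sh, mg) == pytest.approx(
            1.0 / (1.0 + 1.0 / 9.888), abs=1e-6
        )

    def test_strictly_increasing_on_grid(self):
        v = np.arange(-100.0, 60.0 + 0.5, 1.0)
        b = mg_block_coefficient(v)
        assert np.all(np.diff(b) > 0)

    def test_limits(self):
        assert mg_block_coefficient(500.0) == pytest.approx(1.0, abs=1e-6)
        assert mg_block_coefficient(-500.0) == pytest.approx(0.0, abs=1e-6)
        assert 0.0 < mg_block_coefficient(-70.0) < mg_block_coefficient(0.0) <= 1.0

    def test_bounded_in_unit_interval(self):
        v = np.linspace(-200, 200, 4001)
        b = mg_block_coefficient(v)
        assert np.all((b > 0) & (b <= 1))


class TestSynapticCurrent:
    def test_no_events_no_current(self):
        assert synaptic_current(SynapseSpec(), -65.0, []) == 0.0

    def test_zero_at_reversal_potential(self):
        assert synaptic_current(SynapseSpec(), 0.0, [1.0, 5.0]) == 0.0

    def test_pure_ampa_decay(self):
        spec = SynapseSpec(nmda_weight=0.0)
        i1 = synaptic_current(spec, -60.0, [2.0])
        i2 = synaptic_current(spec, -60.0, [2.0 + spec.ampa_tau_decay])
        assert i1 < 0  # inward at -60 mV
        assert abs(i2) < abs(i1)
        # well past the AMPA transient the current is essentially gone
        assert abs(synaptic_current(spec, -60.0, [20.0])) < 1e-3 * abs(i1)

    def test_nmda_blocked_at_rest_open_when_depolarized(self):
        spec = SynapseSpec(ampa_weight=0.0)
        frac = abs(synaptic_current(spec, -70.0, [5.0])) / (
            spec.nmda_weight * 70.0
        )
        assert frac < 0.05  # mostly blocked at rest
        i_dep = synaptic_current(spec, -20.0, [5.0])
        assert abs(i_dep) > abs(synaptic_current(spec, -70.0, [5.0]))

    def test_events_sum_linearly_in_conductance(self):
        spec = SynapseSpec(nmda_weight=0.0)
        single = synaptic_current(spec, -60.0, [3.0])
        double = synaptic_current(spec, -60.0, [3.0, 3.0])
        assert double == pytest.approx(2.0 * single, rel=1e-9)


class TestSpines:
    def test_nine_spines_span_forty_microns(self, thorny_morph, thorny_params):
        from ca3burst.dendritic_analysis import default_apical_branch

        model = discretize(thorny_morph, 20.0)
        branch = default_apical_branch(thorny_morph)
        before = model.n_comp
        spines = attach_spines(model, branch, 9, spacing=5.0, start_position=0.1)
        assert len(spines) == 9
        assert model.n_comp == before + 18  # neck + head per spine
        dists = [model.path_dist[s.parent_comp] for s in spines]
        assert max(dists) - min(dists) == pytest.approx(40.0, abs=model.length[spines[0].parent_comp] + 1.0)

    def test_single_spine_at_start_position(self, thorny_morph):
        from ca3burst.dendritic_analysis import default_apical_branch

        model = discretize(thorny_morph, 20.0)
        spines = attach_spines(model, default_apical_branch(thorny_morph), 1,
                               start_position=0.5)
        assert len(spines) == 1
        assert model.is_spine[spines[0].neck_comp]
        assert model.is_spine[spines[0].head_comp]
        assert model.parent[spines[0].head_comp] == spines[0].neck_comp

    def test_branch_too_short_rejected(self, thorny_morph):
        from ca3burst.dendritic_analysis import default_apical_branch

        model = discretize(thorny_morph, 20.0)
        with pytest.raises(ValueError):
            attach_spines(model, default_apical_branch(thorny_morph), 9,
                          spacing=5.0, start_position=0.95)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SpineSpec(neck_diameter=0.0)

    def test_passive_spines_leave_resting_potential(self, thorny_morph,
                                                    passive_params):
        from ca3burst.dendritic_analysis import default_apical_branch

        bare = discretize(thorny_morph, 25.0)
        res0 = simulate(bare, passive_params, duration=500.0, dt=0.05)
        spiny = discretize(thorny_morph, 25.0)
        attach_spines(spiny, default_apical_branch(thorny_morph), 9,
                      start_position=0.1)
        res1 = simulate(spiny, passive_params, duration=500.0, dt=0.05)
        v0 = res0.voltage.vm[-1, 0]
        v1 = res1.voltage.vm[-1, 0]
        assert abs(v1 - v0) < 0.1

    def test_neck_resistance_scales_with_resistivity(self):
        spine = SpineSpec()
        r150 = spine_neck_resistance(spine, 150.0)
        r340 = spine_neck_resistance(spine, 340.0)
        assert r340 / r150 == pytest.approx(340.0 / 150.0)
        assert 300.0 < r150 < 800.0  # several hundred MΩ


class TestWeightCalibration:
    def test_calibrated_peak_hits_target(self, thorny_morph, thorny_params):
        from ca3burst.dendritic_analysis import default_apical_branch

        model = discretize(thorny_morph, 25.0)
        syn = SynapseSpec()
        spines = attach_spines(model, default_apical_branch(thorny_morph), 1,
                               start_position=0.3, synapse=syn)
        spec = calibrate_synaptic_weights(model, thorny_params, spines[0], syn,
                                          target_deflection=20.0, tolerance=1.0,
                                          zero_na=True)
        # verification run with the returned weights
        model.synapses[0].ampa_weight = spec.ampa_weight
        model.synapses[0].nmda_weight = spec.nmda_weight
        model.synapses[0].set_events([200.0])
        res = simulate(model, thorny_params, recordings=(spines[0].head_comp,),
                       duration=350.0, zero_na=True)
        v = res.voltage.vm[:, 0]
        t = res.voltage.time
        base = v[(t > 180) & (t < 200)].mean()
        assert abs((v[t >= 200].max() - base) - 20.0) <= 1.0

    def test_ratio_preserved_by_calibration(self, thorny_morph, thorny_params):
        from ca3burst.dendritic_analysis import default_apical_branch

        model = discretize(thorny_morph, 25.0)
        syn = SynapseSpec(ampa_weight=2e-4, nmda_weight=8e-4)
        spines = attach_spines(model, default_apical_branch(thorny_morph), 1,
                               start_position=0.3, synapse=syn)
        spec = calibrate_synaptic_weights(model, thorny_params, spines[0], syn,
                                          target_deflection=15.0, tolerance=1.0,
                                          zero_na=True)
        assert spec.nmda_weight / spec.ampa_weight == pytest.approx(4.0, rel=1e-9)
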