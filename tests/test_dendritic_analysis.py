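"""Input-resistance maps, amplitude ratios and cooperativity protocols."""

import numpy as np
import pytest

from ca3burst.dendritic_analysis import (
    amplitude_ratio,
    cooperativity_curve,
    default_apical_branch,
    rin_map,
    rneck_estimate,
)
from ca3burst.simulator import discretize
from ca3burst.spines_synapses import SpineSpec, attach_spines


@pytest.fixture(scope="module")
def thorny_rin(thorny_model, thorny_params):
    tips = [i for i in range(thorny_model.n_comp)
            if thorny_model.region[i] == "oblique"]
    comps = [0, tips[0], tips[-1]]
    return comps, rin_map(thorny_model, thorny_params, comps=comps)


class TestRinMap:
    def test_passive_single_compartment_matches_analytic(self, soma_only_model,
                                                         passive_params):
        rm = rin_map(soma_only_model, passive_params, comps=[0])
        area = soma_only_model.area_cm2()[0]
        rin_pred = 1.0 / (5e-5 * area) * 1e-6  # MΩ
        assert rm.rin[0] == pytest.approx(rin_pred, rel=0.01)

    def test_thin_tip_has_higher_rin_than_soma(self, thorny_rin):
        comps, rm = thorny_rin
        assert rm.at(comps[-1]) > rm.at(0)

    def test_near_linearity_under_ttx(self, thorny_model, thorny_params):
        # in the small-deflection regime (a few mV at the trunk) doubling the
        # pulse amplitude leaves the measured Rin nearly unchanged; thin tips
        # are excluded because a -100 pA pulse drives them tens of mV into
        # the Ih rectification range
        trunk = thorny_model.locate(
            [s.id for s in thorny_model.morphology.by_region("apical_trunk")][0], 0.5)
        a = rin_map(thorny_model, thorny_params, comps=[trunk], amplitude=-0.05)
        b = rin_map(thorny_model, thorny_params, comps=[trunk], amplitude=-0.10)
        assert b.rin[0] == pytest.approx(a.rin[0], rel=0.02)

    def test_rin_decreases_with_diameter_across_regions(self, thorny_model,
                                                        thorny_params):
        comps = [0,
                 thorny_model.locate(
                     [s.id for s in thorny_model.morphology.by_region("apical_trunk")][0], 0.5),
                 [i for i in range(thorny_model.n_comp)
                  if thorny_model.region[i] == "oblique"][-1]]
        rm = rin_map(thorny_model, thorny_params, comps=comps)
        order = np.argsort(rm.diameter)
        assert np.all(np.diff(rm.rin[order]) <= 0)


class TestAmplitudeRatio:
    def test_default_spine_is_compartmentalized(self, thorny_morph, thorny_params):
        model = discretize(thorny_morph, 25.0)
        sp = attach_spines(model, default_apical_branch(thorny_morph), 1,
                           start_position=0.3)
        out = amplitude_ratio(model, thorny_params, sp[0])
        assert out["AR"] > 1.0
        assert out["EPSP_spine"] == pytest.approx(20.0, rel=0.1)

    def test_fat_neck_limit_approaches_unity(self, thorny_morph, thorny_params):
        model = discretize(thorny_morph, 25.0)
        fat = SpineSpec(neck_length=0.5, neck_diameter=2.0)
        sp = attach_spines(model, default_apical_branch(thorny_morph), 1,
                           start_position=0.3, spine=fat)
        out = amplitude_ratio(model, thorny_params, sp[0])
        assert out["AR"] == pytest.approx(1.0, abs=0.05)

    def test_injection_and_synaptic_modes_give_comparable_ranges(
            self, thorny_morph, thorny_params):
        # synaptic activation (fast AMPA conductance) filters differently
        # from the slower EPSP-shaped current, so the comparison is between
        # the ranges of AR the two protocols produce across the branch, not
        # pointwise values
        from ca3burst.spines_synapses import SynapseSpec

        inj_ars, syn_ars = [], []
        for pos in (0.2, 0.8):
            model = discretize(thorny_morph, 25.0)
            sp = attach_spines(model, default_apical_branch(thorny_morph), 1,
                               start_position=pos, synapse=SynapseSpec())
            inj_ars.append(amplitude_ratio(model, thorny_params, sp[0],
                                           mode="current_injection")["AR"])
            syn_ars.append(amplitude_ratio(model, thorny_params, sp[0],
                                           mode="synaptic")["AR"])
        assert all(a > 1.0 for a in inj_ars + syn_ars)
        assert np.mean(syn_ars) / np.mean(inj_ars) < 2.0
        assert np.mean(inj_ars) / np.mean(syn_ars) < 2.0

    def test_higher_rin_branch_gives_higher_ar(self, thorny_morph, thorny_params):
        # proximal vs distal position on the same branch: distal has higher
        # Rin (taper) and must show the larger amplitude ratio
        branch = default_apical_branch(thorny_morph)
        model = discretize(thorny_morph, 25.0)
        sp_prox = attach_spines(model, branch, 1, start_position=0.15)
        sp_dist = attach_spines(model, branch, 1, start_position=0.85)
        rm = rin_map(model, thorny_params,
                     comps=[sp_prox[0].parent_comp, sp_dist[0].parent_comp])
        ar_p = amplitude_ratio(model, thorny_params, sp_prox[0])["AR"]
        ar_d = amplitude_ratio(model, thorny_params, sp_dist[0])["AR"]
        assert rm.rin[1] > rm.rin[0]
        assert ar_d < ar_p  # higher dendritic Rin -> smaller spine/dend ratio


class TestRneck:
    def test_unity_ratio_gives_zero(self):
        assert rneck_estimate(1.0, 150.0) == 0.0

    def test_printed_example_arithmetic(self):
        assert rneck_estimate(7.3, 100.0) == pytest.approx(630.0)

    def test_linear_in_dendritic_resistance(self):
        assert rneck_estimate(3.0, 200.0) == 2.0 * rneck_estimate(3.0, 100.0)

    def test_sub_unity_ratio_rejected(self):
        with pytest.raises(ValueError):
            rneck_estimate(0.9, 100.0)

    def test_consistency_with_simulated_spine(self, thorny_morph, thorny_params):
        # (AR-1)·Rdend must land in the same range as the analytic neck
        # resistance of the default spine geometry
        from ca3burst.spines_synapses import spine_neck_resistance

        model = discretize(thorny_morph, 25.0)
        sp = attach_spines(model, default_apical_branch(thorny_morph), 1,
                           start_position=0.3)
        out = amplitude_ratio(model, thorny_params, sp[0])
        rm = rin_map(model, thorny_params, comps=[sp[0].parent_comp])
        est = rneck_estimate(out["AR"], rm.rin[0])
        analytic = spine_neck_resistance(SpineSpec(),
                                         thorny_params.ra_somatodendritic)
        assert est == pytest.approx(analytic, rel=0.5)


class TestCooperativity:
    def test_first_point_equals_linear_prediction(self, athorny_morph,
                                                  athorny_params):
        c = cooperativity_curve(athorny_morph, athorny_params, n_max=4)
        assert c.soma_epsp[0] == c.soma_linear[0]
        assert c.dend_epsp[0] == c.dend_linear[0]

    def test_nmda_off_control_stays_linear(self, thorny_morph, thorny_params):
        from ca3burst.spines_synapses import SynapseSpec

        syn = SynapseSpec.for_cell_type("thorny", nmda_weight=0.0)
        c = cooperativity_curve(thorny_morph, thorny_params, n_max=9,
                                synapse=syn)
        assert np.all(c.soma_epsp <= 1.05 * c.soma_linear)
        assert c.supralinearity_threshold is None

    def test_nmda_on_reaches_supralinearity_without_sodium(self, athorny_morph,
                                                           athorny_params):
        c = cooperativity_curve(athorny_morph, athorny_params, n_max=9)
        assert c.supralinearity_threshold is not None
        assert not c.spiking_in_ttx

    def test_bursting_cell_threshold_not_above_regular_cell(
            self, thorny_morph, athorny_morph, thorny_params, athorny_params):
        ca = cooperativity_curve(athorny_morph, athorny_params, n_max=9)
        ct = cooperativity_curve(thorny_morph, thorny_params, n_max=9)
        assert ca.supralinearity_threshold is not None
        thorny_thr = ct.supralinearity_threshold or 10
        assert ca.supralinearity_threshold <= thorny_thr
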