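"""Channel formalism, calcium shell dynamics and the free-parameter space."""

import math

import numpy as np
import pytest

from ca3burst.biophysics import (
    CHANNEL_ORDER,
    CHANNELS,
    GMAX_NAMES,
    PARAMETER_NAMES,
    CA_REST,
    ChannelSpec,
    GateSpec,
    ParameterBounds,
    ParameterError,
    ParameterSet,
    channel_current,
    distribute_channels,
    na_gradient_factor,
    update_calcium,
)
from ca3burst.morphology import generate_reduced_morphology, thorny_spec


def _params(**overrides):
    gmax = {n: 1e-4 for n in GMAX_NAMES}
    p = dict(gmax=gmax)
    p.update(overrides)
    return ParameterSet(**p)


class TestChannelCurrent:
    def test_zero_conductance_gives_zero_current(self):
        spec = CHANNELS["kdr"]
        for vm in (-90.0, -40.0, 20.0):
            assert channel_current(spec, 0.0, [0.7], vm) == 0.0

    def test_current_vanishes_at_reversal(self):
        spec = CHANNELS["kdr"]
        assert channel_current(spec, 0.01, [1.0], -90.0) == pytest.approx(0.0)

    def test_open_na_at_zero_mv_is_inward(self):
        # fully open Na conductance g at Vm = 0 gives I = -50 g (inward)
        spec = CHANNELS["nat"]
        g = 0.02
        i = channel_current(spec, g, [1.0, 1.0], 0.0)
        assert i == pytest.approx(-50.0 * g)

    def test_gate_exponent_applied(self):
        spec = CHANNELS["nat"]  # m^3 h
        half = channel_current(spec, 1.0, [0.5, 1.0], 0.0)
        full = channel_current(spec, 1.0, [1.0, 1.0], 0.0)
        assert half == pytest.approx(full * 0.5**3)

    def test_out_of_range_gate_state_rejected(self):
        with pytest.raises(ValueError):
            channel_current(CHANNELS["kdr"], 0.01, [1.2], -40.0)


class TestGateCurves:
    @pytest.mark.parametrize("cname", [c for c in CHANNEL_ORDER if CHANNELS[c].gates])
    def test_steady_states_bounded_and_monotone(self, cname):
        vgrid = np.linspace(-120.0, 60.0, 721)
        for gate in CHANNELS[cname].gates:
            if gate.kind == "ca":
                ca = np.logspace(-6, -1, 200)
                x = gate.steady_state(ca)
                assert np.all((x >= 0) & (x <= 1))
                assert np.all(np.diff(x) >= 0)  # activation in [Ca]
                continue
            x = gate.steady_state(vgrid)
            assert np.all((x >= 0) & (x <= 1))
            d = np.diff(x)
            if gate.k > 0:
                assert np.all(d >= -1e-12)  # activation increases with Vm
            else:
                assert np.all(d <= 1e-12)  # inactivation decreases with Vm

    @pytest.mark.parametrize("cname", [c for c in CHANNEL_ORDER if CHANNELS[c].gates])
    def test_time_constants_positive(self, cname):
        vgrid = np.linspace(-120.0, 60.0, 721)
        for gate in CHANNELS[cname].gates:
            tau = gate.time_constant(CA_REST if gate.kind == "ca" else vgrid)
            assert np.all(tau > 0)

    def test_q10_scaling_divides_time_constant(self):
        gate = CHANNELS["kdr"].gates[0]
        spec = CHANNELS["kdr"]
        tau_ref = gate.time_constant(-40.0, tadj=spec.tadj(spec.t_ref))
        tau_warm = gate.time_constant(-40.0, tadj=spec.tadj(spec.t_ref + 10.0))
        assert tau_warm == pytest.approx(tau_ref / spec.q10)


class TestCalcium:
    def test_resting_point_is_fixed(self):
        p = _params()
        ca = update_calcium(CA_REST, 0.0, p, dt=0.1)
        assert ca == pytest.approx(CA_REST, rel=1e-12)

    def test_exponential_decay_to_rest(self):
        p = _params(tau_ca_decay=40.0)
        ca = 150e-6
        t = 5.0 * p.tau_ca_decay
        out = update_calcium(ca, 0.0, p, dt=t)
        # closed form: rest + (ca - rest) e^{-t/tau}; 5 tau -> within 1%
        assert abs(out - CA_REST) < 0.01 * (ca - CA_REST)
        exact = CA_REST + (ca - CA_REST) * math.exp(-t / p.tau_ca_decay)
        assert out == pytest.approx(exact, rel=1e-12)

    def test_flux_increment_linear_in_gamma(self):
        p1 = _params(gamma_free_ca=0.05)
        p2 = _params(gamma_free_ca=0.10)
        i_ca = -0.5  # inward
        dt = 0.01
        d1 = update_calcium(CA_REST, i_ca, p1, dt) - CA_REST
        d2 = update_calcium(CA_REST, i_ca, p2, dt) - CA_REST
        assert d2 == pytest.approx(2.0 * d1, rel=1e-6)

    def test_outward_ca_current_does_not_deplete_below_rest(self):
        p = _params()
        out = update_calcium(CA_REST, +1.0, p, dt=1.0)
        assert out >= CA_REST * 0.999

    def test_invalid_inputs_rejected(self):
        p = _params()
        with pytest.raises(ValueError):
            update_calcium(CA_REST, 0.0, p, dt=0.0)
        with pytest.raises(ValueError):
            update_calcium(-1e-6, 0.0, p, dt=0.1)


class TestNaGradient:
    def test_full_density_at_soma_boundary(self):
        assert na_gradient_factor(0.0) == pytest.approx(1.0)

    def test_half_density_at_infinity(self):
        assert na_gradient_factor(1e9) == pytest.approx(0.5)

    def test_value_at_one_length_constant(self):
        assert na_gradient_factor(100.0) == pytest.approx(0.5 + 0.5 / math.e)

    def test_continuity_near_soma(self):
        assert abs(na_gradient_factor(1e-6) - 1.0) < 1e-6

    def test_distribute_applies_gradient_to_apical_only(self):
        morph = generate_reduced_morphology(thorny_spec(seed=0))
        p = _params()
        with_grad = distribute_channels(morph, p, na_gradient=True)
        soma_na = p.gmax["gbar_nat_somatic"]
        for sec in morph.sections:
            g = with_grad[sec.id]["nat"]
            if sec.region in ("apical_trunk", "oblique", "terminal"):
                assert 0.5 * soma_na <= g <= soma_na
            elif sec.region == "basal":
                assert g == pytest.approx(p.gmax["gbar_nat_dendritic"])


class TestParameterSet:
    def test_vector_round_trip(self):
        p = _params(tau_ca_decay=77.0, gamma_free_ca=0.3)
        q = ParameterSet.from_vector(p.to_vector())
        assert q.to_dict() == p.to_dict()

    def test_free_vector_has_24_entries(self):
        assert len(PARAMETER_NAMES) == 24
        assert len(GMAX_NAMES) == 18

    def test_negative_conductance_rejected(self):
        gmax = {n: 1e-4 for n in GMAX_NAMES}
        gmax["gbar_kdr_somatic"] = -1e-5
        with pytest.raises(ParameterError):
            ParameterSet(gmax=gmax)

    def test_gamma_range_enforced(self):
        with pytest.raises(ParameterError):
            _params(gamma_free_ca=1.5)

    def test_bounds_validate_rejects_out_of_range(self):
        p = _params()
        bounds = ParameterBounds.around(p, factor=2.0)
        assert bounds.contains(p)
        q = p.copy()
        q.gmax["gbar_nat_somatic"] *= 10.0
        with pytest.raises(ParameterError):
            bounds.validate(q)

    def test_region_specific_scalars(self):
        p = _params(ra_axonal=100.0, ra_somatodendritic=200.0,
                    el_axonal=-75.0, el_somatodendritic=-65.0)
        assert p.ra("axon") == 100.0
        assert p.ra("basal") == 200.0
        assert p.el("axon") == -75.0
        assert p.el("soma") == -65.0
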