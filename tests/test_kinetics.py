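"""Eyring rates, detailed balance, stiff simulation and phenomenology."""

import math

import numpy as np
import pytest

from acetalnet import examples
from acetalnet.constants import K_B, PLANCK_H, R_KJ
from acetalnet.kinetics import (
    MicrokineticModel,
    build_rate_model,
    eyring_rate,
    is_unimodal,
    pyranose_selectivity,
    simulate,
)
from acetalnet.network import NetworkError
from conftest import make_linear_network

T = 333.15
RT = R_KJ * T


class TestEyring:
    def test_barrierless_rate_is_the_universal_frequency(self):
        assert eyring_rate(0.0, T) == pytest.approx(K_B * T / PLANCK_H)
        assert eyring_rate(0.0, T) == pytest.approx(6.94e12, rel=1e-2)

    def test_huge_barrier_underflows_to_zero_without_error(self):
        assert eyring_rate(500.0, T) < 1e-60

    def test_rt_ln10_increment_divides_the_rate_by_ten(self):
        g = 40.0
        assert eyring_rate(g + RT * math.log(10), T) == pytest.approx(
            eyring_rate(g, T) / 10.0)

    def test_negative_barrier_raises(self):
        with pytest.raises(ValueError):
            eyring_rate(-1.0, T)


class TestRateModel:
    def test_thermoneutral_step_has_equal_rates(self):
        net = make_linear_network([0.0, 0.0], [20.0])
        model = build_rate_model(net)
        k = model.rates.set_index("step")["k_per_s"]
        assert k["A0->A1"] == pytest.approx(k["A0->A1_rev"])

    def test_detailed_balance_ratio_of_two(self):
        net = make_linear_network([0.0, -RT * math.log(2)], [20.0])
        model = build_rate_model(net)
        k = model.rates.set_index("step")["k_per_s"]
        assert k["A0->A1"] / k["A0->A1_rev"] == pytest.approx(2.0, rel=1e-9)

    def test_detailed_balance_holds_for_every_pair_of_the_paper_network(self, paper_net):
        model = build_rate_model(paper_net, mu_shifts=examples.HYDRONIUM_MU_SHIFT)
        k = model.rates.set_index("step")["k_per_s"]
        idx = model.index
        for step in paper_net.steps:
            if step.id.endswith("_rev"):
                continue
            kf, kb = k[step.id], k[step.id + "_rev"]
            dg_eff = model.g_eff[idx[step.product]] - model.g_eff[idx[step.reactant]]
            if kb > 0 and kf / kb < 1e12:  # skip underflow-limited pairs
                assert kf / kb == pytest.approx(math.exp(-dg_eff / RT), rel=1e-9)

    def test_paper_network_builds_without_error(self, paper_net):
        model = build_rate_model(paper_net)
        # 70 species minus the three small-molecule reservoirs
        assert model.matrix.shape == (67, 67)
        scale = np.abs(np.diag(model.matrix)).max()
        assert np.abs(model.matrix.sum(axis=0)).max() < 1e-9 * scale

    def test_step_without_barrier_or_equilibrated_flag_is_an_error(self):
        net = make_linear_network([0.0, -10.0], [None])
        for step in net.steps:
            object.__setattr__(step, "reversible", False)
        with pytest.raises(NetworkError, match="equilibrated"):
            build_rate_model(net)

    def test_rate_cap_preserves_the_stationary_distribution(self, paper_net):
        free = build_rate_model(paper_net, mu_shifts=examples.HYDRONIUM_MU_SHIFT)
        capped = build_rate_model(paper_net, mu_shifts=examples.HYDRONIUM_MU_SHIFT,
                                  k_cap=1e5)
        assert capped.rates["k_per_s"].max() <= 1e5 * (1 + 1e-12)
        pd_diff = (free.boltzmann_weights() - capped.boltzmann_weights()).abs().max()
        assert pd_diff < 1e-12


class TestSimulate:
    def test_irreversible_decay_matches_closed_form(self):
        net = make_linear_network([0.0, -40.0], [10.0])
        net.steps[:] = [s for s in net.steps if s.id == "A0->A1"]  # irreversible
        model = build_rate_model(net)
        k = model.rates["k_per_s"].iloc[0]
        t_min = np.linspace(0.0, 3.0 / (k * 60.0), 40)
        trace = simulate(model, {"A0": 1.0}, t_min[-1], t_eval_min=t_min)
        assert np.allclose(trace.fractions["A0"], np.exp(-k * t_min * 60.0), atol=1e-6)

    def test_thermoneutral_exchange_relaxes_to_half(self):
        net = make_linear_network([0.0, 0.0], [30.0])
        model = build_rate_model(net)
        k = model.rates["k_per_s"].iloc[0]
        trace = simulate(model, {"A0": 1.0}, 20.0 / (k * 60.0), n_points=20)
        assert trace.final()["A0"] == pytest.approx(0.5, abs=1e-6)
        assert trace.final()["A1"] == pytest.approx(0.5, abs=1e-6)

    def test_consecutive_chain_intermediate_is_unimodal(self):
        # A -> I -> P with k1 > k2: Bateman behaviour, I rises then decays
        net = make_linear_network([0.0, -50.0, -100.0], [20.0, 35.0])
        net.steps[:] = [s for s in net.steps if not s.id.endswith("_rev")]
        model = build_rate_model(net)
        k2 = model.rates.set_index("step")["k_per_s"]["A1->A2"]
        t_min = np.linspace(0.0, 8.0 / (k2 * 60.0), 400)
        trace = simulate(model, {"A0": 1.0}, t_min[-1], t_eval_min=t_min)
        mid = trace.fractions["A1"].to_numpy()
        assert is_unimodal(mid, tol=1e-9)
        assert 0.0 < mid.max() < 1.0
        # cross-check against the Bateman closed form
        k1 = model.rates.set_index("step")["k_per_s"]["A0->A1"]
        t_s = t_min * 60.0
        closed = k1 / (k2 - k1) * (np.exp(-k1 * t_s) - np.exp(-k2 * t_s))
        assert np.allclose(mid, closed, atol=1e-6)

    def test_non_normalised_init_is_rejected(self):
        net = make_linear_network([0.0, -10.0], [20.0])
        model = build_rate_model(net)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate(model, {"A0": 0.7}, 1.0)

    def test_expm_and_bdf_agree_on_a_moderate_problem(self):
        net = make_linear_network([0.0, -20.0, -35.0, -60.0], [30.0, 45.0, 55.0])
        model = build_rate_model(net)
        t_min = np.geomspace(1e-10, 1e3, 40)
        a = simulate(model, {"A0": 1.0}, t_min[-1], t_eval_min=t_min, method="BDF")
        b = simulate(model, {"A0": 1.0}, t_min[-1], t_eval_min=t_min, method="expm")
        assert np.allclose(a.fractions.to_numpy(), b.fractions.to_numpy(), atol=1e-6)


class TestConservationAndEquilibrium:
    def test_mass_conservation_on_the_paper_network(self, paper_trace):
        _, trace = paper_trace
        assert np.abs(trace.total() - 1.0).max() < 1e-6
        assert trace.fractions.to_numpy().min() >= -1e-12

    def test_long_time_populations_match_boltzmann_weights(self):
        net = make_linear_network([0.0, -12.0, 8.0, -20.0], [25.0, 40.0, 30.0])
        model = build_rate_model(net)
        t_eval = np.array([0.0, 1e9])
        trace = simulate(model, {"A0": 1.0}, 1e9, t_eval_min=t_eval, method="expm")
        eq = model.boltzmann_weights()
        np.testing.assert_allclose(trace.final().to_numpy(), eq.to_numpy(), rtol=1e-4)

    def test_pyranose_monoacetals_are_unimodal_on_the_paper_network(self, paper_trace):
        _, trace = paper_trace
        for sid in examples.PYRANOSE_MONOACETALS:
            assert is_unimodal(trace.fractions[sid].to_numpy(), tol=1e-7), sid
        # the experimentally prominent ones carry real transient weight
        assert trace.fractions["Int1_alpha"].max() > 0.05
        assert trace.fractions["Int2_alpha"].max() > 0.05

    def test_diacetal_is_nondecreasing_and_dominant_at_long_time(self, paper_trace):
        _, trace = paper_trace
        dfx = trace.fractions["DFX"].to_numpy()
        assert np.all(np.diff(dfx) >= -1e-9)
        final = trace.final()
        assert final["DFX"] > 0.9
        assert final["DFX"] == final.max()

    def test_deepening_the_diacetal_never_lowers_its_final_share(self, paper_net):
        from dataclasses import replace

        def final_share(extra):
            net = paper_net
            species = dict(net.species)
            species["DFX"] = replace(species["DFX"],
                                     g_formation=species["DFX"].g_formation + extra,
                                     energy_terms=None)
            mod = net.__class__(species=species, steps=list(net.steps),
                                references=net.references, temperature=net.temperature)
            model = MicrokineticModel(mod, mu_shifts=examples.HYDRONIUM_MU_SHIFT)
            return model.equilibrium()["DFX"]

        shares = [final_share(extra) for extra in (0.0, -5.0, -10.0, -20.0)]
        assert all(b >= a - 1e-12 for a, b in zip(shares, shares[1:]))


class TestSelectivity:
    @pytest.mark.parametrize("pyr,fur,expected", [
        (0.0, 3.0, 0.0),
        (2.5, 2.5, 50.0),
        (30.0, 70.0, 30.0),
    ])
    def test_selectivity_percent(self, pyr, fur, expected):
        assert pyranose_selectivity(pyr, fur) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        assert pyranose_selectivity(0.0, 0.0) is None

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            pyranose_selectivity(-1.0, 2.0)
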