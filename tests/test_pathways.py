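"""Free-energy profiles, energetic spans and pathway ranking."""

import numpy as np
import pytest

from acetalnet.examples import PATHWAY_SEQUENCES
from acetalnet.network import NetworkError
from acetalnet.pathways import (
    INTERMEDIATE,
    TRANSITION_STATE,
    PathwayProfile,
    ProfileState,
    apparent_barrier,
    build_profile,
    compare_anomer_routes,
    enumerate_pathways,
)
from conftest import make_linear_network


def profile_from_values(values, kinds=None):
    kinds = kinds or [INTERMEDIATE] * len(values)
    return PathwayProfile(tuple(
        ProfileState(f"s{i}", k, g) for i, (g, k) in enumerate(zip(values, kinds))
    ))


def brute_force_span(profile):
    """Independent oracle: exhaustive maximisation over ordered pairs."""
    best = 0.0
    states = profile.states
    for i, low in enumerate(states):
        if low.kind != INTERMEDIATE:
            continue
        for high in states[i + 1:]:
            best = max(best, high.g_cum - low.g_cum)
    return best


class TestBuildProfile:
    def test_single_step_inserts_ts_between_intermediates(self):
        net = make_linear_network([0.0, -10.0], [15.0])
        profile = build_profile(net, ["A0", "A1"])
        assert [(s.kind, s.g_cum) for s in profile.states] == [
            (INTERMEDIATE, 0.0), (TRANSITION_STATE, 15.0), (INTERMEDIATE, -10.0)]

    def test_cumulative_sum_oracle_two_steps(self):
        net = make_linear_network([0.0, -100.0, -80.0], [30.0, 110.0])
        profile = build_profile(net, ["A0", "A1", "A2"])
        assert [s.g_cum for s in profile.states] == [0.0, 30.0, -100.0, 10.0, -80.0]

    def test_barrierless_and_uncomputed_steps_add_no_ts(self):
        net = make_linear_network([0.0, -5.0, -8.0], [0.0, None])
        profile = build_profile(net, ["A0", "A1", "A2"])
        assert all(s.kind == INTERMEDIATE for s in profile.states)

    def test_disconnected_pair_names_the_gap(self, paper_net):
        with pytest.raises(NetworkError, match="6a.*DFX"):
            build_profile(paper_net, ["6a", "DFX"])

    def test_pathway2_ts_sits_one_kj_above_16a(self, paper_net):
        profile = build_profile(paper_net, PATHWAY_SEQUENCES["2"])
        states = {s.label: s for s in profile.states}
        assert states["TS_2d"].g_cum - states["16a"].g_cum == pytest.approx(1.0)


class TestApparentBarrier:
    def test_single_barrier(self):
        p = profile_from_values([0.0, 50.0, -10.0],
                                [INTERMEDIATE, TRANSITION_STATE, INTERMEDIATE])
        res = apparent_barrier(p)
        assert res.span == 50.0
        assert (res.low_state, res.high_state) == ("s0", "s1")

    def test_five_state_example_from_brute_force(self):
        kinds = [INTERMEDIATE, TRANSITION_STATE, INTERMEDIATE, TRANSITION_STATE,
                 INTERMEDIATE]
        p = profile_from_values([0.0, 30.0, -100.0, 10.0, -150.0], kinds)
        res = apparent_barrier(p)
        assert res.span == 110.0
        assert (res.low_state, res.high_state) == ("s2", "s3")

    def test_downhill_profile_has_zero_span(self):
        p = profile_from_values([0.0, -10.0, -30.0])
        res = apparent_barrier(p)
        assert res.span == 0.0
        assert res.low_state == res.high_state == "s0"

    def test_matches_exhaustive_pairwise_oracle_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(2, 13)
            values = rng.normal(0.0, 60.0, size=n)
            kinds = [INTERMEDIATE if rng.random() < 0.6 else TRANSITION_STATE
                     for _ in range(n)]
            kinds[0] = INTERMEDIATE
            p = profile_from_values(values, kinds)
            assert apparent_barrier(p).span == pytest.approx(brute_force_span(p))

    def test_shift_invariance(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0.0, 50.0, size=9)
        p1 = profile_from_values(values)
        p2 = profile_from_values(values + 123.456)
        assert apparent_barrier(p1).span == pytest.approx(apparent_barrier(p2).span)

    def test_reversed_profile_span_equals_maximal_descent(self):
        """Dual property: the span of the reversed profile is the forward
        profile's largest descent onto a later intermediate (brute force)."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 10))
            values = rng.normal(0.0, 40.0, size=n)
            kinds = [INTERMEDIATE if rng.random() < 0.7 else TRANSITION_STATE
                     for _ in range(n)]
            kinds[0] = kinds[-1] = INTERMEDIATE
            p = profile_from_values(values, kinds)
            rev = PathwayProfile(tuple(
                ProfileState(s.label, s.kind, s.g_cum - values[-1])
                for s in reversed(p.states)))
            descent = 0.0
            for i, high in enumerate(p.states):
                for low in p.states[i + 1:]:
                    if low.kind == INTERMEDIATE:
                        descent = max(descent, high.g_cum - low.g_cum)
            assert apparent_barrier(rev).span == pytest.approx(descent)

    def test_span_bounded_below_by_largest_single_barrier(self, paper_net):
        for pid, seq in PATHWAY_SEQUENCES.items():
            profile = build_profile(paper_net, seq)
            largest_ga = max(
                (s.g_a for a, b in zip(seq, seq[1:])
                 for s in paper_net.steps_between(a, b) if s.g_a), default=0.0)
            assert apparent_barrier(profile).span >= largest_ga - 1e-9


class TestEnumerate:
    def test_linear_toy_network_has_exactly_one_path(self):
        net = make_linear_network([0.0, -20.0, -40.0], [30.0, 25.0])
        ranked = enumerate_pathways(net, "A0", "A2")
        # the only other simple route would revisit states, so one path
        assert len(ranked) == 1
        path, res = ranked[0]
        assert path == ("A0", "A1", "A2")
        assert res.span == apparent_barrier(build_profile(net, path)).span

    def test_two_branch_toy_ranks_the_lower_span_first(self):
        from acetalnet.network import ElementaryStep, reverse_step
        net = make_linear_network([0.0, -30.0, -60.0], [40.0, 20.0])
        mid = net.species["A1"]
        net.species["B"] = mid.__class__(id="B", role="open_intermediate",
                                         stoich=(1, 0, 0, 0), g_formation=-10.0)
        for a, b, ga in [("A0", "B", 60.0), ("B", "A2", 10.0)]:
            fwd = ElementaryStep(id=f"{a}->{b}", reactant=a, product=b,
                                 delta_g=net.species[b].g_formation
                                 - net.species[a].g_formation, g_a=ga, reversible=True)
            net.steps.extend([fwd, reverse_step(fwd)])
        ranked = enumerate_pathways(net, "A0", "A2")
        spans = [res.span for _, res in ranked]
        assert spans == sorted(spans)
        assert ranked[0][1].span == pytest.approx(40.0)
        assert ranked[0][0] == ("A0", "A1", "A2")

    def test_deterministic_output(self, paper_net):
        r1 = enumerate_pathways(paper_net, "alpha_xylopyranose", "Int4_alpha")
        r2 = enumerate_pathways(paper_net, "alpha_xylopyranose", "Int4_alpha")
        assert [p for p, _ in r1] == [p for p, _ in r2]

    def test_no_route_gives_empty_list(self):
        net = make_linear_network([0.0, -20.0], [30.0])
        net.species["Z"] = net.species["A1"].__class__(
            id="Z", role="open_intermediate", stoich=(1, 0, 0, 0), g_formation=0.0)
        assert enumerate_pathways(net, "A0", "Z") == []


class TestAnomerRoutes:
    def test_published_ordering_and_spans(self, paper_net):
        df = compare_anomer_routes(
            paper_net, ["Int4_alpha", "Int4_beta", "Int5_alpha"])
        spans = dict(zip(df["target"], df["span"]))
        assert spans["Int5_alpha"] == pytest.approx(145.0, abs=0.1)
        assert spans["Int4_alpha"] == pytest.approx(152.5, abs=0.1)
        assert spans["Int4_beta"] == pytest.approx(186.2, abs=0.1)
        assert list(df["target"]) == ["Int5_alpha", "Int4_alpha", "Int4_beta"]

    def test_unreachable_target_is_recorded_as_absent(self, paper_net):
        df = compare_anomer_routes(paper_net, ["Int4_alpha", "NOPE"])
        row = df[df["target"] == "NOPE"].iloc[0]
        assert not row["present"] and np.isnan(row["span"])

    def test_sky_high_barrier_ranks_last(self):
        from acetalnet.network import ElementaryStep, reverse_step
        net = make_linear_network([0.0, -20.0, -40.0], [30.0, 25.0])
        net.species["X"] = net.species["A1"].__class__(
            id="X", role="monoacetal", stoich=(1, 0, 0, 0), g_formation=-10.0)
        fwd = ElementaryStep(id="A0->X", reactant="A0", product="X", delta_g=-10.0,
                             g_a=999.0, reversible=True)
        net.steps.extend([fwd, reverse_step(fwd)])
        df = compare_anomer_routes(net, ["A2", "X"], source="A0")
        assert list(df["target"]) == ["A2", "X"]
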