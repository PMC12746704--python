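"""Cumulative free-energy profiles and apparent barriers (energetic spans).

A pathway profile lists the states visited along a route, each at its
cumulative free energy relative to the first state; transition states are
inserted at G_intermediate + G_a.  The apparent barrier of a profile is the
largest climb from an intermediate to any *later* state — the energetic span
of the route.  Because the transformation studied here is a one-way
conversion rather than a closed catalytic cycle, no wrap-around term is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .network import ElementaryStep, NetworkError, ReactionNetwork

INTERMEDIATE = "intermediate"
TRANSITION_STATE = "transition_state"


@dataclass(frozen=True)
class ProfileState:
    label: str
    kind: str  # INTERMEDIATE or TRANSITION_STATE
    g_cum: float


@dataclass(frozen=True)
class PathwayProfile:
    states: tuple[ProfileState, ...]
    pathway_id: str | None = None

    def __len__(self):
        return len(self.states)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    def intermediates(self) -> list[ProfileState]:
        return [s for s in self.states if s.kind == INTERMEDIATE]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "label": [s.label for s in self.states],
                "kind": [s.kind for s in self.states],
                "G_cum_kJ_mol": [s.g_cum for s in self.states],
            }
        )

    def plot(self, ax=None, **kwargs):
        """Draw the free-energy diagram (flat levels joined by dashed lines)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, len(self.states)), 4))
        half = 0.3
        xs, ys = [], []
        for i, st in enumerate(self.states):
            ax.hlines(st.g_cum, i - half, i + half,
                      colors="k" if st.kind == INTERMEDIATE else "tab:red", lw=2)
            if i:
                prev = self.states[i - 1]
                ax.plot([i - 1 + half, i - half], [prev.g_cum, st.g_cum],
                        "k--", lw=0.8, alpha=0.6)
            xs.append(i)
            ys.append(st.g_cum)
        ax.set_xticks(xs)
        ax.set_xticklabels([s.label for s in self.states], rotation=90, fontsize=8)
        ax.set_ylabel("G (kJ/mol)")
        if self.pathway_id:
            ax.set_title(self.pathway_id)
        return ax


@dataclass(frozen=True)
class SpanResult:
    span: float
    low_state: str
    high_state: str
    pathway_id: str | None = None


def _pick_step(net: ReactionNetwork, a: str, b: str) -> ElementaryStep:
    steps = net.steps_between(a, b)
    if not steps:
        raise NetworkError(f"no elementary step connects {a!r} -> {b!r}")
    # deterministic choice: lowest barrier first (None = no barrier state),
    # then step id
    def key(s: ElementaryStep):
        return (s.g_a is not None, s.g_a if s.g_a is not None else 0.0, s.id)

    return sorted(steps, key=key)[0]


def build_profile(
    net: ReactionNetwork, state_sequence, pathway_id: str | None = None
) -> PathwayProfile:
    """Cumulative free-energy profile along a sequence of species ids.

    Intermediates accumulate each step's delta_g; a transition state is
    inserted at G_intermediate + g_a for steps with a positive computed
    barrier.  Steps with g_a absent (not computed / equilibrated) or printed
    as 0 (barrierless) contribute no TS state.
    """
    seq = list(state_sequence)
    if len(seq) < 1:
        raise ValueError("state_sequence must contain at least one species id")
    states = [ProfileState(seq[0], INTERMEDIATE, 0.0)]
    g = 0.0
    for a, b in zip(seq, seq[1:]):
        step = _pick_step(net, a, b)
        if step.g_a is not None and step.g_a > 0.0:
            ts_label = step.ts_id or f"TS({a}->{b})"
            states.append(ProfileState(ts_label, TRANSITION_STATE, g + step.g_a))
        g += step.delta_g
        states.append(ProfileState(b, INTERMEDIATE, g))
    return PathwayProfile(states=tuple(states), pathway_id=pathway_id)


def apparent_barrier(profile: PathwayProfile) -> SpanResult:
    """Energetic span of a profile.

    span = max over ordered pairs (i before j) of G(j) - G(i), with i
    restricted to intermediates and j any later state.  A monotone-downhill
    profile has span 0 with low = high = the first state.
    """
    states = profile.states
    if len(states) < 2:
        raise ValueError("profile needs at least two states")
    best = 0.0
    low = high = states[0].label
    min_g = None
    min_label = None
    for st in states:
        if min_label is not None:
            climb = st.g_cum - min_g
            if climb > best + 1e-12:
                best = climb
                low, high = min_label, st.label
        if st.kind == INTERMEDIATE and (min_g is None or st.g_cum < min_g):
            min_g = st.g_cum
            min_label = st.label
    return SpanResult(span=best, low_state=low, high_state=high, pathway_id=profile.pathway_id)


def _graph(net: ReactionNetwork) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    g.add_nodes_from(net.species)
    for step in net.steps:
        g.add_edge(step.reactant, step.product, key=step.id)
    return g


def enumerate_pathways(
    net: ReactionNetwork, source: str, sink: str, max_states: int = 25
) -> list[tuple[tuple[str, ...], SpanResult]]:
    """All simple paths from source to sink (<= max_states states), ranked
    ascending by apparent barrier; ties broken by path length then labels.

    Returns an empty list when no route exists.
    """
    if source not in net.species:
        raise NetworkError(f"unknown source species {source!r}")
    if sink not in net.species:
        raise NetworkError(f"unknown sink species {sink!r}")
    g = _graph(net)
    results = []
    for path in nx.all_simple_paths(g, source, sink, cutoff=max_states - 1):
        profile = build_profile(net, path)
        results.append((tuple(path), apparent_barrier(profile)))
    results.sort(key=lambda item: (item[1].span, len(item[0]), item[0]))
    return results


def compare_anomer_routes(
    net: ReactionNetwork,
    targets,
    source: str = "alpha_xylopyranose",
    max_states: int = 25,
):
    """Minimal apparent barrier from ``source`` to each target species.

    Returns a DataFrame sorted ascending by span; targets with no route are
    recorded as absent (NaN span), not raised.
    """
    import pandas as pd

    rows = []
    for target in targets:
        if target not in net.species:
            rows.append({"target": target, "span": float("nan"), "low_state": None,
                         "high_state": None, "n_routes": 0, "present": False})
            continue
        ranked = enumerate_pathways(net, source, target, max_states=max_states)
        if not ranked:
            rows.append({"target": target, "span": float("nan"), "low_state": None,
                         "high_state": None, "n_routes": 0, "present": True})
        else:
            _, best = ranked[0]
            rows.append({"target": target, "span": best.span, "low_state": best.low_state,
                         "high_state": best.high_state, "n_routes": len(ranked),
                         "present": True})
    df = pd.DataFrame(rows)
    return df.sort_values("span", na_position="last").reset_index(drop=True)
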