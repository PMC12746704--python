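import numpy as np
import pytest

from acetalnet import examples
from acetalnet.kinetics import MicrokineticModel
from acetalnet.network import ElementaryStep, ReactionNetwork, Species, reverse_step


@pytest.fixture(scope="session")
def paper_net():
    """The packaged xylose + formaldehyde network."""
    return examples.xylose_formaldehyde_network()


@pytest.fixture(scope="session")
def paper_trace(paper_net):
    """One wide-timescale kinetic run on the packaged network, shared by the
    phenomenology tests (log-spaced sampling out to complete conversion)."""
    model = MicrokineticModel(paper_net, mu_shifts=examples.HYDRONIUM_MU_SHIFT)
    t_eval = np.concatenate([[0.0], np.geomspace(1e-9, 1e11, 200)])
    trace = model.simulate({"alpha_xylopyranose": 1.0}, t_end_min=1e11,
                           t_eval_min=t_eval, method="expm")
    return model, trace


def make_linear_network(g_values, g_a_values, temperature=333.15):
    """Chain network A0 -> A1 -> ... with given state energies and barriers.

    Barriers may contain None (fast equilibrated step).  Reverse steps are
    added automatically.  Used as a hand-built oracle network in tests.
    """
    ids = [f"A{i}" for i in range(len(g_values))]
    species = {
        "HCHO": Species(id="HCHO", role="reference", stoich=(0, 1, 0, 0), g_formation=0.0),
        "H2O": Species(id="H2O", role="reference", stoich=(0, 0, 1, 0), g_formation=0.0),
        "H3O+": Species(id="H3O+", role="reference", charge=1, stoich=(0, 0, 0, 1),
                        g_formation=0.0),
    }
    for sid, g in zip(ids, g_values):
        species[sid] = Species(id=sid, role="sugar_tautomer" if sid == "A0" else
                               "open_intermediate", stoich=(1, 0, 0, 0), g_formation=g)
    steps = []
    for (a, b), g_a in zip(zip(ids, ids[1:]), g_a_values):
        fwd = ElementaryStep(id=f"{a}->{b}", reactant=a, product=b,
                             delta_g=species[b].g_formation - species[a].g_formation,
                             g_a=g_a, reversible=True)
        steps.append(fwd)
        steps.append(reverse_step(fwd))
    return ReactionNetwork(species=species, steps=steps,
                           references=(ids[0], "HCHO", "H2O", "H3O+"),
                           temperature=temperature)
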