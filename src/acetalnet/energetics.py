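"""Formation free energies and step free energies with proton-transfer
referencing, plus uniform solvation shifts.

Each species' formation free energy is its Gibbs energy E + ZPE - T*S minus
the stoichiometric combination of the four reference species' Gibbs energies:

    G_i = (E + ZPE - T*S)_i - a*g_sugar - b*g_HCHO - c*g_H2O - d*g_H3O+

so that every network state shares one energy zero and proton-addition steps
(A + H3O+ -> B + H2O) reduce to plain differences G_B - G_A.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .constants import convert_energy  # re-exported for table/CLI use
from .network import EnergyTerms, NetworkError, ReactionNetwork, Species

__all__ = [
    "formation_free_energy",
    "step_delta_g",
    "apply_solvation_shift",
    "convert_energy",
    "network_formation_energies",
    "EnergyTerms",
]


def formation_free_energy(species: Species, refs, T: float) -> float:
    """Formation free energy (kJ/mol) of ``species`` at temperature ``T``.

    ``refs`` is the four reference species in (sugar, HCHO, H2O, H3O+) order,
    matching the species' ``stoich = (a, b, c, d)``.  The sugar reference
    defaults to alpha-D-xylopyranose but any tautomer id may be configured in
    the network's ``references``.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    if species.energy_terms is None:
        raise NetworkError(f"species {species.id!r} has no energy terms")
    refs = tuple(refs)
    if len(refs) != 4:
        raise ValueError("exactly four reference species are required")
    g = species.energy_terms.gibbs(T)
    for coeff, ref in zip(species.stoich, refs):
        if ref.energy_terms is None:
            raise NetworkError(f"reference species {ref.id!r} has no energy terms")
        g -= coeff * ref.energy_terms.gibbs(T)
    return g


def step_delta_g(
    g_a: float,
    g_b: float,
    g_h2o: float = 0.0,
    g_h3o: float = 0.0,
    proton_transfer: bool = False,
) -> float:
    """Reaction free energy of A -> B (kJ/mol).

    With ``proton_transfer`` the step is A + H3O+ -> B + H2O and
    dG = G_B + G_H2O - G_A - G_H3O+.  When all energies are formation free
    energies on the common reference, G_H2O = G_H3O+ = 0 and both branches
    coincide.
    """
    if proton_transfer:
        return g_b + g_h2o - g_a - g_h3o
    return g_b - g_a


def apply_solvation_shift(
    net: ReactionNetwork, shift_per_species: float
) -> tuple[ReactionNetwork, pd.DataFrame]:
    """Shift every sugar-derived state's formation energy by a uniform amount.

    Emulates applying one implicit-solvent correction per network state (one
    solvated "molecule" each); since every elementary step converts one state
    into one state, all step free energies are invariant.  Returns the shifted
    network and a table of step dG before/after.
    """
    species = {}
    for sid, sp in net.species.items():
        if sp.stoich[0] >= 1 and sp.g_formation is not None:
            species[sid] = replace(sp, g_formation=sp.g_formation + shift_per_species)
        else:
            species[sid] = sp
    shifted = ReactionNetwork(
        species=species,
        steps=list(net.steps),
        references=net.references,
        temperature=net.temperature,
    )

    rows = []
    for step in net.steps:
        try:
            before = net.g_formation(step.product) - net.g_formation(step.reactant)
            after = shifted.g_formation(step.product) - shifted.g_formation(step.reactant)
        except NetworkError:
            continue
        rows.append({"step": step.id, "delta_g_before": before, "delta_g_after": after})
    return shifted, pd.DataFrame(rows)


def network_formation_energies(net: ReactionNetwork, T: float | None = None) -> pd.Series:
    """Formation free energies of all species, preferring Eq-style recomputation
    from energy terms when present, else the stored G_formation."""
    T = net.temperature if T is None else T
    refs = net.reference_species()
    out = {}
    for sid, sp in net.species.items():
        if sp.energy_terms is not None:
            out[sid] = formation_free_energy(sp, refs, T)
        elif sp.g_formation is not None:
            out[sid] = sp.g_formation
    return pd.Series(out, name="G_kJ_mol")
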