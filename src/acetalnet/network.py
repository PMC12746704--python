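"""Reaction-network data model and its on-disk JSON representation.

Species are labelled thermodynamic states, not molecular structures.  Every
network state is referenced to a stoichiometric combination of four reference
species (the sugar reference, HCHO, H2O and H3O+), recorded per species as the
integer vector ``stoich = (a, b, c, d)``.  Under that referencing all four
reference species have formation free energy zero and every step free energy
is a plain difference of formation free energies, including proton-addition
steps (A + H3O+ -> B + H2O).

The on-disk format is JSON (see ``data/network.schema.json``) with explicit
units; energies are normalised to kJ/mol on load.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .constants import DEFAULT_TEMPERATURE, convert_energy

SCHEMA_VERSION = "1.0"

ROLES = frozenset({
    "reference",
    "sugar_tautomer",
    "open_intermediate",
    "protonated_intermediate",
    "monoacetal",
    "diacetal",
    "transition_state",
    "small_molecule",
})

#: Tolerance for the g_a >= delta_g consistency check (printed values are
#: rounded to 0.1 kJ/mol).
GA_TOLERANCE = 0.5

#: Tolerance for forward/reverse delta_g antisymmetry, kJ/mol.
REVERSE_TOLERANCE = 1e-6


class NetworkError(ValueError):
    """Inconsistent network data (unresolved ids, broken energetics...)."""


class NetworkLoadError(NetworkError):
    """A network file could not be parsed into a valid ReactionNetwork."""


@dataclass(frozen=True)
class EnergyTerms:
    """Per-species electronic energy, zero-point energy and entropy.

    E and ZPE in kJ/mol, S in J/(K mol).
    """

    E: float
    ZPE: float
    S: float

    def __post_init__(self):
        if self.ZPE < 0:
            raise ValueError(f"ZPE must be >= 0, got {self.ZPE}")
        if self.S < 0:
            raise ValueError(f"S must be >= 0, got {self.S}")

    def gibbs(self, T: float) -> float:
        """E + ZPE - T*S in kJ/mol (absolute, not referenced)."""
        if T <= 0:
            raise ValueError(f"temperature must be positive, got {T}")
        return self.E + self.ZPE - T * self.S / 1000.0


@dataclass(frozen=True)
class Species:
    """A network node: intermediate, reference molecule or small molecule.

    ``stoich = (a, b, c, d)`` counts the reference species (sugar, HCHO, H2O,
    H3O+) composing this state; entries may be negative (e.g. an acetal is
    sugar + aldehyde - water).  Only the hydronium reference carries charge,
    so ``charge == d`` for every species.
    """

    id: str
    role: str
    charge: int = 0
    stoich: tuple[int, int, int, int] = (0, 0, 0, 0)
    energy_terms: EnergyTerms | None = None
    g_formation: float | None = None
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for species {self.id!r}")
        if len(self.stoich) != 4:
            raise ValueError(f"stoich of {self.id!r} must have 4 entries")


@dataclass(frozen=True)
class ElementaryStep:
    """A directed elementary step with reaction and activation free energies.

    ``g_a`` is the activation free energy of the *forward* direction, relative
    to the reactant state (plus any consumed co-reagents).  ``g_a is None``
    means the barrier was not computed; ``g_a == 0.0`` means barrierless.
    ``consumes``/``releases`` are multisets of small-molecule ids balancing
    the step.
    """

    id: str
    reactant: str
    product: str
    delta_g: float
    g_a: float | None = None
    ts_id: str | None = None
    consumes: Mapping[str, int] = field(default_factory=dict)
    releases: Mapping[str, int] = field(default_factory=dict)
    pathway_tags: frozenset[str] = frozenset()
    reversible: bool = False

    def __post_init__(self):
        object.__setattr__(self, "consumes", dict(self.consumes))
        object.__setattr__(self, "releases", dict(self.releases))
        object.__setattr__(self, "pathway_tags", frozenset(str(t) for t in self.pathway_tags))


def reverse_step(step: ElementaryStep, id_suffix: str = "_rev") -> ElementaryStep:
    """Return the reverse of ``step`` (same transition state).

    delta_g' = -delta_g and, when a barrier is present, g_a' = g_a - delta_g.
    Raises :class:`NetworkError` if the reverse barrier would be negative
    (the forward energetics were inconsistent to begin with).
    """
    g_a_rev = None
    if step.g_a is not None:
        g_a_rev = step.g_a - step.delta_g
        if g_a_rev < -1e-9:
            raise NetworkError(
                f"step {step.id!r}: reverse activation free energy "
                f"{g_a_rev:.3f} kJ/mol is negative (g_a < delta_g)"
            )
        g_a_rev = max(g_a_rev, 0.0)
    rev_id = step.id[: -len(id_suffix)] if step.id.endswith(id_suffix) else step.id + id_suffix
    return ElementaryStep(
        id=rev_id,
        reactant=step.product,
        product=step.reactant,
        delta_g=-step.delta_g,
        g_a=g_a_rev,
        ts_id=step.ts_id,
        consumes=dict(step.releases),
        releases=dict(step.consumes),
        pathway_tags=step.pathway_tags,
        reversible=step.reversible,
    )


@dataclass
class ReactionNetwork:
    """Species, elementary steps and the four reference ids."""

    species: dict[str, Species]
    steps: list[ElementaryStep]
    references: tuple[str, str, str, str]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if len(self.references) != 4:
            raise NetworkError("exactly four reference species are required")
        for step in self.steps:
            for endpoint in (step.reactant, step.product):
                if endpoint not in self.species:
                    raise NetworkError(
                        f"step {step.id!r} references undeclared species {endpoint!r}"
                    )

    # -- convenience accessors -------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def get_species(self, species_id: str) -> Species:
        try:
            return self.species[species_id]
        except KeyError:
            for sp in self.species.values():
                if species_id in sp.aliases:
                    return sp
            raise NetworkError(f"unknown species id {species_id!r}") from None

    def steps_between(self, reactant: str, product: str) -> list[ElementaryStep]:
        return [s for s in self.steps if s.reactant == reactant and s.product == product]

    def g_formation(self, species_id: str) -> float:
        sp = self.get_species(species_id)
        if sp.g_formation is not None:
            return sp.g_formation
        if sp.energy_terms is not None:
            from .energetics import formation_free_energy

            return formation_free_energy(sp, self.reference_species(), self.temperature)
        raise NetworkError(f"species {species_id!r} has neither G_formation nor energy terms")

    def reference_species(self) -> tuple[Species, Species, Species, Species]:
        return tuple(self.species[r] for r in self.references)  # type: ignore[return-value]

    def sugar_states(self) -> list[Species]:
        """Species carrying the sugar moiety (stoich a >= 1), in insertion order."""
        return [sp for sp in self.species.values() if sp.stoich[0] >= 1]

    def summary(self) -> str:
        by_role = Counter(sp.role for sp in self.species.values())
        by_tag = Counter(tag for s in self.steps for tag in (s.pathway_tags or {"untagged"}))
        lines = [
            f"ReactionNetwork: {self.n_species} species, {self.n_steps} steps "
            f"at T = {self.temperature} K",
            "species by role:",
        ]
        lines += [f"  {role:24s} {n:4d}" for role, n in sorted(by_role.items())]
        lines.append("steps by pathway tag:")
        lines += [f"  {tag:24s} {n:4d}" for tag, n in sorted(by_tag.items())]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One broken invariant; ``target`` is the offending species/step id."""

    target: str
    rule: str
    message: str

    def __str__(self):
        return f"[{self.rule}] {self.target}: {self.message}"


def _composition_vector(sp: Species, consumed: Mapping[str, int],
                        small_molecule_stoich: Mapping[str, tuple[int, int, int, int]]):
    vec = list(sp.stoich)
    for mol, count in consumed.items():
        mol_vec = small_molecule_stoich.get(mol)
        if mol_vec is None:
            return None
        for k in range(4):
            vec[k] += count * mol_vec[k]
    return tuple(vec)


def validate_network(net: ReactionNetwork) -> list[Violation]:
    """Check every type invariant; violations are data, not exceptions."""
    out: list[Violation] = []

    small = {
        sid: net.species[sid].stoich
        for sid in net.species
        if net.species[sid].stoich[0] == 0
    }

    for sp in net.species.values():
        if sp.charge != sp.stoich[3]:
            out.append(Violation(sp.id, "charge", f"charge {sp.charge} != hydronium count {sp.stoich[3]}"))
        if sp.energy_terms is None and sp.g_formation is None:
            out.append(Violation(sp.id, "energy", "neither energy_terms nor G_formation given"))
    for ref in net.references:
        sp = net.species.get(ref)
        if sp is None:
            out.append(Violation(ref, "reference", "reference species not declared"))
        elif sp.g_formation not in (None, 0.0) and abs(sp.g_formation) > 1e-9:
            out.append(Violation(ref, "reference", f"reference G_formation = {sp.g_formation} != 0"))

    by_endpoints: dict[tuple[str, str], list[ElementaryStep]] = {}
    for step in net.steps:
        by_endpoints.setdefault((step.reactant, step.product), []).append(step)

    for step in net.steps:
        if step.g_a is not None:
            if step.g_a < 0:
                out.append(Violation(step.id, "barrier", f"negative activation free energy ({step.g_a} kJ/mol)"))
            elif step.g_a < step.delta_g - GA_TOLERANCE:
                out.append(Violation(
                    step.id, "barrier",
                    f"g_a = {step.g_a} kJ/mol below delta_g = {step.delta_g} kJ/mol",
                ))
        lhs = _composition_vector(net.species[step.reactant], step.consumes, small)
        rhs = _composition_vector(net.species[step.product], step.releases, small)
        if lhs is None or rhs is None:
            out.append(Violation(step.id, "balance", "consumes/releases refer to a non-small-molecule id"))
        elif lhs != rhs:
            out.append(Violation(step.id, "balance", f"stoichiometry imbalance: {lhs} != {rhs}"))
        if step.reversible:
            partners = by_endpoints.get((step.product, step.reactant), [])
            matches = [p for p in partners if abs(p.delta_g + step.delta_g) <= REVERSE_TOLERANCE]
            if not partners:
                out.append(Violation(step.id, "reverse", "marked reversible but no reverse step exists"))
            elif not matches:
                gap = min(abs(p.delta_g + step.delta_g) for p in partners)
                out.append(Violation(step.id, "reverse", f"reverse mismatch {gap:.6g} kJ/mol"))
    return out


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------

_UNIT_KEYS = ("delta_g", "g_a")


def _species_from_dict(d: dict, scale: float, path) -> Species:
    for key in ("id", "role"):
        if key not in d:
            raise NetworkLoadError(f"{path}: species entry missing {key!r}: {d}")
    terms = None
    if d.get("energy_terms") is not None:
        et = d["energy_terms"]
        try:
            terms = EnergyTerms(E=et["E"] * scale, ZPE=et["ZPE"] * scale, S=et["S"])
        except (KeyError, ValueError) as exc:
            raise NetworkLoadError(f"{path}: bad energy_terms for {d['id']!r}: {exc}") from None
    g_form = d.get("g_formation")
    return Species(
        id=d["id"],
        role=d["role"],
        charge=int(d.get("charge", 0)),
        stoich=tuple(int(x) for x in d.get("stoich", (0, 0, 0, 0))),
        energy_terms=terms,
        g_formation=None if g_form is None else g_form * scale,
        aliases=tuple(d.get("aliases", ())),
    )


def _step_from_dict(d: dict, scale: float, path) -> ElementaryStep:
    for key in ("id", "reactant", "product", "delta_g"):
        if key not in d:
            raise NetworkLoadError(f"{path}: step entry missing {key!r}: {d}")
    return ElementaryStep(
        id=d["id"],
        reactant=d["reactant"],
        product=d["product"],
        delta_g=d["delta_g"] * scale,
        g_a=None if d.get("g_a") is None else d["g_a"] * scale,
        ts_id=d.get("ts_id"),
        consumes=d.get("consumes", {}),
        releases=d.get("releases", {}),
        pathway_tags=frozenset(str(t) for t in d.get("pathway_tags", ())),
        reversible=bool(d.get("reversible", False)),
    )


def network_from_dict(payload: dict, path="<dict>") -> ReactionNetwork:
    if "units" not in payload:
        raise NetworkLoadError(f"{path}: top-level 'units' field is required")
    units = payload["units"]
    if units not in ("kJ/mol", "eV"):
        raise NetworkLoadError(f"{path}: unsupported units {units!r} (use 'kJ/mol' or 'eV')")
    scale = convert_energy(1.0, units, "kJ/mol")
    refs = payload.get("references")
    if not refs or len(refs) != 4:
        raise NetworkLoadError(f"{path}: 'references' must list exactly four species ids")

    species: dict[str, Species] = {}
    for entry in payload.get("species", []):
        sp = _species_from_dict(entry, scale, path)
        if sp.id in species:
            raise NetworkLoadError(f"{path}: duplicate species id {sp.id!r}")
        species[sp.id] = sp

    steps: list[ElementaryStep] = []
    seen_step_ids: set[str] = set()
    for entry in payload.get("steps", []):
        step = _step_from_dict(entry, scale, path)
        if step.id in seen_step_ids:
            raise NetworkLoadError(f"{path}: duplicate step id {step.id!r}")
        seen_step_ids.add(step.id)
        for endpoint in (step.reactant, step.product):
            if endpoint not in species:
                raise NetworkLoadError(
                    f"{path}: step {step.id!r} references undeclared species {endpoint!r}"
                )
        steps.append(step)

    for ref in refs:
        if ref not in species:
            raise NetworkLoadError(f"{path}: reference species {ref!r} not declared")

    for sp in species.values():
        if sp.energy_terms is None and sp.g_formation is None:
            raise NetworkLoadError(
                f"{path}: species {sp.id!r} has neither energy_terms nor g_formation"
            )

    return ReactionNetwork(
        species=species,
        steps=steps,
        references=tuple(refs),
        temperature=float(payload.get("temperature_K", DEFAULT_TEMPERATURE)),
    )


def load_network(path) -> ReactionNetwork:
    """Load a network JSON file, normalising energies to kJ/mol."""
    path = Path(path)
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkLoadError(f"{path}: not valid JSON ({exc})") from None
    return network_from_dict(payload, path)


def network_to_dict(net: ReactionNetwork) -> dict:
    species = []
    for sp in net.species.values():
        d: dict = {"id": sp.id, "role": sp.role, "charge": sp.charge, "stoich": list(sp.stoich)}
        if sp.aliases:
            d["aliases"] = list(sp.aliases)
        if sp.energy_terms is not None:
            d["energy_terms"] = {"E": sp.energy_terms.E, "ZPE": sp.energy_terms.ZPE, "S": sp.energy_terms.S}
        if sp.g_formation is not None:
            d["g_formation"] = sp.g_formation
        species.append(d)
    steps = []
    for s in net.steps:
        d = {
            "id": s.id,
            "reactant": s.reactant,
            "product": s.product,
            "delta_g": s.delta_g,
            "reversible": s.reversible,
        }
        if s.g_a is not None:
            d["g_a"] = s.g_a
        if s.ts_id:
            d["ts_id"] = s.ts_id
        if s.consumes:
            d["consumes"] = dict(s.consumes)
        if s.releases:
            d["releases"] = dict(s.releases)
        if s.pathway_tags:
            d["pathway_tags"] = sorted(s.pathway_tags)
        steps.append(d)
    return {
        "schema_version": SCHEMA_VERSION,
        "units": "kJ/mol",
        "temperature_K": net.temperature,
        "references": list(net.references),
        "species": species,
        "steps": steps,
    }


def save_network(net: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)
        fh.write("\n")


def subnetwork(net: ReactionNetwork, species_ids: Iterable[str]) -> ReactionNetwork:
    """Restrict a network to the given species (plus the references)."""
    keep = set(species_ids) | set(net.references)
    species = {sid: sp for sid, sp in net.species.items() if sid in keep}
    steps = [s for s in net.steps if s.reactant in keep and s.product in keep]
    return ReactionNetwork(
        species=species, steps=steps, references=net.references, temperature=net.temperature
    )
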