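"""Conceptual-DFT reactivity descriptors of aldehydes.

From frontier-orbital energies: electronegativity mu = (e_HOMO + e_LUMO)/2,
chemical hardness eta = (e_LUMO - e_HOMO)/2, and the Parr electrophilicity
index EI = mu^2 / (2 eta).  The carbonyl-carbon electrophilicity EI_-CHO is
EI weighted by the Mulliken spin density at the carbonyl carbon of the
radical state; the condensed Fukui index is the Mulliken-charge difference
between radical and neutral species.  Aldehydes with EI_-CHO above roughly
28-29 kcal/mol stabilise both pyranose and furanose acetals of xylose;
weaker electrophiles are restricted to the less strained furanose acetals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .constants import convert_energy

PYRANOSE_AND_FURANOSE = "pyranose_and_furanose"
FURANOSE_ONLY = "furanose_only"
BOUNDARY = "boundary"

#: EI_-CHO band (kcal/mol) separating the two acetal-accessibility regimes;
#: inclusive on both ends for the boundary class.
DEFAULT_THRESHOLD_BAND = (28.0, 29.0)


def conceptual_dft(e_homo: float, e_lumo: float) -> tuple[float, float, float]:
    """(mu, eta, EI) from frontier-orbital energies in any consistent unit.

    Requires e_lumo > e_homo (positive hardness); EI carries the unit of the
    inputs and scales linearly under a common rescaling of both orbitals.
    """
    if e_lumo <= e_homo:
        raise ValueError(
            f"e_lumo ({e_lumo}) must exceed e_homo ({e_homo}): hardness would be <= 0"
        )
    mu = (e_homo + e_lumo) / 2.0
    eta = (e_lumo - e_homo) / 2.0
    ei = mu * mu / (2.0 * eta)
    return mu, eta, ei


def ei_cho(ei: float, spin_density_c: float) -> float:
    """Carbonyl-carbon electrophilicity: EI weighted by the carbon spin
    density of the radical state (Mulliken populations may slightly exceed 1)."""
    if spin_density_c < 0:
        raise ValueError(f"spin density must be non-negative, got {spin_density_c}")
    return ei * spin_density_c


def fukui_index(q_radical: float, q_neutral: float) -> float:
    """Condensed Fukui index: Mulliken charge difference radical - neutral."""
    return q_radical - q_neutral


def classify_acetal_scope(
    ei_cho_kcal: float, threshold_band: tuple[float, float] = DEFAULT_THRESHOLD_BAND
) -> str:
    """Acetal-accessibility class from EI_-CHO (kcal/mol).

    Above the band both pyranose and furanose monoacetals are accessible
    (formaldehyde-like); below it only furanose acetals form; within the band
    (inclusive) the outcome is boundary.
    """
    lo, hi = threshold_band
    if lo > hi:
        raise ValueError("threshold band must be (low, high)")
    if ei_cho_kcal > hi:
        return PYRANOSE_AND_FURANOSE
    if ei_cho_kcal < lo:
        return FURANOSE_ONLY
    return BOUNDARY


@dataclass(frozen=True)
class AldehydeDescriptors:
    """Electronic-structure descriptors of one aldehyde (energies in kcal/mol)."""

    name: str
    e_homo: float
    e_lumo: float
    mu: float
    eta: float
    ei: float
    spin_density_c: float
    ei_cho: float
    q_mulliken_neutral: float
    q_mulliken_radical: float
    fukui_c: float

    def __post_init__(self):
        if self.e_lumo <= self.e_homo:
            raise ValueError(f"{self.name}: e_lumo must exceed e_homo")
        if not (0.0 <= self.spin_density_c <= 1.2):
            raise ValueError(f"{self.name}: spin density {self.spin_density_c} outside [0, 1.2]")

    @property
    def acetal_scope(self) -> str:
        return classify_acetal_scope(self.ei_cho)


def from_orbitals(
    name: str,
    e_homo: float,
    e_lumo: float,
    spin_density_c: float,
    q_neutral: float,
    q_radical: float,
    unit: str = "kcal/mol",
) -> AldehydeDescriptors:
    """Build the full descriptor record; orbital energies are accepted in
    Hartree, eV, kJ/mol or kcal/mol and reported in kcal/mol."""
    e_h = convert_energy(e_homo, unit, "kcal/mol")
    e_l = convert_energy(e_lumo, unit, "kcal/mol")
    mu, eta, ei = conceptual_dft(e_h, e_l)
    return AldehydeDescriptors(
        name=name,
        e_homo=e_h,
        e_lumo=e_l,
        mu=mu,
        eta=eta,
        ei=ei,
        spin_density_c=spin_density_c,
        ei_cho=ei_cho(ei, spin_density_c),
        q_mulliken_neutral=q_neutral,
        q_mulliken_radical=q_radical,
        fukui_c=fukui_index(q_radical, q_neutral),
    )


def compute_descriptor_table(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptor pipeline over an input CSV-style table.

    Expects columns name, e_homo, e_lumo, unit, spin_density_C, q_neutral,
    q_radical; returns one row per aldehyde with mu/eta/ei/ei_cho (kcal/mol),
    fukui_C and the acetal-scope class, sorted by descending EI_-CHO.
    """
    records = []
    for row in table.itertuples(index=False):
        desc = from_orbitals(
            name=row.name,
            e_homo=row.e_homo,
            e_lumo=row.e_lumo,
            spin_density_c=row.spin_density_C,
            q_neutral=row.q_neutral,
            q_radical=row.q_radical,
            unit=getattr(row, "unit", "kcal/mol"),
        )
        records.append({
            "name": desc.name,
            "e_homo_kcal": desc.e_homo,
            "e_lumo_kcal": desc.e_lumo,
            "mu_kcal": desc.mu,
            "eta_kcal": desc.eta,
            "ei_kcal": desc.ei,
            "spin_density_C": desc.spin_density_c,
            "ei_cho_kcal": desc.ei_cho,
            "fukui_C": desc.fukui_c,
            "acetal_scope": desc.acetal_scope,
        })
    return rank_aldehydes(pd.DataFrame(records))


def rank_aldehydes(table: pd.DataFrame, by: str = "ei_cho_kcal") -> pd.DataFrame:
    """Deterministic ordering by descending EI_-CHO; ties break alphabetically."""
    if len(table) < 1:
        raise ValueError("need at least one aldehyde to rank")
    return (
        table.sort_values([by, "name"], ascending=[False, True])
        .reset_index(drop=True)
    )
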