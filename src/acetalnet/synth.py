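"""Synthetic-data generators for every input the pipeline consumes.

Each generator is a pure function of its configuration and seed, emulating
the corresponding measurement protocol: van't Hoff equilibrium series on the
20-140 degC / 10 degC NMR grid with multiplicative lognormal noise on K
(peak-area ratios are ratio data); kinetic traces on the operando 6-minute
sampling cadence with additive truncated-Gaussian noise renormalised per
time point; aldehyde descriptor tables whose EI_-CHO values straddle the
28-29 kcal/mol accessibility band; and random reaction networks built from
latent per-species potentials so that loop closure and reverse-step
consistency hold exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R_J
from .kinetics import RateModel, simulate
from .network import ElementaryStep, ReactionNetwork, Species, reverse_step
from .thermo import EquilibriumSeries


@dataclass(frozen=True)
class VantHoffConfig:
    """Truth parameters and protocol of the tautomer-equilibrium experiment."""

    dh: float = 11.3            # kJ/mol, apparent reaction enthalpy
    ds: float = 13.6            # J/(K mol), apparent reaction entropy
    t_min_c: float = 20.0
    t_max_c: float = 140.0
    t_step_c: float = 10.0
    sigma_ln_k: float = 0.02    # lognormal noise on K

    def grid_kelvin(self) -> np.ndarray:
        n = int(round((self.t_max_c - self.t_min_c) / self.t_step_c)) + 1
        return 273.15 + self.t_min_c + self.t_step_c * np.arange(n)


@dataclass(frozen=True)
class KineticsConfig:
    """Operando sampling protocol: one point per 6 min over 10 h."""

    cadence_min: float = 6.0
    t_end_min: float = 600.0
    sigma: float = 0.005        # additive noise on mole fractions


@dataclass(frozen=True)
class DescriptorConfig:
    n_aldehydes: int = 6
    ei_cho_range: tuple[float, float] = (15.0, 40.0)  # kcal/mol, straddles 28-29


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    vant_hoff: VantHoffConfig = field(default_factory=VantHoffConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    descriptors: DescriptorConfig = field(default_factory=DescriptorConfig)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_vant_hoff(
    config: VantHoffConfig | None = None, seed: int = 0, pair: str = "pyranose->furanose"
) -> EquilibriumSeries:
    """K(T) = exp(-dH/RT + dS/R) with multiplicative lognormal noise."""
    cfg = config or VantHoffConfig()
    if cfg.sigma_ln_k < 0:
        raise ValueError("sigma_ln_k must be >= 0")
    t = cfg.grid_kelvin()
    k_true = np.exp(-cfg.dh * 1000.0 / (R_J * t) + cfg.ds / R_J)
    noise = _rng(seed).normal(0.0, cfg.sigma_ln_k, size=t.shape) if cfg.sigma_ln_k else 0.0
    return EquilibriumSeries(t, k_true * np.exp(noise), pair=pair)


def gen_peak_area_table(
    config: VantHoffConfig | None = None, seed: int = 0, total_area: float = 100.0
) -> pd.DataFrame:
    """Long-form NMR peak-area table consistent with ``gen_vant_hoff``:
    pyranose and furanose areas whose ratio reproduces the noisy K series."""
    series = gen_vant_hoff(config, seed)
    rows = []
    for t_k, k in zip(series.temperatures, series.k_values):
        fur = total_area * k / (1.0 + k)
        pyr = total_area - fur
        rows.append({"temperature_C": t_k - 273.15, "tautomer": "pyranose", "peak_area": pyr})
        rows.append({"temperature_C": t_k - 273.15, "tautomer": "furanose", "peak_area": fur})
    return pd.DataFrame(rows)


def gen_kinetic_observations(
    model: RateModel,
    init,
    config: KineticsConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate, sample on the observation cadence, add truncated-at-zero
    Gaussian noise and renormalise each time point."""
    cfg = config or KineticsConfig()
    if cfg.sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    n = int(round(cfg.t_end_min / cfg.cadence_min)) + 1
    t_eval = cfg.cadence_min * np.arange(n)
    trace = simulate(model, init, t_end_min=cfg.t_end_min, t_eval_min=t_eval)
    frac = trace.fractions.to_numpy()
    if cfg.sigma > 0:
        frac = frac + _rng(seed).normal(0.0, cfg.sigma, size=frac.shape)
        frac = np.clip(frac, 0.0, None)
        frac /= frac.sum(axis=1, keepdims=True)
    out = pd.DataFrame(frac, columns=trace.fractions.columns)
    out.insert(0, "time_min", t_eval)
    return out


def gen_descriptor_table(config: DescriptorConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Synthetic aldehyde descriptor table (shape of a frontier-orbital /
    population-analysis summary).

    EI_-CHO targets are spread across the configured range (guaranteeing at
    least one aldehyde in each accessibility class when the range straddles
    the 28-29 kcal/mol band) and the orbital energies are reverse-engineered
    so the conceptual-DFT pipeline reproduces them exactly.
    """
    cfg = config or DescriptorConfig()
    if cfg.n_aldehydes < 2:
        raise ValueError("need at least two aldehydes")
    rng = _rng(seed)
    lo, hi = cfg.ei_cho_range
    targets = np.linspace(hi, lo, cfg.n_aldehydes)  # descending, FA-like first
    rows = []
    for i, ei_cho_target in enumerate(targets):
        rho = rng.uniform(0.6, 1.0)
        ei_mol = ei_cho_target / rho                 # kcal/mol
        eta = rng.uniform(80.0, 140.0)               # kcal/mol
        mu = -np.sqrt(2.0 * eta * ei_mol)            # electronegativity < 0
        q_neutral = rng.uniform(0.05, 0.25)
        fukui = rng.uniform(0.1, 0.4)
        rows.append({
            "name": f"aldehyde_{i:02d}",
            "e_homo": mu - eta,
            "e_lumo": mu + eta,
            "unit": "kcal/mol",
            "spin_density_C": rho,
            "q_neutral": q_neutral,
            "q_radical": q_neutral + fukui,
        })
    return pd.DataFrame(rows)


def gen_toy_network(
    n_intermediates: int = 6,
    seed: int = 0,
    extra_edge_prob: float = 0.3,
    temperature: float = 333.15,
) -> ReactionNetwork:
    """Random connected reaction network with exact thermodynamic consistency.

    Species free energies are latent potentials; each step's dG is a
    potential difference (so every loop closes exactly) and its barrier is
    max(0, dG) plus a positive offset.  All steps are stored with their
    explicit reverse, so the network validates clean for any seed.
    """
    if n_intermediates < 2:
        raise ValueError("need at least two intermediates")
    rng = _rng(seed)
    ids = [f"S{i}" for i in range(n_intermediates)]
    potentials = dict(zip(ids, rng.uniform(-100.0, 50.0, size=n_intermediates)))
    potentials[ids[0]] = 0.0  # the sugar reference state

    refs = (ids[0], "HCHO", "H2O", "H3O+")
    species = {
        ids[0]: Species(id=ids[0], role="sugar_tautomer", stoich=(1, 0, 0, 0),
                        g_formation=0.0),
        "HCHO": Species(id="HCHO", role="reference", stoich=(0, 1, 0, 0), g_formation=0.0),
        "H2O": Species(id="H2O", role="reference", stoich=(0, 0, 1, 0), g_formation=0.0),
        "H3O+": Species(id="H3O+", role="reference", charge=1, stoich=(0, 0, 0, 1),
                        g_formation=0.0),
    }
    for sid in ids[1:]:
        species[sid] = Species(id=sid, role="open_intermediate", stoich=(1, 0, 0, 0),
                               g_formation=float(potentials[sid]))

    edges = {(ids[i], ids[i + 1]) for i in range(n_intermediates - 1)}  # spanning chain
    for i in range(n_intermediates):
        for j in range(i + 2, n_intermediates):
            if rng.random() < extra_edge_prob:
                edges.add((ids[i], ids[j]))

    steps: list[ElementaryStep] = []
    for a, b in sorted(edges):
        dg = float(potentials[b] - potentials[a])
        g_a = max(0.0, dg) + float(rng.uniform(5.0, 40.0))
        fwd = ElementaryStep(
            id=f"{a}->{b}", reactant=a, product=b, delta_g=dg, g_a=g_a, reversible=True
        )
        steps.append(fwd)
        steps.append(reverse_step(fwd))
    return ReactionNetwork(species=species, steps=steps, references=refs,
                           temperature=temperature)
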