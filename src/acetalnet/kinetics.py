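"""Microkinetic simulation of the reaction network via transition-state theory.

Forward rate constants come from the Eyring equation on each step's
activation free energy; backward rates follow from detailed balance.  H2O,
H3O+ and the aldehyde are treated as reservoirs in excess whose activities
are folded into the rate constants (pseudo-first-order reduction), which
keeps the ODE system linear in the sugar-derived mole fractions.

Because the network references an *isolated* hydronium ion, protonated
adducts are strongly overstabilised relative to a solution; the rate model
therefore accepts per-reservoir chemical-potential offsets (``mu_shifts``,
kJ/mol) that shift the effective free energy of any state consuming that
reservoir.  Offsets default to zero; the packaged example network recommends
-60 kJ/mol on H3O+ (see :mod:`acetalnet.examples`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constants import DEFAULT_TEMPERATURE, K_B, PLANCK_H, R_KJ
from .network import NetworkError, ReactionNetwork


def eyring_rate(g_a: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """TST rate constant k = (k_B T / h) exp(-G_a / RT), in 1/s.

    Transmission coefficient fixed at 1.  Very large barriers underflow
    towards 0 without error.
    """
    if g_a < 0:
        raise ValueError(f"activation free energy must be >= 0, got {g_a} kJ/mol")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    exponent = -g_a / (R_KJ * T)
    try:
        boltz = math.exp(exponent)
    except OverflowError:  # pragma: no cover - g_a >= 0 makes this unreachable
        boltz = float("inf")
    return K_B * T / PLANCK_H * boltz


@dataclass
class RateModel:
    """Pseudo-first-order rate matrix over the sugar-derived states.

    ``matrix`` is the mass-action generator K (1/s): dx/dt = K x, columns sum
    to zero so the total sugar-derived fraction is conserved.  ``g_eff`` are
    the reservoir-corrected formation free energies used for detailed balance.
    """

    species: list[str]
    matrix: np.ndarray
    g_eff: np.ndarray
    temperature: float
    rates: pd.DataFrame = field(repr=False, default=None)

    @property
    def index(self) -> dict[str, int]:
        return {sid: i for i, sid in enumerate(self.species)}

    def boltzmann_weights(self) -> pd.Series:
        """Equilibrium mole fractions implied by the effective free energies."""
        g = self.g_eff - self.g_eff.min()
        w = np.exp(-g / (R_KJ * self.temperature))
        return pd.Series(w / w.sum(), index=self.species, name="fraction")


def _step_mu(multiset, mu_shifts) -> float:
    return sum(count * mu_shifts.get(mol, 0.0) for mol, count in multiset.items())


def build_rate_model(
    net: ReactionNetwork,
    T: float | None = None,
    mu_shifts: dict[str, float] | None = None,
    k_equilibrated: float = 1e3,
    auto_equilibrate_reversible: bool = True,
    k_cap: float | None = None,
) -> RateModel:
    """Build the linear rate model from a network's free energies.

    Steps with a computed g_a get Eyring forward rates; steps lacking g_a are
    treated as fast equilibrated steps (k = ``k_equilibrated`` downhill, with
    the detailed-balance Boltzmann factor applied uphill) when they are marked
    reversible — the low-barrier anomerizations.  A step lacking g_a that is
    not marked reversible is an error (its kinetics are undefined).

    ``k_cap`` (1/s) uniformly rescales both directions of any reversible pair
    whose faster rate exceeds it.  A common factor per pair leaves every
    equilibrium constant — hence the stationary distribution and detailed
    balance — exactly intact while removing irrelevant fast-equilibrium
    stiffness; it only matters when the capped steps stay much faster than
    the rate-limiting ones.
    """
    T = net.temperature if T is None else T
    mu_shifts = dict(mu_shifts or {})
    rt = R_KJ * T

    sugar = [sp.id for sp in net.sugar_states()]
    if not sugar:
        raise NetworkError("network has no sugar-derived states to simulate")
    idx = {sid: i for i, sid in enumerate(sugar)}

    g_eff = np.empty(len(sugar))
    for sid in sugar:
        sp = net.species[sid]
        g = net.g_formation(sid)
        _, b, c, d = sp.stoich
        g -= b * mu_shifts.get("HCHO", 0.0)
        g -= c * mu_shifts.get("H2O", 0.0)
        g -= d * mu_shifts.get("H3O+", 0.0)
        g_eff[idx[sid]] = g

    missing = [
        s.id
        for s in net.steps
        if s.g_a is None and not (auto_equilibrate_reversible and s.reversible)
        and s.reactant in idx and s.product in idx
    ]
    if missing:
        raise NetworkError(
            "steps lack an activation free energy and are not flagged as "
            f"equilibrated: {missing}"
        )

    raw = []
    for step in net.steps:
        if step.reactant not in idx or step.product not in idx:
            continue
        i = idx[step.reactant]
        j = idx[step.product]
        dg_eff = g_eff[j] - g_eff[i]
        if step.g_a is not None:
            g_a_eff = step.g_a - _step_mu(step.consumes, mu_shifts)
            g_a_eff = max(g_a_eff, dg_eff, 0.0)
            k = eyring_rate(g_a_eff, T)
            equilibrated = False
        else:
            k = k_equilibrated * math.exp(-max(dg_eff, 0.0) / rt)
            equilibrated = True
        raw.append([step, i, j, k, equilibrated])

    if k_cap is not None:
        fastest: dict[frozenset, float] = {}
        for _, i, j, k, _eq in raw:
            key = frozenset((i, j))
            fastest[key] = max(fastest.get(key, 0.0), k)
        for entry in raw:
            kmax = fastest[frozenset((entry[1], entry[2]))]
            if kmax > k_cap:
                entry[3] *= k_cap / kmax

    n = len(sugar)
    K = np.zeros((n, n))
    rows = []
    for step, i, j, k, equilibrated in raw:
        K[j, i] += k
        rows.append({"step": step.id, "reactant": step.reactant, "product": step.product,
                     "k_per_s": k, "equilibrated": equilibrated})
    # exact column-sum-zero diagonal: mass conservation to working precision
    K[np.diag_indices(n)] = 0.0
    K[np.diag_indices(n)] = -K.sum(axis=0)
    return RateModel(
        species=sugar, matrix=K, g_eff=g_eff, temperature=T, rates=pd.DataFrame(rows)
    )


@dataclass
class KineticTrace:
    """Mole-fraction trajectories of the sugar-derived states."""

    times_min: np.ndarray
    fractions: pd.DataFrame  # index: time (min), columns: species

    def total(self) -> np.ndarray:
        return self.fractions.to_numpy().sum(axis=1)

    def final(self) -> pd.Series:
        return self.fractions.iloc[-1]

    def plot(self, species=None, ax=None, logx=False):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cols = list(species) if species is not None else list(self.fractions.columns)
        for col in cols:
            ax.plot(self.times_min, self.fractions[col], label=col)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("mole fraction")
        if logx:
            ax.set_xscale("log")
        ax.legend(fontsize=7, ncol=2)
        return ax


def _propagate_expm(K: np.ndarray, x0: np.ndarray, t_eval_s: np.ndarray) -> np.ndarray:
    """Exact propagator powering for the linear master equation.

    Computes P = expm(K t_base) on a base interval resolving the fastest
    rate, then reaches each requested time through binary powers of P.
    Products of the (entrywise non-negative, column-sum-one) propagator are
    free of cancellation, so the scheme is uniformly accurate across
    arbitrarily many decades of time — where implicit ODE steppers stall on
    the Newton-matrix conditioning.  Each requested time is reached through
    the binary expansion of t / t_base plus one short remainder exponential,
    so no time rounding is incurred.
    """
    from scipy.linalg import expm

    positive = t_eval_s[t_eval_s > 0]
    out = np.empty((t_eval_s.size, x0.size))
    if positive.size == 0:
        out[:] = x0
        return out
    k_fast = np.abs(np.diag(K)).max()
    t_base = min(positive.min(), 0.1 / k_fast if k_fast > 0 else positive.min())
    def _stochastic(M: np.ndarray) -> np.ndarray:
        # re-project onto the column-stochastic manifold: without this, a
        # column-sum excess of order eps compounds doubly exponentially
        # through repeated squaring
        np.clip(M, 0.0, None, out=M)
        M /= M.sum(axis=0, keepdims=True)
        return M

    P = _stochastic(expm(K * t_base))

    n_max = int(round(positive.max() / t_base))
    powers = [P]
    while 2 ** len(powers) <= n_max:
        powers.append(_stochastic(powers[-1] @ powers[-1]))

    for row, t in enumerate(t_eval_s):
        if t == 0.0:
            out[row] = x0
            continue
        n = int(t / t_base)
        x = x0
        remainder = t - n * t_base
        if remainder > 0:
            x = _stochastic(expm(K * remainder)) @ x
        bit = 0
        while n:
            if n & 1:
                x = powers[bit] @ x
            n >>= 1
            bit += 1
        out[row] = x
    return out


def simulate(
    model: RateModel,
    init: dict[str, float] | np.ndarray,
    t_end_min: float,
    n_points: int = 101,
    t_eval_min: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "BDF",
) -> KineticTrace:
    """Integrate the stiff linear mass-action system and sample it.

    ``init`` holds mole fractions over the model's sugar-derived states and
    must sum to 1 (the sugar moiety is the conserved quantity).  Sampling
    defaults to ``n_points`` uniformly spaced over [0, t_end_min]; pass
    ``t_eval_min`` (e.g. log-spaced) for wide-timescale runs.

    ``method="BDF"`` is scipy's stiff multistep integrator; ``method="expm"``
    propagates through binary powers of the exact matrix exponential, which
    stays accurate when the time horizon spans many more decades than the
    stiffest rate allows BDF to cover.
    """
    n = len(model.species)
    if isinstance(init, dict):
        unknown = set(init) - set(model.species)
        if unknown:
            raise NetworkError(f"init references unknown species: {sorted(unknown)}")
        x0 = np.zeros(n)
        for sid, frac in init.items():
            x0[model.index[sid]] = frac
    else:
        x0 = np.asarray(init, dtype=float)
        if x0.shape != (n,):
            raise ValueError(f"init must have length {n}")
    if np.any(x0 < 0):
        raise ValueError("initial fractions must be non-negative")
    if abs(x0.sum() - 1.0) > 1e-6:
        raise ValueError(f"initial fractions must sum to 1, got {x0.sum():.6g}")

    if t_eval_min is None:
        t_eval_min = np.linspace(0.0, t_end_min, n_points)
    else:
        t_eval_min = np.asarray(t_eval_min, dtype=float)
    t_eval_s = t_eval_min * 60.0

    K = model.matrix
    if method == "expm":
        y = _propagate_expm(K, x0, t_eval_s)
    elif method == "BDF":
        sol = solve_ivp(
            lambda t, y: K @ y,
            t_span=(0.0, float(t_eval_s[-1])),
            y0=x0,
            method="BDF",
            t_eval=t_eval_s,
            jac=lambda t, y: K,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"stiff integrator failed: {sol.message}")
        y = sol.y.T
    else:
        raise ValueError(f"unknown method {method!r} (use 'BDF' or 'expm')")
    frac = pd.DataFrame(y, index=pd.Index(t_eval_min, name="time_min"),
                        columns=model.species)
    return KineticTrace(times_min=t_eval_min, fractions=frac)


class MicrokineticModel:
    """Model object binding a reaction network to a TST rate model.

    Parameters
    ----------
    network : ReactionNetwork
    temperature : float, optional
        Defaults to the network's temperature (333.15 K for the packaged
        example).
    mu_shifts : dict, optional
        Chemical-potential offsets (kJ/mol) for the co-reagent reservoirs,
        e.g. ``{"H3O+": -60.0}``.
    """

    def __init__(self, network: ReactionNetwork, temperature: float | None = None,
                 mu_shifts: dict[str, float] | None = None, k_equilibrated: float = 1e3,
                 k_cap: float | None = None):
        self.network = network
        self.temperature = network.temperature if temperature is None else temperature
        self.mu_shifts = dict(mu_shifts or {})
        self.rate_model = build_rate_model(
            network, self.temperature, self.mu_shifts,
            k_equilibrated=k_equilibrated, k_cap=k_cap,
        )

    def simulate(self, init, t_end_min: float, n_points: int = 101,
                 t_eval_min=None, rtol: float = 1e-8, atol: float = 1e-12,
                 method: str = "BDF") -> KineticTrace:
        return simulate(self.rate_model, init, t_end_min, n_points=n_points,
                        t_eval_min=t_eval_min, rtol=rtol, atol=atol, method=method)

    def equilibrium(self) -> pd.Series:
        return self.rate_model.boltzmann_weights()


def pyranose_selectivity(pyranose_total: float, furanose_total: float) -> float | None:
    """Equilibrium pyranose-monoacetal selectivity, in mol percent.

    selectivity = 100 * pyr / (pyr + fur); returns None (undefined) when both
    totals are zero.
    """
    if pyranose_total < 0 or furanose_total < 0:
        raise ValueError("monoacetal totals must be non-negative")
    total = pyranose_total + furanose_total
    if total == 0:
        return None
    return 100.0 * pyranose_total / total


def is_unimodal(values, tol: float = 1e-9) -> bool:
    """True when a trace rises to a single maximum and then decays,
    allowing wiggles up to ``tol``."""
    v = np.asarray(values, dtype=float)
    peak = int(np.argmax(v))
    before = np.all(np.diff(v[: peak + 1]) >= -tol)
    after = np.all(np.diff(v[peak:]) <= tol)
    return bool(before and after)
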