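"""Screened-Coulomb deprotonation potentials and constant-pH titration.

The configuration-dependent cost of removing the titratable proton from a
tagged site is scored with a uniform-dielectric, Debye-screened Coulomb sum

    ddG = sum_ij 332.06 * dq_i * q_j * exp(-kappa r_ij) / (eps * r_ij)

over site atoms i (``dq`` = charge difference deprotonated - protonated)
and environment atoms j, in kcal/mol.  The isolated model compound
contributes nothing by construction (no environment), so ``ddG`` is already
the environment-induced shift, and the effective pKa follows as

    pKa = pKa_ref + ddG / (ln 10 * kT).

Only deprotonation is scored (no proton placement), so the value is a
"deprotonation potential" — a proxy for the true equilibrium pKa that is
high exactly when the protonated site coordinates a nearby anion.

A Metropolis two-state constant-pH titration plus Henderson–Hasselbalch
fitting provides an independent, sampling-based route to the same quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants, optimize

from .toy_system import Structure

__all__ = [
    "ElectrostaticParams",
    "TitrationCurve",
    "COULOMB_KCAL",
    "debye_kappa",
    "deprotonation_potential",
    "effective_pka",
    "titration_curve",
    "fit_hh",
]

#: Coulomb constant in kcal/mol * Angstrom / e^2
COULOMB_KCAL = 332.06


@dataclass(frozen=True)
class ElectrostaticParams:
    """Uniform-dielectric screened-Coulomb scorer parameters.

    ``dielectric`` is the single relative permittivity applied to all pairs
    (default 10, a conventional effective value for a buried protein site);
    ``ionic_strength`` sets the Debye screening length (0.15 M is
    physiological); ``pka_ref`` is the model-compound pKa of the titratable
    site (4.25 for glutamate).
    """

    dielectric: float = 10.0
    ionic_strength: float = 0.15  # mol/L
    temperature: float = 298.0  # K
    pka_ref: float = 4.25

    def __post_init__(self) -> None:
        if self.dielectric < 1:
            raise ValueError("relative dielectric must be >= 1")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")

    @property
    def kt_kcal(self) -> float:
        return constants.R / constants.calorie / 1000.0 * self.temperature

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength, self.dielectric, self.temperature)


def debye_kappa(ionic_strength: float, dielectric: float, temperature: float = 298.0) -> float:
    """Inverse Debye length in 1/Angstrom for a uniform dielectric.

    ``kappa^2 = 2 N_A e^2 I / (eps eps0 kB T)`` with I in mol/m^3.
    """
    if ionic_strength == 0:
        return 0.0
    i_si = ionic_strength * 1000.0  # mol/m^3
    k2 = (2.0 * constants.N_A * constants.e ** 2 * i_si
          / (dielectric * constants.epsilon_0 * constants.k * temperature))
    return math.sqrt(k2) * 1e-10  # 1/m -> 1/A


def _site_deltas(structure: Structure, site: str) -> tuple[np.ndarray, np.ndarray]:
    """Positions and charge differences (deprotonated - protonated) of the
    site atoms, plus implicit removal of the titratable proton's charge."""
    try:
        states = structure.site_charge_states[site]
    except KeyError:
        raise ValueError(f"structure has no titratable site {site!r}") from None
    prot, deprot = states["protonated"], states["deprotonated"]
    ids = sorted(set(prot) | set(deprot))
    present = set(structure.ids.tolist())
    pos, dq = [], []
    for aid in ids:
        delta = deprot.get(aid, 0.0) - prot.get(aid, 0.0)
        if aid not in present:
            if abs(delta) > 1e-12:
                raise ValueError(
                    f"site {site!r} charge state references missing atom {aid}")
            continue
        pos.append(structure.xyz[structure.index_of(aid)])
        dq.append(delta)
    return np.asarray(pos), np.asarray(dq)


def deprotonation_potential(structure: Structure, site: str,
                            params: ElectrostaticParams | None = None) -> float:
    """Electrostatic deprotonation cost ddG in kcal/mol (see module docstring).

    Positive values mean the environment penalizes deprotonation (e.g. a
    coordinated anion next to the protonated site); with no environment
    charges the result is exactly 0 (the model-compound limit).
    """
    params = params or ElectrostaticParams()
    site_pos, dq = _site_deltas(structure, site)
    if site_pos.size == 0:
        return 0.0
    site_ids = set(structure.site_charge_states[site]["protonated"]) \
        | set(structure.site_charge_states[site]["deprotonated"])
    env_mask = np.array([aid not in site_ids for aid in structure.ids.tolist()])
    env_pos = structure.xyz[env_mask]
    env_q = structure.charges[env_mask]
    if env_pos.size == 0:
        return 0.0
    r = np.linalg.norm(site_pos[:, None, :] - env_pos[None, :, :], axis=-1)
    if np.any(r < 0.5):
        raise ValueError("site/environment atom overlap (r < 0.5 A)")
    kappa = params.kappa
    e = COULOMB_KCAL * dq[:, None] * env_q[None, :] * np.exp(-kappa * r) / (params.dielectric * r)
    return float(e.sum())


def effective_pka(structure: Structure, site: str,
                  params: ElectrostaticParams | None = None) -> float:
    """Effective (conditional) pKa: ``pKa_ref + ddG / (ln 10 * kT)``."""
    params = params or ElectrostaticParams()
    ddg = deprotonation_potential(structure, site, params)
    return params.pka_ref + ddg / (math.log(10.0) * params.kt_kcal)


@dataclass(frozen=True)
class TitrationCurve:
    ph_values: np.ndarray
    deprotonated_fraction: np.ndarray
    fitted_pka: float
    hill_coefficient: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "ph_values", np.asarray(self.ph_values, dtype=float))
        object.__setattr__(self, "deprotonated_fraction",
                           np.asarray(self.deprotonated_fraction, dtype=float))
        if np.any(np.diff(self.ph_values) <= 0):
            raise ValueError("pH values must be strictly increasing")
        f = self.deprotonated_fraction
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")


def titration_curve(delta_g_fn, ph_values, n_steps: int = 100_000,
                    seed: int = 0) -> TitrationCurve:
    """Metropolis constant-pH titration of a two-state titratable site.

    ``delta_g_fn(pH)`` returns the deprotonation free energy in kT at that
    pH; for a simple site ``ln10 * (pKa - pH)`` (any structure-dependent
    term may be added by the caller).  Per pH window a single-site
    Metropolis chain samples the protonation indicator; the default of
    eight pH windows mirrors standard constant-pH practice.  The mean
    deprotonated fractions are then fit with :func:`fit_hh`.
    """
    ph_values = np.sort(np.asarray(ph_values, dtype=float))
    if ph_values.size < 4:
        raise ValueError("need at least 4 pH windows to fit a titration curve")
    if n_steps < 100:
        raise ValueError("n_steps must be >= 100")
    rng = np.random.default_rng(seed)
    fractions = np.empty(ph_values.size)
    for i, ph in enumerate(ph_values):
        dg = float(delta_g_fn(ph))  # kT, deprotonated minus protonated
        u = rng.random(n_steps)
        state = 0  # 0 = protonated, 1 = deprotonated
        acc_prob_up = math.exp(-dg) if dg > 0 else 1.0
        acc_prob_down = math.exp(dg) if dg < 0 else 1.0
        count = 0
        for s in range(n_steps):
            if state == 0:
                if u[s] < acc_prob_up:
                    state = 1
            else:
                if u[s] < acc_prob_down:
                    state = 0
            count += state
        fractions[i] = count / n_steps
    pka, hill = fit_hh(ph_values, fractions)
    return TitrationCurve(ph_values=ph_values, deprotonated_fraction=fractions,
                          fitted_pka=pka, hill_coefficient=hill)


def fit_hh(ph_values, fractions) -> tuple[float, float]:
    """Least-squares Henderson–Hasselbalch fit
    ``f = 1 / (1 + 10^(n (pKa - pH)))``; returns (pKa, n).

    Degenerate data (all fractions 0 or all 1) carry no pKa information and
    raise ValueError.
    """
    ph = np.asarray(ph_values, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if np.all(f < 1e-12) or np.all(f > 1 - 1e-12):
        raise ValueError("degenerate titration data: site never changes state")

    def hh(x, pka, n):
        return 1.0 / (1.0 + 10.0 ** (n * (pka - x)))

    p0 = (float(np.interp(0.5, f, ph)) if np.all(np.diff(f) >= 0) else float(ph.mean()), 1.0)
    popt, _ = optimize.curve_fit(hh, ph, f, p0=p0, maxfev=10_000)
    return float(popt[0]), float(popt[1])
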