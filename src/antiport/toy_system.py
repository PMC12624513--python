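"""Synthetic model systems: analytic landscapes, Langevin walkers, toy snapshots.

Everything downstream (metadynamics, FES analysis, reweighting, pKa maps,
wire search) is exercised against objects built here, so every generator is
deterministic given a seed and every planted feature (well depth, barrier,
wire geometry) is recoverable in closed form.

Conventions
-----------
* Collective variables (CVs) are measured in nanometers.  For the
  two-dimensional landscapes the two CVs are the z-displacements of two
  chloride ions from the center of the transporter's central cavity;
  positive values point to the extracellular side, negative values to the
  intracellular side.
* Energies are in units of kT unless stated otherwise.
* Toy atomic coordinates are in Angstrom; the CV (nm) is mapped onto
  chloride z-coordinates through ``GeometryParams.angstrom_per_nm``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "GaussianTerm",
    "PotentialSurface",
    "WalkerFrame",
    "GeometryParams",
    "Structure",
    "make_landscape",
    "potential_energy",
    "langevin_step",
    "simulate_langevin",
    "boltzmann_density",
    "build_snapshot",
    "plant_wire",
    "random_water_box",
    "PRESETS",
]


class GaussianTerm(NamedTuple):
    """One Gaussian contribution ``A * exp(-sum_d (x_d-c_d)^2 / (2 w_d^2))``."""

    amplitude: float  # kT; negative = well, positive = ridge
    center: tuple  # nm
    widths: tuple  # nm, strictly positive


@dataclass(frozen=True)
class PotentialSurface:
    """Analytic free-energy landscape over 1 or 2 CVs.

    Parameters
    ----------
    dimension : int
        Number of collective variables (1 or 2).
    terms : list of GaussianTerm
        Gaussian wells/ridges summed to give the potential.
    bounds : ndarray, shape (dimension, 2)
        Per-CV (lo, hi) box, nm.  Dynamics reflects at these walls.
    symmetric : bool
        If True the surface is exchange-symmetric in its two CVs:
        every term either lies on the diagonal (self-mirrored) or has a
        mirror term with swapped center/width components.
    """

    dimension: int
    terms: tuple
    bounds: np.ndarray
    symmetric: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "bounds", np.asarray(self.bounds, dtype=float).reshape(self.dimension, 2))
        object.__setattr__(self, "terms", tuple(
            GaussianTerm(float(a), tuple(np.atleast_1d(c).astype(float)), tuple(np.atleast_1d(w).astype(float)))
            for a, c, w in self.terms
        ))
        if self.dimension not in (1, 2):
            raise ValueError(f"dimension must be 1 or 2, got {self.dimension}")
        for t in self.terms:
            if len(t.center) != self.dimension or len(t.widths) != self.dimension:
                raise ValueError("term center/widths do not match surface dimension")
            if any(w <= 0 for w in t.widths):
                raise ValueError(f"nonpositive Gaussian width in term {t}")
        if np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("bounds must satisfy lo < hi on every CV")
        if self.symmetric:
            if self.dimension != 2:
                raise ValueError("exchange symmetry only applies to 2D surfaces")
            self._check_mirror_terms()

    def _check_mirror_terms(self) -> None:
        def key(t: GaussianTerm):
            return (round(t.amplitude, 9), tuple(round(x, 9) for x in t.center),
                    tuple(round(x, 9) for x in t.widths))

        have = {key(t) for t in self.terms}
        for t in self.terms:
            mirror = GaussianTerm(t.amplitude, t.center[::-1], t.widths[::-1])
            if key(mirror) not in have:
                raise ValueError(f"symmetric surface lacks mirror of term {t}")

    # -- evaluation ---------------------------------------------------
    def energy(self, points: np.ndarray) -> np.ndarray:
        """Potential V(x) in kT at ``points`` (shape (..., dimension))."""
        pts = np.asarray(points, dtype=float)
        scalar_in = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = np.zeros(pts.shape[:-1])
        for amp, center, widths in self.terms:
            d2 = ((pts - np.asarray(center)) ** 2 / (2.0 * np.asarray(widths) ** 2)).sum(axis=-1)
            out += amp * np.exp(-d2)
        return float(out[0]) if scalar_in else out

    def gradient(self, point: np.ndarray) -> np.ndarray:
        """Analytic gradient dV/dx at a single point, kT/nm."""
        x = np.asarray(point, dtype=float)
        g = np.zeros_like(x)
        for amp, center, widths in self.terms:
            c = np.asarray(center)
            w2 = np.asarray(widths) ** 2
            diff = x - c
            e = amp * math.exp(-float((diff ** 2 / (2.0 * w2)).sum()))
            g += e * (-diff / w2)
        return g

    def gradient_multi(self, points: np.ndarray) -> np.ndarray:
        """Gradients at several points at once (shape (n, dimension))."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = np.zeros_like(pts)
        for amp, center, widths in self.terms:
            c = np.asarray(center)
            w2 = np.asarray(widths) ** 2
            diff = pts - c
            e = amp * np.exp(-((diff ** 2) / (2.0 * w2)).sum(axis=1))
            g += e[:, None] * (-diff / w2)
        return g

    def in_bounds(self, point: np.ndarray) -> bool:
        x = np.atleast_1d(np.asarray(point, dtype=float))
        return bool(np.all(x >= self.bounds[:, 0]) and np.all(x <= self.bounds[:, 1]))

    def grid_axes(self, n: int = 100) -> list[np.ndarray]:
        return [np.linspace(lo, hi, n) for lo, hi in self.bounds]


@dataclass(frozen=True)
class WalkerFrame:
    """One recorded frame of a (possibly biased) walker trajectory."""

    time: float  # ps
    walker_id: int
    chain_label: str  # "A" or "B"
    cv: np.ndarray  # nm
    bias_at_frame: float  # kT, instantaneous bias at deposition time
    snapshot_ref: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cv", np.atleast_1d(np.asarray(self.cv, dtype=float)))
        if self.bias_at_frame < 0:
            raise ValueError("bias_at_frame must be >= 0")


# ----------------------------------------------------------------------
# Landscape presets
# ----------------------------------------------------------------------

def _flat(dimension: int = 1) -> PotentialSurface:
    return PotentialSurface(dimension=dimension, terms=(),
                            bounds=[(-2.0, 2.0)] * dimension, symmetric=dimension == 2)


def _double_well_1d(well_pos: float = 1.0, depth: float = 6.0, width: float = 0.3) -> PotentialSurface:
    terms = (
        GaussianTerm(-depth, (+well_pos,), (width,)),
        GaussianTerm(-depth, (-well_pos,), (width,)),
    )
    return PotentialSurface(dimension=1, terms=terms, bounds=[(-2.5, 2.5)])


def _wp_like() -> PotentialSurface:
    """Trap-chain landscape: one ion parked extracellular, the other stepping
    through three binding sites (S_ext -> intermediate -> S_cen), with a high
    ridge blocking the diagonal two-ion exit.  Exchange-symmetric."""
    chain = [
        (-12.0, (1.2, 0.55)),   # M1: first site, shallowest
        (-13.0, (1.2, 0.0)),    # M2
        (-14.0, (1.2, -0.55)),  # M3: central-cavity trap, deepest
    ]
    terms = []
    for amp, (a, b) in chain:
        terms.append(GaussianTerm(amp, (a, b), (0.20, 0.20)))
        terms.append(GaussianTerm(amp, (b, a), (0.20, 0.20)))
    # ridge on the concerted-exit diagonal (self-mirrored)
    terms.append(GaussianTerm(8.0, (-1.0, -1.0), (0.6, 0.6)))
    return PotentialSurface(dimension=2, terms=tuple(terms), bounds=[(-2, 2), (-2, 2)], symmetric=True)


def _wd_like() -> PotentialSurface:
    """Downhill diagonal channel: after the protonation switch the concerted
    movement of both ions toward the intracellular side is monotonically
    favorable along the diagonal from (1,1) to (-1.5,-1.5).  Realized as a
    dense ramp of increasingly deep Gaussians on the diagonal (self-mirrored,
    hence exchange-symmetric); the ramp continues past the channel end so no
    spurious uphill stretch appears inside it."""
    centers = np.arange(1.0, -2.3, -0.25)
    depths = -0.6 - 0.6 * np.arange(centers.size)
    terms = tuple(GaussianTerm(float(d), (float(c), float(c)), (0.5, 0.5))
                  for d, c in zip(depths, centers))
    return PotentialSurface(dimension=2, terms=terms, bounds=[(-2, 2), (-2, 2)], symmetric=True)


PRESETS: dict[str, Callable[[], PotentialSurface]] = {
    "flat": _flat,
    "double_well_1d": _double_well_1d,
    "wp_like": _wp_like,
    "wd_like": _wd_like,
}


def make_landscape(spec: str | dict | PotentialSurface, **kwargs) -> PotentialSurface:
    """Build a validated landscape from a preset name or explicit parameters.

    ``spec`` may be a preset name (``flat``, ``double_well_1d``, ``wp_like``,
    ``wd_like``), a dict of :class:`PotentialSurface` fields, or an already
    constructed surface (returned unchanged after validation).
    """
    if isinstance(spec, PotentialSurface):
        return spec
    if isinstance(spec, str):
        try:
            factory = PRESETS[spec]
        except KeyError:
            raise ValueError(f"unknown landscape preset {spec!r}; known: {sorted(PRESETS)}") from None
        return factory(**kwargs)
    if isinstance(spec, dict):
        return PotentialSurface(**spec)
    raise TypeError(f"cannot build a landscape from {type(spec).__name__}")


def potential_energy(surface: PotentialSurface, point) -> float:
    """V(point) in kT; raises for out-of-bounds points."""
    if not surface.in_bounds(point):
        raise ValueError(f"point {point} outside surface bounds {surface.bounds.tolist()}")
    return surface.energy(np.atleast_1d(np.asarray(point, dtype=float)))


# ----------------------------------------------------------------------
# Overdamped Langevin dynamics
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LangevinParams:
    diffusion: float = 0.01  # nm^2/ps
    dt: float = 1.0  # ps
    kt: float = 1.0  # thermal energy; potentials are in these units


def _reflect(x: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (handles multiple bounces)."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def langevin_step(position: np.ndarray,
                  force_field: Callable[[np.ndarray], np.ndarray],
                  params: LangevinParams,
                  rng: np.random.Generator,
                  bounds: np.ndarray | None = None) -> np.ndarray:
    """One Euler-Maruyama step of overdamped Langevin dynamics.

    ``x' = x - (D/kT) * grad(V) * dt + sqrt(2 D dt) * eta``, with ``eta``
    standard normal and reflection at ``bounds`` if given.  ``force_field``
    returns the *gradient* of the total potential (analytic surface plus any
    bias) at a point.
    """
    x = np.atleast_1d(np.asarray(position, dtype=float))
    grad = np.atleast_1d(np.asarray(force_field(x), dtype=float))
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError(f"non-finite gradient {grad} at {x}")
    noise = rng.standard_normal(x.shape)
    new = x - params.diffusion / params.kt * grad * params.dt \
        + math.sqrt(2.0 * params.diffusion * params.dt) * noise
    if bounds is not None:
        new = _reflect(new, np.asarray(bounds, dtype=float))
    return new


def simulate_langevin(surface: PotentialSurface, n_steps: int, params: LangevinParams,
                      seed: int, x0: np.ndarray | None = None,
                      extra_gradient: Callable[[np.ndarray], np.ndarray] | None = None,
                      record_stride: int = 1) -> np.ndarray:
    """Unbiased (or externally biased) trajectory on an analytic surface.

    Returns recorded positions, shape (n_recorded, dimension).
    """
    rng = np.random.default_rng(seed)
    if x0 is None:
        x = rng.uniform(surface.bounds[:, 0], surface.bounds[:, 1])
    else:
        x = np.atleast_1d(np.asarray(x0, dtype=float))

    if extra_gradient is None:
        grad = surface.gradient
    else:
        def grad(p, _g=extra_gradient):
            return surface.gradient(p) + _g(p)

    out = []
    for step in range(n_steps):
        x = langevin_step(x, grad, params, rng, bounds=surface.bounds)
        if step % record_stride == 0:
            out.append(x)
    return np.asarray(out)


def boltzmann_density(surface: PotentialSurface, axes: Sequence[np.ndarray],
                      kt: float = 1.0) -> np.ndarray:
    """Normalized Boltzmann probability of the surface on a grid (test oracle)."""
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack(mesh, axis=-1)
    v = surface.energy(pts)
    p = np.exp(-(v - v.min()) / kt)
    return p / p.sum()


# ----------------------------------------------------------------------
# Toy structures
# ----------------------------------------------------------------------

#: charge sets for a toy glutamate carboxylate, by protonation state.
#: Keys are atom roles within the site; HE2 is the titratable proton.
GLU_CHARGES = {
    "protonated": {"CD": 0.30, "OE1": -0.55, "OE2": -0.55, "HE2": 0.80},   # net 0
    "deprotonated": {"CD": 0.10, "OE1": -0.55, "OE2": -0.55, "HE2": 0.0},  # net -1
}

_RADII = {"C": 1.70, "O": 1.52, "H": 1.20, "CL": 1.81}
_WATER_Q = {"O": -0.834, "H": 0.417}


@dataclass(frozen=True)
class GeometryParams:
    """Geometry of the toy pore used by :func:`build_snapshot`.

    The pore axis is z; the cavity center is the origin.  The two gating
    carboxylates sit on the axis at ``+-glu_o_separation/2`` (their
    hydrogen-bonding oxygens), chlorides ride at a lateral offset so they
    never clash with a planted water wire.
    """

    angstrom_per_nm: float = 10.0  # CV(nm) -> chloride z(A) placement scale
    glu_o_separation: float = 11.0  # A between the two wire-endpoint oxygens
    chloride_lateral_offset: float = 3.0  # A, x-offset of the chloride track
    glu_ext_protonated: bool = True
    glu_int_protonated: bool = False


@dataclass
class Structure:
    """Toy atomic snapshot with charges, radii and titratable-site tags.

    ``site_tags`` maps roles (``glu_ext_carboxylate``, ``glu_int_carboxylate``,
    ``titratable_proton``, ``chloride_1``, ``chloride_2``, ``water_O``,
    ``water_H``) to atom ids.  ``site_charge_states`` stores, per titratable
    site, the atom charges in both protonation states so the electrostatics
    module can form charge differences without re-deriving chemistry.
    """

    ids: np.ndarray
    elements: list[str]
    names: list[str]
    resnames: list[str]
    resids: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    xyz: np.ndarray
    site_tags: dict[str, list[int]] = field(default_factory=dict)
    protonated: dict[str, bool] = field(default_factory=dict)
    site_charge_states: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.resids = np.asarray(self.resids, dtype=int)
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(len(self.ids), 3)

    # -- helpers ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.ids)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def index_of(self, atom_id: int) -> int:
        idx = np.nonzero(self.ids == atom_id)[0]
        if idx.size != 1:
            raise KeyError(f"atom id {atom_id} not present exactly once")
        return int(idx[0])

    def positions_of(self, atom_ids: Sequence[int]) -> np.ndarray:
        return self.xyz[[self.index_of(i) for i in atom_ids]]

    def copy(self) -> "Structure":
        return Structure(
            ids=self.ids.copy(), elements=list(self.elements), names=list(self.names),
            resnames=list(self.resnames), resids=self.resids.copy(),
            charges=self.charges.copy(), radii=self.radii.copy(), xyz=self.xyz.copy(),
            site_tags={k: list(v) for k, v in self.site_tags.items()},
            protonated=dict(self.protonated),
            site_charge_states={s: {st: dict(q) for st, q in states.items()}
                                for s, states in self.site_charge_states.items()},
        )

    def validate(self, min_separation: float = 1.0) -> None:
        """Check structural invariants; raises ValueError on violation."""
        id_set = set(self.ids.tolist())
        for role, ids in self.site_tags.items():
            missing = [i for i in ids if i not in id_set]
            if missing:
                raise ValueError(f"site tag {role!r} references missing atoms {missing}")
        # each water O has exactly two water H within 1.2 A
        w_o = self.site_tags.get("water_O", [])
        w_h = self.site_tags.get("water_H", [])
        if w_o:
            hpos = self.positions_of(w_h) if w_h else np.empty((0, 3))
            for oid in w_o:
                d = np.linalg.norm(hpos - self.xyz[self.index_of(oid)], axis=1)
                if int((d <= 1.2).sum()) != 2:
                    raise ValueError(f"water O {oid} does not have exactly two bonded H within 1.2 A")
        # steric sanity: no inter-residue pair closer than min_separation
        # (covalently bonded atoms always share a residue in these toys)
        diff = self.xyz[:, None, :] - self.xyz[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        same_res = (self.resids[:, None] == self.resids[None, :]) \
            & (np.array(self.resnames)[:, None] == np.array(self.resnames)[None, :])
        iu = np.triu_indices(self.n_atoms, k=1)
        for a, b in zip(*iu):
            if dist[a, b] < min_separation and not same_res[a, b]:
                raise ValueError(
                    f"atoms {self.ids[a]} and {self.ids[b]} overlap ({dist[a, b]:.2f} A)")

    def cv_readback(self, geometry: GeometryParams) -> np.ndarray:
        """Chloride z-displacements (nm) implied by the coordinates."""
        z1 = self.xyz[self.index_of(self.site_tags["chloride_1"][0])][2]
        z2 = self.xyz[self.index_of(self.site_tags["chloride_2"][0])][2]
        return np.array([z1, z2]) / geometry.angstrom_per_nm


class _Builder:
    def __init__(self):
        self.rows = []
        self.tags: dict[str, list[int]] = {}
        self._next = 1

    def add(self, element, name, resname, resid, charge, xyz, roles=()):
        aid = self._next
        self._next += 1
        self.rows.append((aid, element, name, resname, resid, charge,
                          _RADII[element.upper()], tuple(float(v) for v in xyz)))
        for r in roles:
            self.tags.setdefault(r, []).append(aid)
        return aid

    def build(self, protonated, site_charge_states) -> Structure:
        ids, el, nm, rn, ri, q, rad, xyz = zip(*self.rows)
        return Structure(ids=np.array(ids), elements=list(el), names=list(nm),
                         resnames=list(rn), resids=np.array(ri), charges=np.array(q),
                         radii=np.array(rad), xyz=np.array(xyz),
                         site_tags=self.tags, protonated=protonated,
                         site_charge_states=site_charge_states)


def _add_glutamate(b: _Builder, which: str, o1_xyz: np.ndarray, inward: np.ndarray,
                   protonated: bool, resid: int) -> dict[str, int]:
    """Toy carboxylate: hydrogen-bonding O on the pore axis, the rest tucked
    laterally.  ``inward`` is the unit vector toward the pore center (where a
    titratable proton points when present)."""
    state = "protonated" if protonated else "deprotonated"
    q = GLU_CHARGES[state]
    role = f"glu_{which}_carboxylate"
    # lateral atoms sit along y, orthogonal to the +-x chloride tracks
    lateral = np.array([0.0, 1.0, 0.0])
    o1 = b.add("O", "OE1", "GLU", resid, q["OE1"], o1_xyz, roles=[role])
    cd = b.add("C", "CD", "GLU", resid, q["CD"], o1_xyz + lateral * 1.3 - inward * 0.5)
    o2 = b.add("O", "OE2", "GLU", resid, q["OE2"], o1_xyz + lateral * 2.2 - inward * 0.3, roles=[role])
    atom_ids = {"CD": cd, "OE1": o1, "OE2": o2}
    if protonated:
        he2 = b.add("H", "HE2", "GLU", resid, q["HE2"], o1_xyz + inward * 0.97,
                    roles=["titratable_proton"])
        atom_ids["HE2"] = he2
    return atom_ids


def build_snapshot(cv_point, geometry: GeometryParams | None = None,
                   n_bulk_waters: int = 0, seed: int = 0) -> Structure:
    """Toy snapshot realizing a CV macrostate.

    The two chlorides are placed at ``z = cv * angstrom_per_nm`` on a track
    laterally offset from the pore axis; the two gating carboxylates occupy
    fixed positions at either end of the axis.  Deterministic given
    ``geometry`` and ``seed``.
    """
    geometry = geometry or GeometryParams()
    cv = np.atleast_1d(np.asarray(cv_point, dtype=float))
    if cv.size == 1:
        cv = np.array([cv[0], cv[0]])
    b = _Builder()
    half = geometry.glu_o_separation / 2.0
    ext_ids = _add_glutamate(b, "ext", np.array([0.0, 0.0, +half]), np.array([0, 0, -1.0]),
                             geometry.glu_ext_protonated, resid=2)
    int_ids = _add_glutamate(b, "int", np.array([0.0, 0.0, -half]), np.array([0, 0, +1.0]),
                             geometry.glu_int_protonated, resid=1)

    xoff = geometry.chloride_lateral_offset
    b.add("CL", "CLA", "CLA", 3, -1.0, (xoff, 0.0, cv[0] * geometry.angstrom_per_nm),
          roles=["chloride_1"])
    b.add("CL", "CLA", "CLA", 4, -1.0, (-xoff, 0.0, cv[1] * geometry.angstrom_per_nm),
          roles=["chloride_2"])

    rng = np.random.default_rng(seed)
    resid = 10
    occupied = [np.asarray(r[7]) for r in b.rows]  # avoid every placed atom
    n_placed = 0
    attempts = 0
    while n_placed < n_bulk_waters:
        attempts += 1
        if attempts > 200 * max(1, n_bulk_waters):
            raise ValueError("could not place bulk waters without clashes")
        pos = rng.uniform([-8, -8, -half - 4], [8, 8, half + 4])
        if min((np.linalg.norm(pos - p) for p in occupied), default=99) < 3.0:
            continue
        if abs(pos[0]) < 2.0 and abs(pos[1]) < 2.0:  # keep the pore axis open
            continue
        occupied.append(pos)
        _add_water(b, pos, _random_unit(rng), resid)
        n_placed += 1
        resid += 1

    protonated = {"glu_ext_carboxylate": geometry.glu_ext_protonated,
                  "glu_int_carboxylate": geometry.glu_int_protonated}
    states = {
        "glu_ext_carboxylate": _charge_states(ext_ids),
        "glu_int_carboxylate": _charge_states(int_ids),
    }
    s = b.build(protonated, states)
    s.validate()
    return s


def _charge_states(atom_ids: dict[str, int]) -> dict[str, dict[int, float]]:
    out: dict[str, dict[int, float]] = {}
    for state, qs in GLU_CHARGES.items():
        out[state] = {atom_ids[n]: q for n, q in qs.items() if n in atom_ids}
    return out


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _perp(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(u, ref)
    return p / np.linalg.norm(p)


def _add_water(b: _Builder, o_pos: np.ndarray, h1_dir: np.ndarray, resid: int,
               h2_dir: np.ndarray | None = None) -> int:
    """Water with O-H 0.96 A and an H-O-H angle of 104.5 degrees."""
    if h2_dir is None:
        perp = _perp(h1_dir)
        ang = math.radians(104.5)
        h2_dir = math.cos(ang) * h1_dir + math.sin(ang) * perp
    oid = b.add("O", "OW", "HOH", resid, _WATER_Q["O"], o_pos, roles=["water_O"])
    b.add("H", "HW1", "HOH", resid, _WATER_Q["H"], o_pos + 0.96 * h1_dir, roles=["water_H"])
    b.add("H", "HW2", "HOH", resid, _WATER_Q["H"], o_pos + 0.96 * h2_dir, roles=["water_H"])
    return oid


def plant_wire(structure: Structure, n_waters: int, max_hop: float = 3.5,
               min_hop: float = 2.3) -> Structure:
    """Insert a hydrogen-bonded donor-acceptor water chain between the two
    gating carboxylates.

    The chain runs from the intracellular carboxylate (proton donor side) to
    the extracellular one; each inserted water donates one O-H along the
    chain toward the acceptor, so every hop satisfies standard H-bond
    geometry by construction.  Raises ValueError if the carboxylate
    separation cannot be spanned by ``n_waters`` waters with hop lengths in
    ``[min_hop, max_hop]`` Angstrom.
    """
    if n_waters < 1:
        raise ValueError("n_waters must be >= 1")
    for role in ("glu_int_carboxylate", "glu_ext_carboxylate"):
        if not structure.site_tags.get(role):
            raise ValueError(f"structure lacks tagged site {role!r}")

    start = structure.xyz[structure.index_of(structure.site_tags["glu_int_carboxylate"][0])]
    end = structure.xyz[structure.index_of(structure.site_tags["glu_ext_carboxylate"][0])]
    span = np.linalg.norm(end - start)
    hop = span / (n_waters + 1)
    if not (min_hop <= hop <= max_hop):
        raise ValueError(
            f"cannot span {span:.2f} A with {n_waters} waters: hop length "
            f"{hop:.2f} A outside [{min_hop}, {max_hop}] A")
    axis = (end - start) / span

    out = structure.copy()
    b = _Builder()
    b._next = int(out.ids.max()) + 1
    resid = int(out.resids.max()) + 1
    nodes = [start + axis * hop * (i + 1) for i in range(n_waters)]
    for i, pos in enumerate(nodes):
        nxt = nodes[i + 1] if i + 1 < n_waters else end
        h1_dir = (nxt - pos) / np.linalg.norm(nxt - pos)
        _add_water(b, pos, h1_dir, resid + i)
    ids, el, nm, rn, ri, q, rad, xyz = zip(*b.rows)
    out.ids = np.concatenate([out.ids, ids])
    out.elements += list(el)
    out.names += list(nm)
    out.resnames += list(rn)
    out.resids = np.concatenate([out.resids, ri])
    out.charges = np.concatenate([out.charges, q])
    out.radii = np.concatenate([out.radii, rad])
    out.xyz = np.vstack([out.xyz, np.array(xyz)])
    for role, aids in b.tags.items():
        out.site_tags.setdefault(role, []).extend(aids)
    # The wire realizes the Grotthuss regeneration state: the extracellular
    # carboxylate accepts (deprotonated), the intracellular one donates
    # (protonated, proton aimed at the first water).
    ext = "glu_ext_carboxylate"
    if out.protonated.get(ext):
        prot_ids = out.site_charge_states[ext]["protonated"]
        he2_ext = [a for a in prot_ids if a in set(out.site_tags.get("titratable_proton", []))]
        if he2_ext:
            keep = out.ids != he2_ext[0]
            out.ids = out.ids[keep]
            out.elements = [e for e, k in zip(out.elements, keep) if k]
            out.names = [n for n, k in zip(out.names, keep) if k]
            out.resnames = [r for r, k in zip(out.resnames, keep) if k]
            out.resids = out.resids[keep]
            out.charges = out.charges[keep]
            out.radii = out.radii[keep]
            out.xyz = out.xyz[keep]
            out.site_tags["titratable_proton"].remove(he2_ext[0])
        for aid, q in out.site_charge_states[ext]["deprotonated"].items():
            if aid in set(out.ids.tolist()):
                out.charges[out.index_of(aid)] = q
        out.protonated[ext] = False
    site = "glu_int_carboxylate"
    if out.protonated.get(site):
        prot_ids = out.site_charge_states[site]["protonated"]
        he2 = [a for a in prot_ids if a in set(out.site_tags.get("titratable_proton", []))]
        out.xyz[out.index_of(he2[0])] = start + 0.97 * axis
    else:
        hid = int(out.ids.max()) + 1
        out.ids = np.concatenate([out.ids, [hid]])
        out.elements.append("H")
        out.names.append("HE2")
        out.resnames.append("GLU")
        out.resids = np.concatenate([out.resids, [1]])
        out.charges = np.concatenate([out.charges, [GLU_CHARGES["protonated"]["HE2"]]])
        out.radii = np.concatenate([out.radii, [_RADII["H"]]])
        out.xyz = np.vstack([out.xyz, start + 0.97 * axis])
        out.site_tags.setdefault("titratable_proton", []).append(hid)
        # switch the site's partial charges to the protonated set
        for aid, q in out.site_charge_states[site]["protonated"].items():
            if aid in set(out.ids.tolist()):
                out.charges[out.index_of(aid)] = q
        out.site_charge_states[site]["protonated"][hid] = GLU_CHARGES["protonated"]["HE2"]
        out.site_charge_states[site]["deprotonated"][hid] = 0.0
        out.protonated[site] = True
    out.validate()
    return out


def random_water_box(n_waters: int, box: float = 10.0, seed: int = 0,
                     glu_o_separation: float = 11.0) -> Structure:
    """Random toy box: two tagged carboxylates plus ``n_waters`` randomly
    placed, randomly oriented waters (wire-search stress-test input)."""
    geometry = GeometryParams(glu_o_separation=glu_o_separation)
    b = _Builder()
    half = glu_o_separation / 2.0
    ext_ids = _add_glutamate(b, "ext", np.array([0.0, 0.0, +half]), np.array([0, 0, -1.0]),
                             False, resid=2)
    int_ids = _add_glutamate(b, "int", np.array([0.0, 0.0, -half]), np.array([0, 0, +1.0]),
                             True, resid=1)
    rng = np.random.default_rng(seed)
    occupied = [np.asarray(r[7]) for r in b.rows]  # avoid every glutamate atom
    resid = 10
    attempts = 0
    while resid - 10 < n_waters:
        attempts += 1
        if attempts > 500 * max(1, n_waters):
            raise ValueError("box too small for requested water count")
        pos = rng.uniform(-box / 2, box / 2, size=3)
        if min(np.linalg.norm(pos - p) for p in occupied) < 3.0:
            continue
        occupied.append(pos)
        _add_water(b, pos, _random_unit(rng), resid)
        resid += 1
    protonated = {"glu_ext_carboxylate": False, "glu_int_carboxylate": True}
    states = {"glu_ext_carboxylate": _charge_states(ext_ids),
              "glu_int_carboxylate": _charge_states(int_ids)}
    s = b.build(protonated, states)
    s.validate()
    return s
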