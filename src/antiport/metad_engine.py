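"""Well-tempered metadynamics with shared-bias multiple walkers.

The engine is dimension-generic (1D or 2D collective variables) and drives
:mod:`antiport.toy_system` Langevin walkers.  All walkers of one chain read
and deposit into a single shared :class:`BiasState`; hill heights follow the
well-tempered rule ``W = W0 * exp(-V_bias(s) / ((gamma - 1) kT))``, so a
revisited point always receives a smaller hill.

Two run modes mirror common practice:

* :func:`run_mwwtmetad` — the ion-migration setting: several walkers per
  chain, one or two independent chains, exchange-symmetric 2D surfaces.
  Chains can be merged with :func:`average_and_symmetrize_hills` and the
  run restarted with a raised initial hill height (``restart_height_factor``,
  conventionally 4).
* :func:`run_metad_1d` — the proton-transfer surrogate: a single 1D walker
  with the ``qmmm_like`` hill schedule (0.5 kcal/mol hills, 0.3 A spread,
  one hill every 5 steps) on an analytic proton-transfer profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .toy_system import LangevinParams, PotentialSurface, WalkerFrame

__all__ = [
    "Hill",
    "BiasState",
    "MetadParams",
    "QMMM_LIKE",
    "bias_value",
    "deposit_hill",
    "run_mwwtmetad",
    "run_metad_1d",
    "average_and_symmetrize_hills",
    "flat_bottom_restraint",
]

#: thermal energy at 298 K in kcal/mol, for runs parameterized in kcal/mol
KT_KCAL_298 = 0.0019872041 * 298.0


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian kernel (height is the *deposited* height,
    i.e. after well-tempered scaling)."""

    time: float  # ps
    center: tuple  # CV units
    widths: tuple  # sigma per CV
    height: float  # energy units (kT unless the run says otherwise)
    bias_factor: float  # gamma, dimensionless

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in np.atleast_1d(self.center)))
        object.__setattr__(self, "widths", tuple(float(w) for w in np.atleast_1d(self.widths)))
        if any(w <= 0 for w in self.widths):
            raise ValueError("hill widths must be positive")
        if self.height < 0:
            raise ValueError("hill height must be >= 0")
        if self.bias_factor <= 1:
            raise ValueError("bias factor gamma must be > 1")


class BiasState:
    """Accumulated metadynamics bias: an ordered hill list with fast
    vectorized evaluation.

    The hill list is append-only and shared by all walkers of a chain; the
    internal arrays grow by doubling so per-step evaluation stays O(n_hills)
    in numpy.
    """

    def __init__(self, dimension: int, initial_height: float, bias_factor: float,
                 deposition_stride: int = 1, kt: float = 1.0,
                 hills: Sequence[Hill] = (),
                 reflect_bounds: np.ndarray | None = None) -> None:
        if bias_factor <= 1:
            raise ValueError("bias factor gamma must be > 1")
        self.dimension = int(dimension)
        self.initial_height = float(initial_height)
        self.bias_factor = float(bias_factor)
        self.deposition_stride = int(deposition_stride)
        self.kt = float(kt)
        #: with reflecting CV walls the bias obeys a zero-flux condition;
        #: kernels deposited near a wall get mirror images beyond it so the
        #: in-domain bias is not under-filled at the edges
        self.reflect_bounds = None if reflect_bounds is None \
            else np.asarray(reflect_bounds, dtype=float).reshape(self.dimension, 2)
        self._n = 0  # kernel count (hills + boundary images)
        cap = 1024
        self._centers = np.empty((cap, self.dimension))
        self._inv_2w2 = np.empty((cap, self.dimension))
        self._inv_w2 = np.empty((cap, self.dimension))
        self._heights = np.empty(cap)
        self.hills: list[Hill] = []
        for h in hills:
            self.append(h)

    # -- hill management ----------------------------------------------
    def append(self, hill: Hill) -> None:
        if len(hill.center) != self.dimension:
            raise ValueError("hill dimension does not match bias state")
        if not math.isclose(hill.bias_factor, self.bias_factor, rel_tol=1e-12):
            raise ValueError("all hills of a bias state must share gamma")
        if self.hills and hill.time < self.hills[-1].time:
            raise ValueError("hills must be appended in time order")
        for center in self._kernel_centers(hill):
            if self._n == self._heights.size:
                self._grow()
            w = np.asarray(hill.widths)
            self._centers[self._n] = center
            self._inv_2w2[self._n] = 1.0 / (2.0 * w * w)
            self._inv_w2[self._n] = 1.0 / (w * w)
            self._heights[self._n] = hill.height
            self._n += 1
        self.hills.append(hill)

    def _kernel_centers(self, hill: Hill) -> list[np.ndarray]:
        """The hill center plus any non-negligible per-dimension mirror
        images at the reflecting walls (pruned beyond 5 sigma)."""
        c = np.asarray(hill.center, dtype=float)
        centers = [c]
        if self.reflect_bounds is None:
            return centers
        w = np.asarray(hill.widths)
        for d in range(self.dimension):
            for wall in self.reflect_bounds[d]:
                if abs(c[d] - wall) <= 5.0 * w[d]:
                    img = c.copy()
                    img[d] = 2.0 * wall - c[d]
                    centers.append(img)
        return centers

    def _grow(self) -> None:
        cap = self._heights.size * 2
        for name in ("_centers", "_inv_2w2", "_inv_w2"):
            arr = getattr(self, name)
            new = np.empty((cap, self.dimension))
            new[: self._n] = arr[: self._n]
            setattr(self, name, new)
        new_h = np.empty(cap)
        new_h[: self._n] = self._heights[: self._n]
        self._heights = new_h

    @property
    def n_hills(self) -> int:
        return len(self.hills)

    # -- evaluation ---------------------------------------------------
    def value(self, point: np.ndarray) -> float:
        """Bias at one point: sum of Gaussian kernels."""
        if self._n == 0:
            return 0.0
        x = np.atleast_1d(np.asarray(point, dtype=float))
        d2 = ((x - self._centers[: self._n]) ** 2 * self._inv_2w2[: self._n]).sum(axis=1)
        return float((self._heights[: self._n] * np.exp(-d2)).sum())

    def value_and_gradient(self, point: np.ndarray) -> tuple[float, np.ndarray]:
        if self._n == 0:
            return 0.0, np.zeros(self.dimension)
        x = np.atleast_1d(np.asarray(point, dtype=float))
        diff = x - self._centers[: self._n]
        e = self._heights[: self._n] * np.exp(-(diff ** 2 * self._inv_2w2[: self._n]).sum(axis=1))
        grad = -(e[:, None] * diff * self._inv_w2[: self._n]).sum(axis=0)
        return float(e.sum()), grad

    def values_and_gradients_multi(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bias values and gradients at several walker positions at once
        (shape (n_walkers, dimension)); the engine's per-step hot path."""
        pts = np.asarray(points, dtype=float)
        if self._n == 0:
            return np.zeros(pts.shape[0]), np.zeros_like(pts)
        diff = pts[None, :, :] - self._centers[: self._n, None, :]
        e = self._heights[: self._n, None] \
            * np.exp(-(diff ** 2 * self._inv_2w2[: self._n, None, :]).sum(axis=2))
        vals = e.sum(axis=0)
        grads = -(e[:, :, None] * diff * self._inv_w2[: self._n, None, :]).sum(axis=0)
        return vals, grads

    def values(self, points: np.ndarray, chunk: int = 256,
               point_chunk: int = 20_000) -> np.ndarray:
        """Vectorized bias at many points (shape (..., dimension)); both
        kernels and points are processed in chunks to bound peak memory."""
        pts = np.asarray(points, dtype=float)
        flat = pts.reshape(-1, self.dimension)
        out = np.zeros(flat.shape[0])
        for p0 in range(0, flat.shape[0], point_chunk):
            block = flat[p0: p0 + point_chunk]
            acc = out[p0: p0 + point_chunk]
            for i in range(0, self._n, chunk):
                c = self._centers[i: min(i + chunk, self._n)]
                iw = self._inv_2w2[i: min(i + chunk, self._n)]
                h = self._heights[i: min(i + chunk, self._n)]
                d2 = ((block[:, None, :] - c[None, :, :]) ** 2 * iw[None, :, :]).sum(axis=2)
                acc += (h[None, :] * np.exp(-d2)).sum(axis=1)
        return out.reshape(pts.shape[:-1])

    def subset(self, start: int, stop: int) -> "BiasState":
        """Bias state over hills[start:stop] (block-profile machinery)."""
        return BiasState(self.dimension, self.initial_height, self.bias_factor,
                         self.deposition_stride, self.kt, self.hills[start:stop],
                         reflect_bounds=self.reflect_bounds)

    def copy(self) -> "BiasState":
        return self.subset(0, self.n_hills)


def bias_value(bias: BiasState, point) -> float:
    """Total bias energy at ``point`` (empty hill list gives 0)."""
    return bias.value(point)


def deposit_hill(bias: BiasState, point, widths=None, time: float = 0.0) -> Hill:
    """Deposit a well-tempered hill at ``point`` and return it.

    The deposited height is ``W0 * exp(-V_bias(point) / ((gamma-1) kT))``
    with ``V_bias`` the bias accumulated so far at that point, so the first
    hill at a fresh point has height exactly W0.
    """
    w = np.atleast_1d(np.asarray(widths if widths is not None else [0.25] * bias.dimension,
                                 dtype=float))
    v = bias.value(point)
    height = bias.initial_height * math.exp(-v / ((bias.bias_factor - 1.0) * bias.kt))
    hill = Hill(time=time, center=tuple(np.atleast_1d(point)), widths=tuple(w),
                height=height, bias_factor=bias.bias_factor)
    bias.append(hill)
    return hill


@dataclass(frozen=True)
class MetadParams:
    """Run parameters for the metadynamics engine.

    Defaults target the 2D ion-migration toy runs; they are package choices
    (the corresponding production run parameters live in simulation inputs,
    not in any printed method section) and are freely overridable.
    """

    initial_height: float = 0.5  # W0, energy units (kT by default)
    bias_factor: float = 10.0  # gamma
    sigma: tuple | float = 0.25  # hill width per CV, CV units
    stride: int = 500  # steps between depositions
    dt: float = 0.2  # ps; keeps D*dt*|V''| well below 1 on the preset wells
    diffusion: float = 0.01  # nm^2/ps
    kt: float = 1.0  # thermal energy in the run's energy units
    n_steps: int = 50_000  # per walker
    frame_stride: int = 10  # steps between recorded frames
    restart_height_factor: float = 1.0  # 4.0 for the symmetrized restart

    def sigmas(self, dimension: int) -> np.ndarray:
        s = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if s.size == 1:
            s = np.repeat(s, dimension)
        if s.size != dimension:
            raise ValueError("sigma does not match CV dimension")
        if np.any(s <= 0) or self.initial_height < 0 or self.bias_factor <= 1 \
                or self.stride < 1 or self.dt <= 0 or self.diffusion <= 0:
            raise ValueError("invalid metadynamics parameters")
        return s


#: hill schedule of the proton-transfer (QM/MM-style) runs: 0.5 kcal/mol
#: hills of 0.3 A spread every 5 steps.  gamma is large because that
#: schedule is plain (untempered) metadynamics; a finite large gamma keeps
#: the same estimator machinery applicable.
QMMM_LIKE = MetadParams(initial_height=0.5, sigma=0.3, stride=5, bias_factor=50.0,
                        kt=KT_KCAL_298, dt=0.5, diffusion=0.002, n_steps=100_000,
                        frame_stride=10)


def run_mwwtmetad(surface: PotentialSurface, n_walkers: int = 8, n_chains: int = 1,
                  params: MetadParams | None = None, seed: int = 0,
                  initial_bias: Sequence[BiasState] | BiasState | None = None,
                  initial_positions: Sequence[np.ndarray] | None = None,
                  ) -> tuple[BiasState | list[BiasState], list[WalkerFrame]]:
    """Multiple-walker well-tempered metadynamics on an analytic surface.

    All walkers of a chain share one :class:`BiasState`; chains are fully
    independent (separate bias, separate RNG streams).  Deterministic given
    ``seed`` and ``params``.  Returns the per-chain bias (a bare
    :class:`BiasState` when ``n_chains == 1``, else a list) and the recorded
    frames, each carrying the instantaneous bias at its CV position.

    For the raised-height restart after chain averaging, pass the averaged
    bias as ``initial_bias`` and set ``params.restart_height_factor`` (the
    conventional restart uses a 4-fold larger initial hill height).
    """
    params = params or MetadParams()
    if n_walkers < 1 or n_chains < 1:
        raise ValueError("n_walkers and n_chains must be >= 1")
    dim = surface.dimension
    sig = params.sigmas(dim)
    w0 = params.initial_height * params.restart_height_factor

    if initial_bias is None:
        seeds: list[BiasState | None] = [None] * n_chains
    elif isinstance(initial_bias, BiasState):
        seeds = [initial_bias] + [None] * (n_chains - 1)
    else:
        seeds = list(initial_bias)
        if len(seeds) != n_chains:
            raise ValueError("initial_bias list must match n_chains")

    lang = LangevinParams(diffusion=params.diffusion, dt=params.dt, kt=params.kt)
    chain_biases: list[BiasState] = []
    frames: list[WalkerFrame] = []
    for chain in range(n_chains):
        label = chr(ord("A") + chain)
        if seeds[chain] is not None:
            bias = seeds[chain].copy()
            bias.initial_height = w0
            t0 = bias.hills[-1].time if bias.hills else 0.0
        else:
            bias = BiasState(dim, w0, params.bias_factor, params.stride, kt=params.kt,
                             reflect_bounds=surface.bounds)
            t0 = 0.0
        rngs = [np.random.default_rng([seed, chain, w]) for w in range(n_walkers)]
        if initial_positions is not None:
            xs = [np.atleast_1d(np.asarray(initial_positions[w], dtype=float))
                  for w in range(n_walkers)]
        else:
            xs = [rng.uniform(surface.bounds[:, 0], surface.bounds[:, 1]) for rng in rngs]

        x = np.array(xs)  # (n_walkers, dim)
        lo, hi = surface.bounds[:, 0], surface.bounds[:, 1]
        span = hi - lo
        noise_scale = math.sqrt(2.0 * lang.diffusion * lang.dt)
        drift = lang.diffusion / lang.kt * lang.dt
        has_multi = hasattr(surface, "gradient_multi")
        _, bgrads = bias.values_and_gradients_multi(x)
        for step in range(1, params.n_steps + 1):
            t = t0 + step * params.dt
            if has_multi:
                sgrads = surface.gradient_multi(x)
            else:
                sgrads = np.array([surface.gradient(x[w]) for w in range(n_walkers)])
            grads = sgrads + bgrads
            if not np.all(np.isfinite(grads)):
                raise FloatingPointError("non-finite gradient during metadynamics")
            noise = np.stack([rngs[w].standard_normal(dim) for w in range(n_walkers)])
            x = x - drift * grads + noise_scale * noise
            y = np.mod(x - lo, 2.0 * span)
            x = lo + np.where(y > span, 2.0 * span - y, y)
            if step % params.stride == 0:
                # sequential deposition: later walkers see the hills the
                # earlier ones just added (shared bias)
                for w in range(n_walkers):
                    deposit_hill(bias, x[w], widths=sig, time=t)
            # single bias evaluation per step at the new positions, reused
            # for the frame record and the next step's drift
            vals, bgrads = bias.values_and_gradients_multi(x)
            if step % params.frame_stride == 0:
                for w in range(n_walkers):
                    frames.append(WalkerFrame(time=t, walker_id=w, chain_label=label,
                                              cv=x[w].copy(),
                                              bias_at_frame=float(vals[w])))
        chain_biases.append(bias)

    if n_chains == 1:
        return chain_biases[0], frames
    return chain_biases, frames


def run_metad_1d(profile: PotentialSurface | Callable[[float], float],
                 params: MetadParams | None = None, seed: int = 0,
                 preset: str | None = None, bounds: tuple[float, float] = (-2.0, 2.0),
                 x0: float | None = None) -> tuple[BiasState, list[WalkerFrame]]:
    """Single-walker metadynamics along a 1D collective variable.

    ``profile`` is either a 1D :class:`PotentialSurface` or a plain callable
    (then ``bounds`` applies).  ``preset='qmmm_like'`` selects the
    proton-transfer hill schedule (0.5 kcal/mol, 0.3 A spread, stride 5).
    """
    if preset is not None:
        if preset != "qmmm_like":
            raise ValueError(f"unknown 1D preset {preset!r}")
        params = params or QMMM_LIKE
    params = params or MetadParams()
    if isinstance(profile, PotentialSurface):
        surface = profile
        if surface.dimension != 1:
            raise ValueError("run_metad_1d requires a 1D surface")
    else:
        surface = _CallableSurface(profile, bounds)
    init = None if x0 is None else [np.atleast_1d(x0)]
    return run_mwwtmetad(surface, n_walkers=1, n_chains=1, params=params, seed=seed,
                         initial_positions=init)


class _CallableSurface:
    """Adapter exposing the PotentialSurface interface for a plain 1D callable
    (gradient by central differences)."""

    dimension = 1

    def __init__(self, fn: Callable[[float], float], bounds: tuple[float, float]):
        self._fn = fn
        self.bounds = np.asarray([bounds], dtype=float)

    def energy(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.array([self._fn(float(p[0])) for p in pts])

    def gradient(self, point):
        x = float(np.atleast_1d(point)[0])
        h = 1e-5
        return np.array([(self._fn(x + h) - self._fn(x - h)) / (2 * h)])

    def in_bounds(self, point):
        x = float(np.atleast_1d(point)[0])
        return self.bounds[0, 0] <= x <= self.bounds[0, 1]


def average_and_symmetrize_hills(chain_a: BiasState, chain_b: BiasState) -> BiasState:
    """Merge two chains' hills into one exchange-symmetric bias.

    The output bias function is
    ``B*(z1,z2) = (B_A(z1,z2) + B_A(z2,z1) + B_B(z1,z2) + B_B(z2,z1)) / 4``,
    realized hill-wise: every input hill is emitted at quarter height
    together with its permuted twin at quarter height, so the result remains
    a plain hill list and restarts stay hill-based.
    """
    for b in (chain_a, chain_b):
        if b.dimension != 2:
            raise ValueError("chain averaging is defined for 2D (two-ion) biases")
    if not math.isclose(chain_a.bias_factor, chain_b.bias_factor, rel_tol=1e-12):
        raise ValueError("chains must share the bias factor gamma")
    merged = sorted(chain_a.hills + chain_b.hills, key=lambda h: h.time)
    out = BiasState(2, chain_a.initial_height, chain_a.bias_factor,
                    chain_a.deposition_stride, kt=chain_a.kt,
                    reflect_bounds=chain_a.reflect_bounds)
    for h in merged:
        out.append(replace(h, height=h.height / 4.0))
        out.append(Hill(time=h.time, center=h.center[::-1], widths=h.widths[::-1],
                        height=h.height / 4.0, bias_factor=h.bias_factor))
    return out


def flat_bottom_restraint(distance: float, upper_wall: float = 2.5,
                          k: float = 1.0) -> tuple[float, float]:
    """Upper-wall flat-bottom restraint (default wall 2.5 A, the cutoff used
    to keep dynamic O-H distances bonded during proton-transfer runs).

    Returns ``(energy, force)``: zero below the wall, harmonic
    ``k/2 (d - wall)^2`` above it; the force is ``-dE/dd`` (negative beyond
    the wall, i.e. pulling the distance back toward it).
    """
    if k < 0:
        raise ValueError("force constant must be >= 0")
    if distance <= upper_wall:
        return 0.0, 0.0
    excess = distance - upper_wall
    return 0.5 * k * excess * excess, -k * excess
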