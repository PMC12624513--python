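"""Free-energy-surface reconstruction and landscape analysis.

The free energy is estimated from the final accumulated bias with the
well-tempered relation ``F(s) = -(gamma/(gamma-1)) V_bias(s)`` and shifted
so that its minimum is zero (the ``min_zero`` offset convention: only
relative free energies are meaningful here).  On top of the gridded
estimate the module provides exchange symmetrization, a strict-local-minima
inventory with basin depths, minimax ("minimum-energy-path") barriers
between basins, and block-averaged profiles with a pointwise spread
estimate for convergence assessment.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metad_engine import BiasState

__all__ = [
    "FESGrid",
    "Minimum",
    "MinimaSet",
    "PathResult",
    "BlockProfiles",
    "fes_from_hills",
    "symmetrize_fes",
    "find_minima",
    "mep_barrier",
    "block_profiles",
]


@dataclass
class FESGrid:
    """Gridded free-energy estimate.

    ``axes`` holds one monotone coordinate array per CV; ``values`` has shape
    ``(len(axes[0]), ...)`` with free energies in the run's energy units
    (kT unless stated otherwise), offset so that ``min(values) == 0``.
    """

    axes: list[np.ndarray]
    values: np.ndarray
    offset_convention: str = "min_zero"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axes = [np.asarray(a, dtype=float) for a in self.axes]
        self.values = np.asarray(self.values, dtype=float)
        for a in self.axes:
            if a.ndim != 1 or a.size < 2 or np.any(np.diff(a) <= 0):
                raise ValueError("each axis must be a monotone 1D array")
        if self.values.shape != tuple(a.size for a in self.axes):
            raise ValueError("values shape does not match axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("free energy values must be finite")
        if self.offset_convention == "min_zero" and self.values.size:
            if abs(float(self.values.min())) > 1e-9:
                raise ValueError("min_zero convention violated")

    @property
    def dimension(self) -> int:
        return len(self.axes)

    def nearest_index(self, point) -> tuple:
        p = np.atleast_1d(np.asarray(point, dtype=float))
        return tuple(int(np.argmin(np.abs(ax - x))) for ax, x in zip(self.axes, p))

    def coords(self, index: tuple) -> np.ndarray:
        return np.array([ax[i] for ax, i in zip(self.axes, index)])


def _min_zero(values: np.ndarray) -> np.ndarray:
    return values - values.min() if values.size else values


def fes_from_hills(bias: BiasState, axes: Sequence[np.ndarray]) -> FESGrid:
    """Well-tempered estimator on a grid: ``F = -(gamma/(gamma-1)) V_bias``,
    min-zero shifted.  An empty hill list yields an all-zero surface."""
    axes = [np.asarray(a, dtype=float) for a in axes]
    if len(axes) != bias.dimension or any(a.size == 0 for a in axes):
        raise ValueError("axes must be non-empty and match the bias dimension")
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack(mesh, axis=-1)
    gamma = bias.bias_factor
    f = -(gamma / (gamma - 1.0)) * bias.values(pts)
    return FESGrid(axes=list(axes), values=_min_zero(f),
                   provenance={"gamma": gamma, "n_hills": bias.n_hills,
                               "kt": bias.kt, "symmetrized": False})


def symmetrize_fes(fes: FESGrid) -> FESGrid:
    """Permutation symmetrization ``F*(i,j) = (F(i,j)+F(j,i))/2`` for the
    exchange-symmetric two-ion landscapes; idempotent."""
    if fes.dimension != 2:
        raise ValueError("symmetrization needs a 2D surface")
    if fes.axes[0].size != fes.axes[1].size or not np.allclose(fes.axes[0], fes.axes[1]):
        raise ValueError("symmetrization needs identical axes on both CVs")
    sym = 0.5 * (fes.values + fes.values.T)
    prov = dict(fes.provenance)
    prov["symmetrized"] = True
    return FESGrid(axes=list(fes.axes), values=_min_zero(sym), provenance=prov)


@dataclass(frozen=True)
class Minimum:
    label: str
    location: np.ndarray  # CV units
    energy: float  # F at the minimum (min_zero scale)
    depth: float  # basin depth: lowest escape barrier (prominence)
    plateau: bool = False


@dataclass(frozen=True)
class MinimaSet:
    minima: tuple

    def __iter__(self):
        return iter(self.minima)

    def __len__(self):
        return len(self.minima)

    def locations(self) -> np.ndarray:
        return np.array([m.location for m in self.minima])


def _neighbors(index: tuple, shape: tuple):
    if len(shape) == 1:
        (i,) = index
        for di in (-1, 1):
            j = i + di
            if 0 <= j < shape[0]:
                yield (j,)
    else:
        i, j = index
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < shape[0] and 0 <= b < shape[1]:
                    yield (a, b)


def find_minima(fes: FESGrid, depth_threshold: float = 0.0) -> MinimaSet:
    """Strict local minima (below all 2 or 8 grid neighbors) whose basin
    depth is at least ``depth_threshold``.

    Basin depth is the topographic prominence on the grid: the minimax
    barrier separating the minimum from any strictly lower grid point (the
    global minimum gets the full surface range).  Minima are labeled
    ``m1, m2, ...`` by ascending free energy; exact plateaus are resolved to
    the lowest lexicographic grid index and flagged.  Only strict interior
    grid points qualify: a dip pinned against the CV box boundary is a
    constrained artifact of the bounded domain, not a landscape feature.
    """
    if depth_threshold < 0:
        raise ValueError("depth threshold must be >= 0")
    v = fes.values
    candidates: list[tuple] = []
    it = np.ndindex(*v.shape)
    for idx in it:
        if any(i == 0 or i == s - 1 for i, s in zip(idx, v.shape)):
            continue
        val = v[idx]
        neigh = [v[n] for n in _neighbors(idx, v.shape)]
        if all(val < nv for nv in neigh):
            candidates.append(idx)
        elif all(val <= nv for nv in neigh) and any(val == nv for nv in neigh):
            # exact plateau: the connected flat patch is a minimum only if
            # everything bordering it is strictly higher; resolve to the
            # lexicographically smallest cell of the patch
            ok, patch = _plateau_is_minimum(v, idx)
            if ok and idx == min(patch):
                candidates.append(idx)

    minima = []
    vmax = float(v.max())
    for idx in candidates:
        val = float(v[idx])
        depth = _escape_barrier(v, idx)
        if depth is None:  # global minimum (no lower point anywhere)
            depth = vmax - val
        if depth >= depth_threshold:
            neigh_vals = [v[n] for n in _neighbors(idx, v.shape)]
            minima.append(Minimum(label="", location=fes.coords(idx), energy=val,
                                  depth=float(depth),
                                  plateau=any(val == nv for nv in neigh_vals)))
    minima.sort(key=lambda m: (m.energy, tuple(m.location)))
    labeled = tuple(
        Minimum(label=f"m{i + 1}", location=m.location, energy=m.energy,
                depth=m.depth, plateau=m.plateau)
        for i, m in enumerate(minima))
    return MinimaSet(minima=labeled)


def _plateau_is_minimum(v: np.ndarray, start: tuple) -> tuple[bool, set]:
    """Flood the connected patch of cells equal to v[start]; a true plateau
    minimum is enclosed entirely by strictly higher cells.  Returns the
    verdict and the patch (for lexicographic tie-breaking)."""
    val = v[start]
    stack = [start]
    seen = {start}
    enclosed = False
    while stack:
        idx = stack.pop()
        for n in _neighbors(idx, v.shape):
            if v[n] == val:
                if n not in seen:
                    seen.add(n)
                    stack.append(n)
            elif v[n] < val:
                return False, seen
            else:
                enclosed = True
    return enclosed, seen


def _escape_barrier(v: np.ndarray, start: tuple) -> float | None:
    """Minimax barrier (relative to v[start]) to reach any strictly lower
    grid point; None if no lower point exists."""
    f0 = v[start]
    best = np.full(v.shape, np.inf)
    best[start] = f0
    heap = [(f0, start)]
    while heap:
        cost, idx = heapq.heappop(heap)
        if cost > best[idx]:
            continue
        if v[idx] < f0:
            return float(cost - f0)
        for n in _neighbors(idx, v.shape):
            c = max(cost, float(v[n]))
            if c < best[n]:
                best[n] = c
                heapq.heappush(heap, (c, n))
    return None


@dataclass(frozen=True)
class PathResult:
    """Minimax path between two basins: consecutive grid neighbors, the
    saddle height relative to the start minimum, and the saddle location."""

    nodes: np.ndarray  # (n, dim) CV coordinates along the path
    saddle_height: float
    barrier_point: np.ndarray


def mep_barrier(fes: FESGrid, start, end) -> PathResult:
    """Lowest-maximum path on the grid from ``start`` to ``end``.

    Dijkstra-like relaxation with path cost ``max(F)`` over visited nodes;
    ``saddle_height`` is that minimax value minus ``F(start)``.
    """
    v = fes.values
    s = fes.nearest_index(start)
    e = fes.nearest_index(end)
    for point, idx in ((start, s), (end, e)):
        p = np.atleast_1d(np.asarray(point, dtype=float))
        for x, ax in zip(p, fes.axes):
            if x < ax[0] - 1e-9 or x > ax[-1] + 1e-9:
                raise ValueError(f"point {point} outside the FES grid")
    best = np.full(v.shape, np.inf)
    best[s] = v[s]
    prev: dict[tuple, tuple] = {}
    heap = [(float(v[s]), s)]
    while heap:
        cost, idx = heapq.heappop(heap)
        if cost > best[idx]:
            continue
        if idx == e:
            break
        for n in _neighbors(idx, v.shape):
            c = max(cost, float(v[n]))
            if c < best[n]:
                best[n] = c
                prev[n] = idx
                heapq.heappush(heap, (c, n))
    path = [e]
    while path[-1] != s:
        path.append(prev[path[-1]])
    path.reverse()
    nodes = np.array([fes.coords(i) for i in path])
    energies = np.array([v[i] for i in path])
    k = int(np.argmax(energies))
    return PathResult(nodes=nodes,
                      saddle_height=float(energies[k] - v[s]),
                      barrier_point=fes.coords(path[k]))


@dataclass(frozen=True)
class BlockProfiles:
    """Profiles at successive kernel-count checkpoints, their mean and
    pointwise standard deviation."""

    mean: np.ndarray
    profiles: np.ndarray  # (n_blocks, *grid)
    spread: np.ndarray  # pointwise std across profiles
    axes: tuple
    boundaries: tuple  # hill counts at each checkpoint


def block_profiles(bias: BiasState, axes: Sequence[np.ndarray],
                   n_blocks: int = 9, block_size_kernels: int = 2500) -> BlockProfiles:
    """Block-averaged free-energy profiles.

    The hill sequence is partitioned into consecutive blocks of
    ``block_size_kernels`` kernels (defaults: 9 blocks of 2,500); at each
    block boundary a profile is estimated from the bias accumulated up to
    that point (same estimator as :func:`fes_from_hills`, min-zero shifted).
    The mean profile and the pointwise standard deviation across the
    checkpoint profiles quantify convergence: for a converged run the later
    profiles coincide and the spread collapses.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if block_size_kernels < 1:
        raise ValueError("block size must be >= 1 kernel")
    axes = [np.asarray(a, dtype=float) for a in axes]
    boundaries = []
    for k in range(1, n_blocks + 1):
        b = min(k * block_size_kernels, bias.n_hills)
        boundaries.append(b)
        if b == bias.n_hills:
            break
    profiles = []
    for b in boundaries:
        grid = fes_from_hills(bias.subset(0, b), axes)
        profiles.append(grid.values)
    prof = np.array(profiles)
    return BlockProfiles(mean=prof.mean(axis=0), profiles=prof,
                         spread=prof.std(axis=0), axes=tuple(axes),
                         boundaries=tuple(boundaries))
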