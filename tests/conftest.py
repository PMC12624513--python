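"""Shared fixtures: the expensive simulation runs are session-scoped so the
FES-recovery, reweighting and block-profile checks all reuse them."""

from __future__ import annotations

import numpy as np
import pytest

from antiport import metad_engine as me
from antiport import toy_system as ts

#: the 2D benchmark surface for reweighting checks: exchange-symmetric,
#: shallow enough (~3 kT wells) that a desk-scale run converges
REWEIGHT_TERMS = (
    (-3.0, (0.8, -0.8), (0.35, 0.35)),
    (-3.0, (-0.8, 0.8), (0.35, 0.35)),
    (-2.0, (0.0, 0.0), (0.4, 0.4)),
)


def reweight_surface() -> ts.PotentialSurface:
    return ts.PotentialSurface(dimension=2, terms=REWEIGHT_TERMS,
                               bounds=[(-1.5, 1.5)] * 2, symmetric=True)


@pytest.fixture(scope="session")
def double_well() -> ts.PotentialSurface:
    return ts.make_landscape("double_well_1d")


@pytest.fixture(scope="session")
def dw_run(double_well):
    """Converged 1D multi-walker run on the double well: 4 walkers sharing
    one bias, 2e5 steps each."""
    params = me.MetadParams(n_steps=200_000, diffusion=0.02)
    bias, frames = me.run_mwwtmetad(double_well, n_walkers=4, n_chains=1,
                                    params=params, seed=11)
    return bias, frames


@pytest.fixture(scope="session")
def reweight_run():
    """Converged 2D run recording every step: 4 walkers, 1e5 steps, so the
    second half of the trajectory holds 2e5 frames for reweighting."""
    surf = reweight_surface()
    params = me.MetadParams(n_steps=100_000, diffusion=0.02, frame_stride=1)
    bias, frames = me.run_mwwtmetad(surf, n_walkers=4, n_chains=1,
                                    params=params, seed=3)
    return surf, bias, frames


@pytest.fixture(scope="session")
def two_chain_run():
    """Two independent chains on the 2D benchmark surface, for the
    averaging/symmetrization protocol."""
    surf = reweight_surface()
    params = me.MetadParams(n_steps=5_000, diffusion=0.02)
    chains, frames = me.run_mwwtmetad(surf, n_walkers=2, n_chains=2,
                                      params=params, seed=5)
    return surf, chains, frames


@pytest.fixture()
def wired_snapshot():
    snap = ts.build_snapshot((0.8, -0.8))
    return ts.plant_wire(snap, n_waters=3)


def brute_force_minimax(values: np.ndarray, start: tuple, end: tuple) -> float:
    """Independent minimax-path oracle: the barrier between two grid cells
    is the smallest threshold T such that start and end are connected in
    the sub-grid {F <= T} (checked by flood fill over sorted levels)."""
    levels = np.unique(values)
    lo = max(values[start], values[end])
    for t in levels[levels >= lo]:
        mask = values <= t
        if not (mask[start] and mask[end]):
            continue
        stack = [start]
        seen = {start}
        while stack:
            cur = stack.pop()
            if cur == end:
                return float(t)
            i, j = cur
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    n = (i + di, j + dj)
                    if 0 <= n[0] < mask.shape[0] and 0 <= n[1] < mask.shape[1] \
                            and mask[n] and n not in seen:
                        seen.add(n)
                        stack.append(n)
    raise AssertionError("grid is connected; a threshold must exist")


def brute_force_wires(structure, criteria, max_waters):
    """Independent wire oracle: explicit all-pairs H-bond evaluation and
    exhaustive enumeration of water sequences up to ``max_waters``."""
    import itertools
    import math as m

    tags = structure.site_tags
    pos = {int(a): structure.xyz[structure.index_of(int(a))] for a in structure.ids}
    waters = list(tags.get("water_O", []))
    w_h = list(tags.get("water_H", []))
    prot = list(tags.get("titratable_proton", []))
    starts = list(tags["glu_int_carboxylate"])
    ends = list(tags["glu_ext_carboxylate"])

    def hydrogens(o):
        src = w_h if o in waters else prot
        return [h for h in src if np.linalg.norm(pos[h] - pos[o]) <= 1.2]

    def bonded(a, b):
        d = np.linalg.norm(pos[a] - pos[b])
        if d > criteria.max_da_distance:
            return False
        for donor, acceptor in ((a, b), (b, a)):
            for h in hydrogens(donor):
                v1 = pos[donor] - pos[h]
                v2 = pos[acceptor] - pos[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = m.degrees(m.acos(max(-1.0, min(1.0, float(cosang)))))
                if ang >= criteria.min_dha_angle:
                    return True
        return False

    found = set()
    for s in starts:
        for e in ends:
            for n in range(0, max_waters + 1):
                for combo in itertools.permutations(waters, n):
                    chain = [s, *combo, e]
                    if all(bonded(chain[i], chain[i + 1]) for i in range(len(chain) - 1)):
                        found.add(tuple(chain))
    return found
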