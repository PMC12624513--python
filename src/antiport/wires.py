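"""Hydrogen-bond graphs and Grotthuss water-wire detection.

A proton can relay between the two gating carboxylates along a contiguous
hydrogen-bonded chain of waters (the Grotthuss mechanism).  This module
builds the donor/acceptor oxygen graph of a snapshot under geometric
H-bond criteria, enumerates simple wire paths from the intracellular to the
extracellular carboxylate with a bounded number of interior waters, and
provides the bond-length-difference collective variable used to drive the
concerted proton transfer.

Default criteria (O-O distance <= 3.5 A, D-H...A angle >= 120 deg) are the
standard MD hydrogen-bond conventions; they are package choices and fully
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .toy_system import Structure

__all__ = [
    "HBondCriteria",
    "WirePath",
    "hbond_edges",
    "find_wires",
    "wire_occupancy",
    "proton_transfer_cv",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition."""

    max_da_distance: float = 3.5  # donor-O to acceptor-O, Angstrom
    min_dha_angle: float = 120.0  # donor-H...acceptor angle, degrees

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("H-bond distance cutoff must be positive")
        if not (0.0 < self.min_dha_angle <= 180.0):
            raise ValueError("H-bond angle cutoff must lie in (0, 180]")


@dataclass(frozen=True)
class WirePath:
    """One donor-acceptor chain from the intracellular to the extracellular
    carboxylate oxygen; interior nodes are water oxygens."""

    node_ids: tuple  # ordered atom ids, carboxylate O ... carboxylate O
    n_waters: int
    hop_distances: tuple  # Angstrom, one per edge


def _oxygen_inventory(structure: Structure):
    """Oxygen nodes of the H-bond graph with their attached hydrogens.

    Water oxygens donate through their two hydrogens; a carboxylate oxygen
    donates only through a titratable proton within bonding distance (i.e.
    when its site is protonated), otherwise it is an acceptor.
    """
    tags = structure.site_tags
    for role in ("glu_int_carboxylate", "glu_ext_carboxylate"):
        if not tags.get(role):
            raise ValueError(f"missing site tag {role!r}")
    nodes: dict[int, dict] = {}
    water_h = tags.get("water_H", [])
    h_pos = {hid: structure.xyz[structure.index_of(hid)] for hid in water_h}
    for oid in tags.get("water_O", []):
        opos = structure.xyz[structure.index_of(oid)]
        hs = [hid for hid, hp in h_pos.items() if np.linalg.norm(hp - opos) <= 1.2]
        nodes[oid] = {"kind": "water", "pos": opos, "h": hs}
    for role, kind in (("glu_int_carboxylate", "glu_int"),
                       ("glu_ext_carboxylate", "glu_ext")):
        for oid in tags[role]:
            opos = structure.xyz[structure.index_of(oid)]
            hs = []
            for hid in tags.get("titratable_proton", []):
                if np.linalg.norm(structure.xyz[structure.index_of(hid)] - opos) <= 1.2:
                    hs.append(hid)
            nodes[oid] = {"kind": kind, "pos": opos, "h": hs}
    return nodes


def _donates(structure: Structure, donor: dict, acceptor_pos: np.ndarray,
             criteria: HBondCriteria) -> bool:
    for hid in donor["h"]:
        hp = structure.xyz[structure.index_of(hid)]
        v1 = donor["pos"] - hp
        v2 = acceptor_pos - hp
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            continue
        cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
        angle = np.degrees(np.arccos(cosang))
        if angle >= criteria.min_dha_angle:
            return True
    return False


def hbond_edges(structure: Structure, criteria: HBondCriteria | None = None,
                ) -> list[tuple[int, int]]:
    """Undirected H-bond edges between oxygen atoms.

    An edge (a, b) exists when the O-O distance is within the cutoff and at
    least one of the two oxygens donates an explicit hydrogen toward the
    other with a D-H...A angle above the cutoff.
    """
    criteria = criteria or HBondCriteria()
    nodes = _oxygen_inventory(structure)
    ids = sorted(nodes)
    edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = float(np.linalg.norm(nodes[a]["pos"] - nodes[b]["pos"]))
            if d > criteria.max_da_distance:
                continue
            if _donates(structure, nodes[a], nodes[b]["pos"], criteria) \
                    or _donates(structure, nodes[b], nodes[a]["pos"], criteria):
                edges.append((a, b))
    return edges


def find_wires(structure: Structure, criteria: HBondCriteria | None = None,
               max_waters: int = 3) -> list[WirePath]:
    """All simple water wires from the intracellular to the extracellular
    carboxylate with at most ``max_waters`` interior waters.

    The default of three waters matches the canonical short Grotthuss wire
    between the two gating glutamates.  Paths are returned shortest first
    (fewest waters), then by node ids; the empty list means no wire.
    """
    if max_waters < 1:
        raise ValueError("max_waters must be >= 1")
    criteria = criteria or HBondCriteria()
    nodes = _oxygen_inventory(structure)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(hbond_edges(structure, criteria))
    starts = [o for o, n in nodes.items() if n["kind"] == "glu_int"]
    ends = [o for o, n in nodes.items() if n["kind"] == "glu_ext"]
    waters = {o for o, n in nodes.items() if n["kind"] == "water"}
    wires = []
    seen = set()
    for s in starts:
        for e in ends:
            if s == e or s not in g or e not in g:
                continue
            for path in nx.all_simple_paths(g, s, e, cutoff=max_waters + 1):
                interior = path[1:-1]
                if not all(p in waters for p in interior):
                    continue
                key = tuple(path)
                if key in seen:
                    continue
                seen.add(key)
                hops = tuple(
                    float(np.linalg.norm(nodes[path[i]]["pos"] - nodes[path[i + 1]]["pos"]))
                    for i in range(len(path) - 1))
                wires.append(WirePath(node_ids=key, n_waters=len(interior),
                                      hop_distances=hops))
    wires.sort(key=lambda w: (w.n_waters, w.node_ids))
    return wires


def wire_occupancy(snapshots: Sequence[Structure],
                   criteria: HBondCriteria | None = None,
                   max_waters: int = 3) -> tuple[float, list[bool]]:
    """Fraction of frames containing at least one wire, with per-frame flags."""
    if len(snapshots) < 1:
        raise ValueError("need at least one snapshot")
    flags = [bool(find_wires(s, criteria, max_waters)) for s in snapshots]
    return sum(flags) / len(flags), flags


def proton_transfer_cv(structure: Structure,
                       forming_pairs: Sequence[tuple[int, int]],
                       formed_pairs: Sequence[tuple[int, int]]) -> float:
    """Bond-length-difference collective variable for concerted proton hops:
    sum of O-H distances about to be formed minus sum of O-H distances
    formed in the starting configuration (Angstrom).  Decreases monotonically
    as the protons migrate from reactant to product geometry."""

    def total(pairs):
        t = 0.0
        for h, o in pairs:
            t += float(np.linalg.norm(structure.xyz[structure.index_of(h)]
                                      - structure.xyz[structure.index_of(o)]))
        return t

    return total(forming_pairs) - total(formed_pairs)
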