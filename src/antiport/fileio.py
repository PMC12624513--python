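"""Readers and writers for the text formats of the pipeline.

HILLS, COLVAR and fes.dat follow the PLUMED dialect (a leading
``#! FIELDS ...`` header, whitespace-separated numeric columns); structures
are standard PDB with charges, radii and site roles in a plain-text sidecar
table.  Writers stamp every file with the package version, the run seed and
a config hash, and close with a row-count footer that readers verify, so a
silently truncated file is always rejected.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from biotite.structure import Atom, array as atom_array_from_atoms
from biotite.structure.io.pdb import PDBFile

from . import __version__
from .fes_analysis import FESGrid
from .metad_engine import BiasState, Hill
from .toy_system import GLU_CHARGES, Structure, WalkerFrame, _RADII

__all__ = [
    "RunConfig",
    "read_hills",
    "write_hills",
    "read_colvar",
    "write_colvar",
    "read_fes",
    "write_fes",
    "read_structure",
    "write_structure",
]

log = logging.getLogger(__name__)

_FMT = "%.17g"  # bit-exact float round-trips


@dataclass
class RunConfig:
    """One document holding engine and analysis parameters for a run."""

    seed: int = 0
    # engine
    initial_height: float = 0.5
    bias_factor: float = 10.0
    sigma: float = 0.25
    stride: int = 500
    dt: float = 1.0
    diffusion: float = 0.01
    n_steps: int = 50_000
    n_walkers: int = 4
    n_chains: int = 2
    frame_stride: int = 10
    # analysis
    grid_points: int = 100
    n_bins: int = 40
    top_k: int = 10
    max_waters: int = 3
    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    # units
    energy_unit: str = "kT"
    cv_unit: str = "nm"

    def __post_init__(self) -> None:
        positive = ["bias_factor", "sigma", "stride", "dt", "diffusion", "n_steps",
                    "n_walkers", "n_chains", "frame_stride", "grid_points", "n_bins",
                    "top_k", "max_waters", "hbond_distance", "hbond_angle"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.initial_height < 0:
            raise ValueError("initial_height must be >= 0")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _header(fields: Sequence[str], sets: dict) -> list[str]:
    lines = [f"#! FIELDS {' '.join(fields)}"]
    lines.append(f"#! SET package antiport {__version__}")
    for k, v in sets.items():
        lines.append(f"#! SET {k} {v}")
    return lines


def _parse_plumed(path):
    """Yield (fields, sets, rows) for a PLUMED-style table; rows carry line
    numbers for error reporting.  Verifies the nrows footer when present."""
    fields = None
    sets: dict[str, str] = {}
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            toks = line.split()
            if len(toks) >= 2 and toks[1] == "FIELDS":
                fields = toks[2:]
            elif len(toks) >= 4 and toks[1] == "SET":
                sets[toks[2]] = " ".join(toks[3:])
            continue
        if line.startswith("#"):
            continue
        rows.append((lineno, line.split()))
    if fields is None:
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    if "nrows" in sets:
        expected = int(sets["nrows"])
        if expected != len(rows):
            raise ValueError(
                f"{path}: truncated file: footer declares {expected} rows, found {len(rows)}")
    return fields, sets, rows


# ----------------------------------------------------------------------
# HILLS
# ----------------------------------------------------------------------

def write_hills(bias: BiasState, path, seed: int | None = None,
                config_hash: str | None = None) -> None:
    dim = bias.dimension
    cvs = [f"cv{i + 1}" for i in range(dim)]
    fields = ["time", *cvs, *[f"sigma_{c}" for c in cvs], "height", "biasf"]
    sets = {"kt": repr(bias.kt), "initial_height": repr(bias.initial_height),
            "stride": bias.deposition_stride}
    if bias.reflect_bounds is not None:
        sets["reflect_bounds"] = " ".join(
            _FMT % v for row in bias.reflect_bounds for v in row)
    if seed is not None:
        sets["seed"] = seed
    if config_hash is not None:
        sets["config_hash"] = config_hash
    lines = _header(fields, sets)
    for h in bias.hills:
        vals = [h.time, *h.center, *h.widths, h.height, h.bias_factor]
        lines.append(" ".join(_FMT % v for v in vals))
    lines.append(f"#! SET nrows {bias.n_hills}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_hills(path) -> BiasState:
    """Parse a PLUMED-dialect HILLS file into a :class:`BiasState`.

    Tolerates comments, blank lines and scientific notation; raises with
    the offending line number on malformed rows.
    """
    fields, sets, rows = _parse_plumed(path)
    sigma_cols = [f for f in fields if f.startswith("sigma_")]
    dim = len(sigma_cols)
    needed = ["time", "height", "biasf"]
    for f in needed:
        if f not in fields:
            raise ValueError(f"{path}: header lacks required column {f!r}")
    if dim < 1:
        raise ValueError(f"{path}: header declares no sigma_* columns")
    cv_cols = [f[len("sigma_"):] for f in sigma_cols]
    col = {f: i for i, f in enumerate(fields)}
    hills = []
    for lineno, toks in rows:
        if len(toks) != len(fields):
            raise ValueError(
                f"{path}:{lineno}: expected {len(fields)} columns, found {len(toks)}")
        try:
            vals = [float(t) for t in toks]
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: non-numeric value ({err})") from None
        hills.append(Hill(
            time=vals[col["time"]],
            center=tuple(vals[col[c]] for c in cv_cols),
            widths=tuple(vals[col[s]] for s in sigma_cols),
            height=vals[col["height"]],
            bias_factor=vals[col["biasf"]],
        ))
    gamma = hills[0].bias_factor if hills else 10.0
    reflect = None
    if "reflect_bounds" in sets:
        vals = [float(t) for t in sets["reflect_bounds"].split()]
        reflect = np.asarray(vals).reshape(dim, 2)
    bias = BiasState(dimension=dim,
                     initial_height=float(sets.get("initial_height", 0.5)),
                     bias_factor=gamma,
                     deposition_stride=int(sets.get("stride", 1)),
                     kt=float(sets.get("kt", 1.0)),
                     reflect_bounds=reflect)
    for h in hills:
        bias.append(h)
    return bias


# ----------------------------------------------------------------------
# COLVAR
# ----------------------------------------------------------------------

def write_colvar(frames: Sequence[WalkerFrame], path, seed: int | None = None,
                 config_hash: str | None = None) -> None:
    dim = len(frames[0].cv) if frames else 2
    fields = ["time", "walker", "chain", *[f"cv{i + 1}" for i in range(dim)], "bias"]
    sets = {}
    if seed is not None:
        sets["seed"] = seed
    if config_hash is not None:
        sets["config_hash"] = config_hash
    lines = _header(fields, sets)
    for f in frames:
        vals = [_FMT % f.time, str(f.walker_id), f.chain_label,
                *[_FMT % c for c in f.cv], _FMT % f.bias_at_frame]
        lines.append(" ".join(vals))
    lines.append(f"#! SET nrows {len(frames)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_colvar(path, require_bias: bool = True) -> list[WalkerFrame]:
    fields, _sets, rows = _parse_plumed(path)
    cv_cols = [f for f in fields if f.startswith("cv")]
    if "bias" not in fields and require_bias:
        raise ValueError(
            f"{path}: no 'bias' column; reweighting needs per-frame bias values — "
            "re-export the frame table with the bias recorded")
    col = {f: i for i, f in enumerate(fields)}
    frames = []
    for lineno, toks in rows:
        if len(toks) != len(fields):
            raise ValueError(
                f"{path}:{lineno}: expected {len(fields)} columns, found {len(toks)}")
        try:
            frames.append(WalkerFrame(
                time=float(toks[col["time"]]),
                walker_id=int(toks[col["walker"]]) if "walker" in col else 0,
                chain_label=toks[col["chain"]] if "chain" in col else "A",
                cv=np.array([float(toks[col[c]]) for c in cv_cols]),
                bias_at_frame=float(toks[col["bias"]]) if "bias" in col else 0.0,
            ))
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: malformed row ({err})") from None
    return frames


# ----------------------------------------------------------------------
# fes.dat
# ----------------------------------------------------------------------

def write_fes(fes: FESGrid, path, seed: int | None = None,
              config_hash: str | None = None) -> None:
    """Gridded FES in the fes.dat convention: CV columns then the free
    energy, with a blank line between blocks of the first CV index."""
    dim = fes.dimension
    fields = [*[f"cv{i + 1}" for i in range(dim)], "free_energy"]
    sets = {"symmetrized": fes.provenance.get("symmetrized", False),
            "gamma": fes.provenance.get("gamma", ""),
            "n_hills": fes.provenance.get("n_hills", "")}
    if seed is not None:
        sets["seed"] = seed
    if config_hash is not None:
        sets["config_hash"] = config_hash
    lines = _header(fields, sets)
    nrows = 0
    if dim == 1:
        for x, v in zip(fes.axes[0], fes.values):
            lines.append(f"{_FMT % x} {_FMT % v}")
            nrows += 1
    else:
        for i, x in enumerate(fes.axes[0]):
            for y, v in zip(fes.axes[1], fes.values[i]):
                lines.append(f"{_FMT % x} {_FMT % y} {_FMT % v}")
                nrows += 1
            lines.append("")
    lines.append(f"#! SET nrows {nrows}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fes(path) -> FESGrid:
    fields, sets, rows = _parse_plumed(path)
    dim = len(fields) - 1
    data = np.array([[float(t) for t in toks] for _, toks in rows])
    if dim == 1:
        axes = [data[:, 0]]
        values = data[:, 1]
    else:
        ax0 = np.unique(data[:, 0])
        ax1 = np.unique(data[:, 1])
        values = data[:, 2].reshape(ax0.size, ax1.size)
        axes = [ax0, ax1]
    sym = str(sets.get("symmetrized", "False")) == "True"
    prov = {"symmetrized": sym}
    for key in ("gamma", "n_hills"):
        if sets.get(key):
            prov[key] = float(sets[key])
    values = values - values.min()
    return FESGrid(axes=axes, values=values, provenance=prov)


# ----------------------------------------------------------------------
# PDB structures + sidecar
# ----------------------------------------------------------------------

def write_structure(structures: Structure | Sequence[Structure], path,
                    sidecar: str | Path | None = None) -> None:
    """Write one structure (or a list, as MODEL blocks) to standard PDB.

    Charges, radii and site roles go to ``sidecar`` (TSV) — never into PDB
    columns.  Coordinates round-trip at PDB precision (0.001 A).
    """
    single = isinstance(structures, Structure)
    structs = [structures] if single else list(structures)
    pdb = PDBFile()
    arrays = []
    for s in structs:
        atoms = []
        for i in range(s.n_atoms):
            hetero = s.resnames[i] in ("HOH", "CLA")
            atoms.append(Atom(coord=s.xyz[i], chain_id="A", res_id=int(s.resids[i]),
                              res_name=s.resnames[i], atom_name=s.names[i],
                              element=s.elements[i].capitalize(), hetero=hetero))
        arr = atom_array_from_atoms(atoms)
        arr.set_annotation("atom_id", s.ids.astype(int))
        arrays.append(arr)
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        from biotite.structure import stack
        pdb.set_structure(stack(arrays))
    pdb.write(str(path))

    if sidecar is not None:
        s0 = structs[0]
        role_of: dict[int, list[str]] = {}
        for role, ids in s0.site_tags.items():
            for aid in ids:
                role_of.setdefault(aid, []).append(role)
        lines = ["# antiport sidecar: atom_id charge radius roles",
                 "atom_id\tcharge\tradius\troles"]
        for i, aid in enumerate(s0.ids.tolist()):
            roles = ",".join(role_of.get(aid, [])) or "-"
            lines.append(f"{aid}\t{_FMT % s0.charges[i]}\t{_FMT % s0.radii[i]}\t{roles}")
        Path(sidecar).write_text("\n".join(lines) + "\n")


def read_structure(path, sidecar: str | Path | None = None,
                   ) -> Structure | list[Structure]:
    """Read PDB (multi-MODEL becomes a list of snapshots).

    With a sidecar table, charges/radii/roles come from it; without one,
    tags are inferred from toy residue-name conventions (GLU carboxylates,
    CLA chlorides, HOH waters) and unknown residues load untagged with a
    warning.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    sidecar_data = _read_sidecar(sidecar) if sidecar is not None else None
    out = []
    for model in range(1, n_models + 1):
        arr = pdb.get_structure(model=model, extra_fields=["atom_id"])
        out.append(_structure_from_array(arr, sidecar_data, source=str(path)))
    return out[0] if n_models == 1 else out


def _read_sidecar(path):
    data = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("atom_id"):
            continue
        toks = line.split("\t") if "\t" in line else line.split()
        if len(toks) != 4:
            raise ValueError(f"{path}:{lineno}: sidecar rows need 4 columns")
        aid = int(toks[0])
        roles = [] if toks[3] == "-" else toks[3].split(",")
        data[aid] = (float(toks[1]), float(toks[2]), roles)
    return data


def _structure_from_array(arr, sidecar_data, source: str) -> Structure:
    n = arr.array_length()
    ids = np.asarray(arr.atom_id, dtype=int) if "atom_id" in arr.get_annotation_categories() \
        else np.arange(1, n + 1)
    elements = [str(e).upper() for e in arr.element]
    names = [str(a) for a in arr.atom_name]
    resnames = [str(r) for r in arr.res_name]
    resids = np.asarray(arr.res_id, dtype=int)
    xyz = np.asarray(arr.coord, dtype=float)

    charges = np.zeros(n)
    radii = np.array([_RADII.get(e, 1.5) for e in elements])
    tags: dict[str, list[int]] = {}
    if sidecar_data is not None:
        for i, aid in enumerate(ids.tolist()):
            if aid not in sidecar_data:
                raise ValueError(f"{source}: atom {aid} missing from sidecar table")
            q, r, roles = sidecar_data[aid]
            charges[i] = q
            radii[i] = r
            for role in roles:
                tags.setdefault(role, []).append(aid)
    else:
        _infer_tags(ids, elements, names, resnames, resids, charges, tags, source)

    protonated = {}
    states: dict[str, dict[str, dict[int, float]]] = {}
    for site in ("glu_int_carboxylate", "glu_ext_carboxylate"):
        if site not in tags:
            continue
        site_resids = {int(resids[np.nonzero(ids == aid)[0][0]]) for aid in tags[site]}
        prot_ids = [aid for aid in tags.get("titratable_proton", [])
                    if int(resids[np.nonzero(ids == aid)[0][0]]) in site_resids]
        protonated[site] = bool(prot_ids)
        by_name = {}
        for i, aid in enumerate(ids.tolist()):
            if int(resids[i]) in site_resids and names[i] in GLU_CHARGES["protonated"]:
                by_name[names[i]] = aid
        states[site] = {
            state: {by_name[nm]: q for nm, q in qs.items() if nm in by_name}
            for state, qs in GLU_CHARGES.items()}
    return Structure(ids=ids, elements=elements, names=names, resnames=resnames,
                     resids=resids, charges=charges, radii=radii, xyz=xyz,
                     site_tags=tags, protonated=protonated, site_charge_states=states)


def _infer_tags(ids, elements, names, resnames, resids, charges, tags, source) -> None:
    """Residue-name-convention fallback when no sidecar is given."""
    glu_resids = sorted({int(r) for r, rn in zip(resids, resnames) if rn == "GLU"})
    unknown = sorted({rn for rn in resnames if rn not in ("GLU", "HOH", "CLA", "TIP3", "WAT", "SOL")})
    if unknown:
        warnings.warn(
            f"{source}: unknown residue names {unknown} without a sidecar; "
            "those atoms are loaded untagged", stacklevel=3)
    n_cl = 0
    for i, aid in enumerate(ids.tolist()):
        rn, nm, el = resnames[i], names[i], elements[i]
        if rn == "GLU":
            role = None
            if nm in ("OE1", "OE2"):
                role = "glu_carboxylate"
            elif nm == "HE2":
                tags.setdefault("titratable_proton", []).append(aid)
                charges[i] = GLU_CHARGES["protonated"]["HE2"]
            if nm in GLU_CHARGES["protonated"]:
                charges[i] = GLU_CHARGES["protonated" if nm == "HE2" else "deprotonated"][nm]
            if role:
                tags.setdefault(role, []).append(aid)
        elif rn in ("HOH", "TIP3", "WAT", "SOL"):
            if el == "O":
                tags.setdefault("water_O", []).append(aid)
                charges[i] = -0.834
            elif el == "H":
                tags.setdefault("water_H", []).append(aid)
                charges[i] = 0.417
        elif rn == "CLA":
            n_cl += 1
            tags.setdefault(f"chloride_{n_cl}", []).append(aid)
            charges[i] = -1.0
    # split the generic carboxylate tag into int/ext by residue order
    if "glu_carboxylate" in tags and len(glu_resids) >= 2:
        car = tags.pop("glu_carboxylate")
        rid_int, rid_ext = glu_resids[0], glu_resids[-1]
        for aid in car:
            rid = int(resids[np.nonzero(ids == aid)[0][0]])
            key = "glu_int_carboxylate" if rid == rid_int else "glu_ext_carboxylate"
            tags.setdefault(key, []).append(aid)
    elif "glu_carboxylate" in tags:
        tags["glu_ext_carboxylate"] = tags.pop("glu_carboxylate")
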