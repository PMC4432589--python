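"""Domain types and PDB coordinate I/O shared by all analysis stages.

The model is deliberately small: an :class:`Atom` is a plain record, a
:class:`Structure` is an ordered atom list for one model, and an
:class:`AtomSelection` is a declarative filter that resolves to an ordered
coordinate set.  Multi-model PDB files are the trajectory interchange
format (:class:`Trajectory`).

Parsing is backed by :mod:`biotite`; writing uses the fixed-column PDB
layout directly so that round trips preserve our atom ordering exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Structure",
    "AtomSelection",
    "ResolvedSelection",
    "Trajectory",
    "PDBFormatError",
    "SelectionError",
    "read_pdb",
    "read_multimodel",
    "write_pdb",
    "write_multimodel",
    "resolve",
]

#: Main-chain (backbone) heavy-atom names.
MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class PDBFormatError(ValueError):
    """Raised for unreadable or internally inconsistent coordinate files."""


class SelectionError(ValueError):
    """Raised when a selection resolves to too few atoms."""


@dataclass(frozen=True)
class Atom:
    """One heavy (or hydrogen) atom of a coordinate model.

    ``res_seq`` is the author residue number as deposited; insertion codes
    are kept as part of the residue identity but ranges compare by the
    integer only.
    """

    chain_id: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    coord: tuple[float, float, float]
    b_factor: float = 0.0
    occupancy: float = 1.0
    alt_loc: str = ""
    ins_code: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")
        if not all(math.isfinite(c) for c in self.coord):
            raise ValueError(f"non-finite coordinate for atom {self.key}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key: (chain, residue number, insertion code, atom name)."""
        return (self.chain_id, self.res_seq, self.ins_code, self.atom_name)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.ins_code)

    @property
    def is_water(self) -> bool:
        return self.res_name in ("HOH", "WAT", "DOD")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_main_chain(self) -> bool:
        return not self.hetero and self.atom_name in MAIN_CHAIN_ATOMS


@dataclass
class Structure:
    """An ordered collection of atoms forming one coordinate model."""

    atoms: list[Atom]
    model_id: int = 1
    title: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Å."""
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with coordinates replaced row-for-row."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        new_atoms = [
            replace(a, coord=(float(c[0]), float(c[1]), float(c[2])))
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(new_atoms, model_id=self.model_id, title=self.title)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply ``x -> R x + t`` to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return self.with_coords(self.coords @ R.T + t)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique residue keys in atom order."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)


@dataclass(frozen=True)
class AtomSelection:
    """Declarative atom filter.

    ``chains``/``atom_names`` may be the string ``"all"``; an empty
    ``ranges`` tuple means "all residue numbers".  ``res_names`` is an
    optional residue-name whitelist — waters and ligands are only included
    in geometric operations when named explicitly (``res_names={"NO3"}``).
    """

    chains: frozenset[str] | str = "all"
    ranges: tuple[tuple[int, int], ...] = ()
    atom_names: frozenset[str] | str = "all"
    res_names: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for start, end in self.ranges:
            if start > end:
                raise ValueError(f"invalid residue range ({start}, {end})")

    @staticmethod
    def make(
        chains: Iterable[str] | str = "all",
        ranges: Iterable[tuple[int, int]] = (),
        atom_names: Iterable[str] | str = "all",
        res_names: Iterable[str] | None = None,
    ) -> "AtomSelection":
        return AtomSelection(
            chains if chains == "all" else frozenset(chains),
            tuple((int(a), int(b)) for a, b in ranges),
            atom_names if atom_names == "all" else frozenset(atom_names),
            None if res_names is None else frozenset(res_names),
        )

    @staticmethod
    def ca(ranges: Iterable[tuple[int, int]] = (), chains="all") -> "AtomSelection":
        """Shorthand for a Cα selection over the given residue ranges."""
        return AtomSelection.make(chains=chains, ranges=ranges, atom_names={"CA"})

    def matches(self, atom: Atom) -> bool:
        if self.chains != "all" and atom.chain_id not in self.chains:
            return False
        if self.ranges and not any(a <= atom.res_seq <= b for a, b in self.ranges):
            return False
        if self.atom_names != "all" and atom.atom_name not in self.atom_names:
            return False
        if self.res_names is not None and atom.res_name not in self.res_names:
            return False
        # Waters and hydrogens only enter a selection when asked for by name.
        if self.res_names is None and atom.is_water:
            return False
        if atom.is_hydrogen:
            return False
        return True


@dataclass
class ResolvedSelection:
    """Result of resolving an :class:`AtomSelection` against a structure."""

    atoms: list[Atom]
    n_skipped_residues: int

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def keys(self) -> list[tuple[str, int, str, str]]:
        return [a.key for a in self.atoms]

    def __len__(self) -> int:
        return len(self.atoms)


def resolve(sel: AtomSelection, s: Structure) -> ResolvedSelection:
    """Resolve a selection to atoms in ascending (chain, res_seq, atom) order.

    Residue numbers requested by ``sel.ranges`` but absent from the model
    (disordered loops) are skipped silently; their count is reported in
    ``n_skipped_residues``.

    Raises
    ------
    SelectionError
        If no atom matches.
    """
    hits = [a for a in s.atoms if sel.matches(a)]
    if not hits:
        raise SelectionError(f"selection {sel} resolves to zero atoms")
    hits.sort(key=lambda a: (a.chain_id, a.res_seq, a.ins_code, a.atom_name))

    n_skipped = 0
    if sel.ranges:
        chains = s.chains() if sel.chains == "all" else sorted(sel.chains)
        present: dict[str, set[int]] = {c: set() for c in chains}
        for a in s.atoms:
            if a.chain_id in present and not a.is_water:
                present[a.chain_id].add(a.res_seq)
        for c in chains:
            if not present[c]:
                continue  # chain entirely absent: not counted as skipped residues
            for start, end in sel.ranges:
                n_skipped += sum(
                    1 for r in range(start, end + 1) if r not in present[c]
                )
    return ResolvedSelection(hits, n_skipped)


@dataclass
class Trajectory:
    """Ordered coordinate frames over one shared atom topology."""

    topology: Structure
    frames: list[np.ndarray]
    frame_times: list[float] | None = None

    def __post_init__(self) -> None:
        n = len(self.topology)
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {i} has shape {f.shape}, expected ({n}, 3)"
                )
            self.frames[i] = f
        if self.frame_times is not None:
            if len(self.frame_times) != len(self.frames):
                raise ValueError("frame_times length does not match frame count")
            if any(b <= a for a, b in zip(self.frame_times, self.frame_times[1:])):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def times(self) -> np.ndarray:
        if self.frame_times is not None:
            return np.asarray(self.frame_times, dtype=float)
        return np.arange(self.n_frames, dtype=float)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def _atoms_from_array(arr) -> list[Atom]:
    occ = (
        arr.occupancy
        if "occupancy" in arr.get_annotation_categories()
        else np.ones(arr.array_length())
    )
    bfac = (
        arr.b_factor
        if "b_factor" in arr.get_annotation_categories()
        else np.zeros(arr.array_length())
    )
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            Atom(
                chain_id=str(arr.chain_id[i]),
                res_seq=int(arr.res_id[i]),
                res_name=str(arr.res_name[i]),
                atom_name=str(arr.atom_name[i]),
                element=str(arr.element[i]).upper(),
                coord=tuple(float(x) for x in arr.coord[i]),
                b_factor=float(bfac[i]),
                occupancy=float(min(max(occ[i], 0.0), 1.0)),
                alt_loc="",
                ins_code=str(arr.ins_code[i]),
                hetero=bool(arr.hetero[i]),
            )
        )
    return atoms


def _read_pdbfile(path: str | Path) -> PDBFile:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - biotite error path
        raise PDBFormatError(f"{path}: {exc}") from exc
    return pdb


def _get_model(pdb: PDBFile, path, model: int):
    try:
        return pdb.get_structure(
            model=model, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
        )
    except Exception as exc:
        raise PDBFormatError(f"{path}: cannot read model {model}: {exc}") from exc


def read_pdb(path: str | Path, model: int | str = "first") -> Structure:
    """Read one model of a PDB file.

    Alt-locs are resolved to the highest-occupancy conformer.  HETATM
    ligand and water records (NO3, HOH, ...) are retained with their
    residue codes.

    Parameters
    ----------
    path:
        PDB file path.
    model:
        1-based model number, or ``"first"``.
    """
    pdb = _read_pdbfile(path)
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    model_no = 1 if model == "first" else int(model)
    if not 1 <= model_no <= n_models:
        raise PDBFormatError(
            f"{path}: requested model {model_no}, file has {n_models}"
        )
    arr = _get_model(pdb, path, model_no)
    return Structure(_atoms_from_array(arr), model_id=model_no)


def read_multimodel(path: str | Path) -> Trajectory:
    """Read a multi-model PDB file as a trajectory (one frame per MODEL).

    All models must share one atom roster in one order; the first
    mismatching model is named in the error.
    """
    pdb = _read_pdbfile(path)
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    topo_arr = _get_model(pdb, path, 1)
    topology = Structure(_atoms_from_array(topo_arr), model_id=1)
    ref_keys = [a.key for a in topology.atoms]
    frames = [topology.coords]
    for m in range(2, n_models + 1):
        arr = _get_model(pdb, path, m)
        atoms = _atoms_from_array(arr)
        if len(atoms) != len(ref_keys):
            raise PDBFormatError(
                f"{path}: model {m} has {len(atoms)} atoms, "
                f"model 1 has {len(ref_keys)}"
            )
        keys = [a.key for a in atoms]
        if keys != ref_keys:
            raise PDBFormatError(
                f"{path}: model {m} atom roster differs from model 1"
            )
        frames.append(np.array([a.coord for a in atoms], dtype=float))
    return Trajectory(topology, frames)


def _format_atom_line(a: Atom, serial: int) -> str:
    record = "HETATM" if a.hetero else "ATOM  "
    name = a.atom_name
    # PDB column convention: 1/2-char element names start in column 14.
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    x, y, z = a.coord
    return (
        f"{record}{serial:>5d} {name:<4s}{a.alt_loc or ' ':1s}"
        f"{a.res_name:>3s} {a.chain_id:1s}{a.res_seq:>4d}{a.ins_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
        f"          {a.element:>2s}"
    )


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a single-model structure in fixed-column PDB format."""
    lines = []
    if s.title:
        lines.append(f"TITLE     {s.title}")
    for i, a in enumerate(s.atoms, start=1):
        lines.append(_format_atom_line(a, min(i, 99999)))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_multimodel(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    lines = []
    for m, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {m:>4d}")
        for i, (a, c) in enumerate(zip(traj.topology.atoms, frame), start=1):
            atom = replace(a, coord=(float(c[0]), float(c[1]), float(c[2])))
            lines.append(_format_atom_line(atom, min(i, 99999)))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
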