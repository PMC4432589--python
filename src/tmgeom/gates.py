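"""Cytoplasmic gate-layer contact inventories and open/closed classification.

Contacts are detected on heavy atoms only (the crystal structures carry no
hydrogens), with distance-only criteria: hydrophobic/van-der-Waals contact
at 4.5 Å, hydrogen bond (donor N/O/S to acceptor N/O) at 3.5 Å, and
water bridges requiring both water-to-group legs within 3.5 Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .report import AnalysisReport
from .structure import Atom, SelectionError, Structure

__all__ = [
    "ResidueSpec",
    "ContactSpec",
    "ContactHit",
    "find_contacts",
    "find_hbonds",
    "find_water_bridges",
    "gate_state",
    "GateVerdict",
    "HYDROPHOBIC_CUTOFF",
    "HBOND_CUTOFF",
    "WATER_BRIDGE_CUTOFF",
]

HYDROPHOBIC_CUTOFF = 4.5
HBOND_CUTOFF = 3.5
WATER_BRIDGE_CUTOFF = 3.5

DONOR_ELEMENTS = frozenset({"N", "O", "S"})
ACCEPTOR_ELEMENTS = frozenset({"N", "O"})

Scope = Literal["side-chain", "main-chain", "any"]


@dataclass(frozen=True)
class ResidueSpec:
    """One residue of a contact group, with an atom scope."""

    res_seq: int
    scope: Scope = "any"
    chain: str | None = None

    def matches(self, atom: Atom) -> bool:
        if atom.res_seq != self.res_seq:
            return False
        if self.chain is not None and atom.chain_id != self.chain:
            return False
        if atom.is_hydrogen or atom.is_water:
            return False
        if self.scope == "main-chain":
            return atom.is_main_chain
        if self.scope == "side-chain":
            return not atom.is_main_chain
        return True


@dataclass(frozen=True)
class ContactSpec:
    """One named inter-bundle interaction of a gate layer."""

    layer: str
    group_n: tuple[ResidueSpec, ...]
    group_c: tuple[ResidueSpec, ...]
    kind: Literal["hydrophobic", "hbond", "water_bridge"]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.group_n or not self.group_c:
            raise ValueError(f"{self.layer}: contact groups must be nonempty")
        if self.kind not in ("hydrophobic", "hbond", "water_bridge"):
            raise ValueError(f"unknown contact kind {self.kind!r}")


@dataclass
class ContactHit:
    spec: ContactSpec | None
    atom_a: tuple[str, int, str, str]
    atom_b: tuple[str, int, str, str]
    distance: float
    water_key: tuple[str, int, str] | None = None


def _group_atoms(s: Structure, group: Sequence[ResidueSpec]) -> list[Atom]:
    atoms = [a for a in s.atoms if any(spec.matches(a) for spec in group)]
    return atoms


def _pair_hits(
    atoms_a: list[Atom],
    atoms_b: list[Atom],
    cutoff: float,
    spec: ContactSpec | None = None,
) -> list[ContactHit]:
    if not atoms_a or not atoms_b:
        return []
    xa = np.array([a.coord for a in atoms_a], dtype=float)
    xb = np.array([b.coord for b in atoms_b], dtype=float)
    tree = cKDTree(xb)
    hits: list[ContactHit] = []
    for i, neighbours in enumerate(tree.query_ball_point(xa, cutoff)):
        for j in sorted(neighbours):
            d = float(np.linalg.norm(xa[i] - xb[j]))
            hits.append(ContactHit(spec, atoms_a[i].key, atoms_b[j].key, d))
    hits.sort(key=lambda h: (h.atom_a, h.atom_b))
    return hits


def find_contacts(
    s: Structure,
    group_a: Sequence[ResidueSpec],
    group_b: Sequence[ResidueSpec],
    cutoff: float = HYDROPHOBIC_CUTOFF,
) -> list[ContactHit]:
    """All heavy-atom pairs (one atom per group) within ``cutoff`` Å."""
    atoms_a = _group_atoms(s, group_a)
    atoms_b = _group_atoms(s, group_b)
    if not atoms_a or not atoms_b:
        raise SelectionError("contact group resolves to zero atoms")
    return _pair_hits(atoms_a, atoms_b, cutoff)


def find_hbonds(
    s: Structure,
    donors: Sequence[ResidueSpec],
    acceptors: Sequence[ResidueSpec],
    d_max: float = HBOND_CUTOFF,
) -> list[ContactHit]:
    """Donor–acceptor heavy-atom pairs within ``d_max`` Å.

    Hydrogen positions are unavailable, so the criterion is purely
    distance between H-bond-capable heavy atoms (N/O/S donor side,
    N/O acceptor side); no angular term is applied.
    """
    atoms_d = [a for a in _group_atoms(s, donors) if a.element in DONOR_ELEMENTS]
    atoms_a = [a for a in _group_atoms(s, acceptors) if a.element in ACCEPTOR_ELEMENTS]
    if not atoms_d or not atoms_a:
        raise SelectionError("H-bond group resolves to zero capable atoms")
    return _pair_hits(atoms_d, atoms_a, d_max)


def find_water_bridges(
    s: Structure,
    group_a: Sequence[ResidueSpec],
    group_b: Sequence[ResidueSpec],
    d_max: float = WATER_BRIDGE_CUTOFF,
) -> list[ContactHit]:
    """Waters bridging the two groups: both legs within ``d_max`` Å.

    One hit is emitted per (water, closest pairing); a structure without
    waters yields an empty list.
    """
    waters = [a for a in s.atoms if a.is_water and a.element == "O"]
    if not waters:
        return []
    atoms_a = [a for a in _group_atoms(s, group_a) if a.element in DONOR_ELEMENTS]
    atoms_b = [b for b in _group_atoms(s, group_b) if b.element in DONOR_ELEMENTS]
    hits: list[ContactHit] = []
    for w in waters:
        wc = np.array(w.coord)
        da = [
            (float(np.linalg.norm(wc - np.array(a.coord))), a)
            for a in atoms_a
        ]
        db = [
            (float(np.linalg.norm(wc - np.array(b.coord))), b)
            for b in atoms_b
        ]
        da = [t for t in da if t[0] <= d_max]
        db = [t for t in db if t[0] <= d_max]
        if da and db:
            best_a = min(da)
            best_b = min(db)
            hits.append(
                ContactHit(
                    None,
                    best_a[1].key,
                    best_b[1].key,
                    best_a[0] + best_b[0],
                    water_key=w.residue_key,
                )
            )
    return hits


_DETECTORS = {
    "hydrophobic": (find_contacts, HYDROPHOBIC_CUTOFF),
    "hbond": (find_hbonds, HBOND_CUTOFF),
    "water_bridge": (find_water_bridges, WATER_BRIDGE_CUTOFF),
}


@dataclass
class GateVerdict:
    state: Literal["closed", "open"]
    layers_formed: dict[str, bool]
    report: AnalysisReport


def gate_state(
    s: Structure,
    layer_specs: Sequence[ContactSpec],
    formed_fraction: float = 0.5,
) -> GateVerdict:
    """Classify the cytoplasmic gate as closed or open.

    A layer counts as *formed* when at least ``formed_fraction`` of its
    specified interactions produce at least one hit; the gate is *closed*
    only when every layer is formed.  Interactions whose residues are
    absent from the model are flagged ``unresolved`` and count as misses.
    """
    if not layer_specs:
        raise ValueError("layer_specs must be nonempty")
    report = AnalysisReport(name="gate_layers")
    per_layer: dict[str, list[bool]] = {}
    for spec in layer_specs:
        detector, cutoff = _DETECTORS[spec.kind]
        label = spec.label or f"{spec.kind}"
        try:
            hits = detector(s, spec.group_n, spec.group_c, cutoff)
        except SelectionError:
            per_layer.setdefault(spec.layer, []).append(False)
            report.add(
                name=f"{spec.layer}:{label}", value=0, units="hits",
                kind=spec.kind, status="unresolved",
            )
            continue
        formed = len(hits) > 0
        per_layer.setdefault(spec.layer, []).append(formed)
        report.add(
            name=f"{spec.layer}:{label}",
            value=len(hits),
            units="hits",
            kind=spec.kind,
            min_distance=min((h.distance for h in hits), default=float("nan")),
            status="ok",
        )
    layers_formed = {
        layer: (sum(flags) >= formed_fraction * len(flags))
        for layer, flags in per_layer.items()
    }
    state = "closed" if all(layers_formed.values()) else "open"
    for layer, formed in layers_formed.items():
        report.add(name=f"{layer}:formed", value=bool(formed), units="")
    report.add(name="gate_state", value=state, units="")
    return GateVerdict(state, layers_formed, report)
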