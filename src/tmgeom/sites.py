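"""Substrate-binding-site geometry and grid flood-fill pocket volume.

Covers: the bidentate arginine salt bridge (site A), the tyrosine-hydroxyl
network with its arginine/serine partners (site B), the asparagine amide
contact (site C), the aromatic sandwich around the ligand, and the
probe-accessible cavity volume measured by flood-filling a cubic grid from
a seed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .report import AnalysisReport
from .structure import AtomSelection, SelectionError, Structure, resolve

__all__ = [
    "SiteResidues",
    "SiteGeometry",
    "PocketResult",
    "site_geometry",
    "ring_geometry",
    "pocket_volume",
    "site_compare",
    "VDW_RADII",
]

#: van der Waals radii (Å) used as the occluding-sphere radii.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_VDW = 1.70

PHE_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


@dataclass(frozen=True)
class SiteResidues:
    """Author residue numbers of the recognition-site residues."""

    arg_saltbridge: int = 89     # bidentate guanidinium (site A)
    tyr_hydroxyl: int = 263      # phenol OH (site B)
    arg_network: int = 305       # guanidinium partner of the tyrosine
    ser_network: int = 366       # hydroxyl partner of the network arginine
    asn_amide: int = 175         # side-chain amide (site C)
    phe_sandwich: tuple[int, int] = (147, 267)


@dataclass
class SiteGeometry:
    """Distances (Å) and sandwich geometry of one structure's binding site.

    Ligand-dependent fields are ``None`` for apo structures; the
    protein-internal network distances are always populated when the
    residues resolve.
    """

    site_a_nh1: float | None = None
    site_a_nh2: float | None = None
    site_a_min: float | None = None
    site_b_min: float | None = None
    site_c: float | None = None
    site_b_network_tyr_arg: float | None = None
    site_b_network_arg_ser: float | None = None
    sandwich: dict[str, tuple[float, float]] = field(default_factory=dict)
    ligand_res_name: str | None = None


def _atom_coords(s: Structure, res_seq: int, atom_names, chain: str | None = None):
    out = []
    for a in s.atoms:
        if a.res_seq != res_seq or a.is_hydrogen:
            continue
        if chain is not None and a.chain_id != chain:
            continue
        if a.atom_name in atom_names:
            out.append(np.array(a.coord))
    return out


def _min_dist(points_a, points_b) -> float | None:
    if not points_a or not points_b:
        return None
    return min(
        float(np.linalg.norm(p - q)) for p in points_a for q in points_b
    )


def site_geometry(
    s: Structure,
    ligand_sel: AtomSelection | None = None,
    residues: SiteResidues = SiteResidues(),
    chain: str | None = None,
) -> SiteGeometry:
    """Measure the recognition-site distances of one structure.

    ``ligand_sel`` should resolve to a single planar anion (NO3/NO2); pass
    ``None`` (or a selection that fails to resolve) for apo structures, in
    which case only the protein-internal network distances are reported.
    """
    geo = SiteGeometry()

    ligand_o: list[np.ndarray] = []
    ligand_all: list[np.ndarray] = []
    if ligand_sel is not None:
        try:
            res = resolve(ligand_sel, s)
        except SelectionError:
            res = None
        if res is not None:
            lig_residues = {a.residue_key for a in res.atoms}
            if len(lig_residues) != 1:
                raise ValueError(
                    f"ligand selection resolves {len(lig_residues)} residues, need 1"
                )
            geo.ligand_res_name = res.atoms[0].res_name
            ligand_all = [np.array(a.coord) for a in res.atoms]
            ligand_o = [np.array(a.coord) for a in res.atoms if a.element == "O"]

    nh1 = _atom_coords(s, residues.arg_saltbridge, {"NH1"}, chain)
    nh2 = _atom_coords(s, residues.arg_saltbridge, {"NH2"}, chain)
    oh = _atom_coords(s, residues.tyr_hydroxyl, {"OH"}, chain)
    guan = _atom_coords(s, residues.arg_network, {"NH1", "NH2", "NE"}, chain)
    og = _atom_coords(s, residues.ser_network, {"OG"}, chain)
    amide = _atom_coords(s, residues.asn_amide, {"ND2", "OD1"}, chain)

    if ligand_o:
        geo.site_a_nh1 = _min_dist(nh1, ligand_o)
        geo.site_a_nh2 = _min_dist(nh2, ligand_o)
        candidates = [d for d in (geo.site_a_nh1, geo.site_a_nh2) if d is not None]
        geo.site_a_min = min(candidates) if candidates else None
        geo.site_b_min = _min_dist(oh, ligand_o)
        geo.site_c = _min_dist(amide, ligand_o)

    geo.site_b_network_tyr_arg = _min_dist(oh, guan)
    geo.site_b_network_arg_ser = _min_dist(guan, og)

    if ligand_all:
        lig = np.array(ligand_all)
        for phe in residues.phe_sandwich:
            ring = _atom_coords(s, phe, set(PHE_RING_ATOMS), chain)
            if len(ring) == len(PHE_RING_ATOMS):
                dist, angle = ring_geometry(np.array(ring), lig)
                geo.sandwich[f"F{phe}"] = (dist, angle)
    return geo


def _plane_normal(points: np.ndarray) -> np.ndarray:
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return vt[-1]


def ring_geometry(ring: np.ndarray, ligand: np.ndarray) -> tuple[float, float]:
    """Centroid distance (Å) and interplanar angle (deg, folded to [0, 90]).

    ``ring`` must contain the six aromatic carbons; ``ligand`` at least
    three atoms of a planar group.
    """
    ring = np.asarray(ring, dtype=float)
    ligand = np.asarray(ligand, dtype=float)
    if ring.shape[0] != 6:
        raise ValueError(f"ring must have 6 atoms, got {ring.shape[0]}")
    if ligand.shape[0] < 3:
        raise ValueError("ligand plane needs >= 3 atoms")
    dist = float(np.linalg.norm(ring.mean(axis=0) - ligand.mean(axis=0)))
    n1 = _plane_normal(ring)
    n2 = _plane_normal(ligand)
    cosang = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    return dist, float(np.degrees(np.arccos(cosang)))


@dataclass
class PocketResult:
    volume: float
    grid_spacing: float
    probe_radius: float
    n_grid_points: int
    seed_point: np.ndarray
    open_pocket: bool = False


def pocket_volume(
    s: Structure,
    seed: np.ndarray,
    spacing: float = 0.25,
    probe: float = 1.4,
    half_width: float = 6.0,
    exclude_res_names: frozenset[str] = frozenset({"NO3", "NO2", "HOH", "WAT"}),
) -> PocketResult:
    """Probe-accessible cavity volume by grid flood-fill from a seed point.

    A cubic grid of ``spacing`` Å within ``±half_width`` of the seed is
    marked blocked wherever a point lies within (vdW radius + ``probe``) of
    any protein heavy atom; ligand and water residues named in
    ``exclude_res_names`` do not occlude.  The connected free component
    containing the seed (6-connectivity) is counted:
    ``volume = n_points × spacing³``.  A fill that reaches the box boundary
    is flagged ``open_pocket`` and the truncated volume returned.
    """
    seed = np.asarray(seed, dtype=float)
    atoms = [
        a
        for a in s.atoms
        if not a.is_hydrogen and a.res_name not in exclude_res_names
    ]
    if not atoms:
        raise SelectionError("structure has no occluding atoms")
    coords = np.array([a.coord for a in atoms], dtype=float)
    radii = np.array(
        [VDW_RADII.get(a.element, DEFAULT_VDW) + probe for a in atoms], dtype=float
    )
    d_seed = np.linalg.norm(coords - seed, axis=1)
    inside = d_seed < radii
    if inside.any():
        i = int(np.argmin(d_seed - radii))
        raise ValueError(
            f"seed point lies inside the sphere of atom {atoms[i].key} "
            f"(distance {d_seed[i]:.2f} Å < {radii[i]:.2f} Å)"
        )

    n_side = int(round(2 * half_width / spacing)) + 1
    axes = [seed[k] - half_width + spacing * np.arange(n_side) for k in range(3)]
    blocked = np.zeros((n_side,) * 3, dtype=bool)

    r_max = radii.max()
    lo = seed - half_width
    for c, r in zip(coords, radii):
        # subgrid bounding box of this atom's sphere
        i0 = np.maximum(np.floor((c - r - lo) / spacing).astype(int), 0)
        i1 = np.minimum(np.ceil((c + r - lo) / spacing).astype(int) + 1, n_side)
        if np.any(i0 >= i1):
            continue
        gx = axes[0][i0[0]:i1[0]]
        gy = axes[1][i0[1]:i1[1]]
        gz = axes[2][i0[2]:i1[2]]
        dx2 = (gx - c[0])[:, None, None] ** 2
        dy2 = (gy - c[1])[None, :, None] ** 2
        dz2 = (gz - c[2])[None, None, :] ** 2
        blocked[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= (
            dx2 + dy2 + dz2 <= r * r
        )

    free = ~blocked
    labels, _ = ndimage.label(free, structure=ndimage.generate_binary_structure(3, 1))
    seed_idx = tuple(int(round((seed[k] - lo[k]) / spacing)) for k in range(3))
    seed_label = labels[seed_idx]
    if seed_label == 0:  # numerically on a blocked point; should not happen
        raise ValueError("seed grid point is blocked")
    component = labels == seed_label
    n_points = int(component.sum())
    open_pocket = bool(
        component[0, :, :].any() or component[-1, :, :].any()
        or component[:, 0, :].any() or component[:, -1, :].any()
        or component[:, :, 0].any() or component[:, :, -1].any()
    )
    return PocketResult(
        volume=n_points * spacing**3,
        grid_spacing=spacing,
        probe_radius=probe,
        n_grid_points=n_points,
        seed_point=seed,
        open_pocket=open_pocket,
    )


def _add_geometry_rows(report: AnalysisReport, prefix: str, geo: SiteGeometry) -> None:
    pairs = [
        ("site_a_nh1", geo.site_a_nh1),
        ("site_a_nh2", geo.site_a_nh2),
        ("site_a_min", geo.site_a_min),
        ("site_b_min", geo.site_b_min),
        ("site_c", geo.site_c),
        ("site_b_network_tyr_arg", geo.site_b_network_tyr_arg),
        ("site_b_network_arg_ser", geo.site_b_network_arg_ser),
    ]
    for key, value in pairs:
        report.add(
            name=f"{prefix}:{key}",
            value=float("nan") if value is None else value,
            units="Å",
            status="ok" if value is not None else "no_ligand",
        )
    for phe, (dist, angle) in geo.sandwich.items():
        report.add(name=f"{prefix}:sandwich_{phe}_dist", value=dist, units="Å")
        report.add(name=f"{prefix}:sandwich_{phe}_angle", value=angle, units="deg")


def site_compare(
    occluded: Structure,
    inward: Structure,
    ligand_sel: AtomSelection | None = None,
    residues: SiteResidues = SiteResidues(),
    pocket: bool = True,
    spacing: float = 0.25,
    probe: float = 1.4,
) -> AnalysisReport:
    """Tabulate site geometry (and optionally pocket volume) for two states.

    The pocket is seeded at the ligand centroid of each structure; states
    without a resolvable ligand get geometry rows only.
    """
    report = AnalysisReport(name="site_compare")
    geos = {}
    for prefix, struct in (("occluded", occluded), ("inward_open", inward)):
        geo = site_geometry(struct, ligand_sel, residues)
        geos[prefix] = geo
        _add_geometry_rows(report, prefix, geo)
        if pocket and ligand_sel is not None and geo.ligand_res_name is not None:
            lig = resolve(ligand_sel, struct)
            seed = lig.coords.mean(axis=0)
            try:
                pr = pocket_volume(struct, seed, spacing=spacing, probe=probe)
            except (ValueError, SelectionError) as exc:
                report.add(name=f"{prefix}:pocket_volume", value=float("nan"),
                           units="Å³", status=f"failed: {exc}")
            else:
                report.add(
                    name=f"{prefix}:pocket_volume", value=pr.volume, units="Å³",
                    status="open_pocket" if pr.open_pocket else "ok",
                )
    for key in ("site_a_min", "site_b_min"):
        a = getattr(geos["occluded"], key)
        b = getattr(geos["inward_open"], key)
        if a is not None and b is not None:
            report.add(name=f"delta:{key}", value=b - a, units="Å")
    return report
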