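"""Synthetic-structure generators with known ground truth.

Every analysis stage in this package is validated against fixtures built
here: ideal and hinge-bent helices with planted bend angles, two-bundle
toys with exact centroid separations, enclosed cavities of analytic
volume, interpolation trajectories with Gaussian noise of known σ, and
verbatim-placed interaction sites.  Generators are deterministic under a
fixed seed and emit regular :class:`~tmgeom.structure.Structure` objects,
so fixtures can exercise the real PDB I/O path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, AtomSelection, Structure, Trajectory, resolve

__all__ = [
    "HelixSpec",
    "TrajectorySpec",
    "make_helix",
    "make_two_bundle",
    "make_cavity",
    "make_trajectory",
    "plant_site",
]

# cylindrical placement (radius Å, phase deg, z-offset Å) per backbone atom,
# relative to the Cα of the same residue — geometric, not physical
_BACKBONE = {
    "N": ("N", 1.46, -28.0, -0.90),
    "CA": ("C", 2.30, 0.0, 0.00),
    "C": ("C", 1.64, 21.0, 0.55),
    "O": ("O", 2.00, 38.0, 0.65),
    "CB": ("C", 3.30, -8.0, -0.25),
}


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)


def _align_z_to(axis: np.ndarray) -> np.ndarray:
    """Rotation taking +z onto the given direction."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    s = np.linalg.norm(v)
    c = float(np.dot(z, axis))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    return _rotation_about(v / s, math.degrees(math.atan2(s, c)))


@dataclass(frozen=True)
class HelixSpec:
    """Parameters of an ideal (optionally hinge-bent) α-helix fixture."""

    n_res: int = 20
    rise_per_res: float = 1.5
    twist_per_res: float = 100.0
    ca_radius: float = 2.3
    bend_angle: float = 0.0
    hinge_index: int | None = None
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0
    noise_sigma: float = 0.0
    start_res: int = 1
    chain_id: str = "A"
    with_backbone: bool = True
    res_name: str = "ALA"

    def __post_init__(self) -> None:
        if not 0.0 <= self.bend_angle <= 90.0:
            raise ValueError("bend_angle must be in [0, 90]")
        if self.bend_angle > 0 and self.hinge_index is None:
            raise ValueError("a bend requires hinge_index")
        if self.hinge_index is not None and self.n_res < 8:
            raise ValueError("n_res must be >= 8 when a hinge is requested")


def make_helix(spec: HelixSpec) -> Structure:
    """Generate a helix along ``spec.axis``.

    When ``bend_angle > 0``, every residue beyond ``hinge_index`` (0-based
    position in the helix) is rotated rigidly by that angle about an axis
    through the hinge Cα perpendicular to the helix axis — so the planted
    angle is recoverable exactly by axis fitting on the two halves.
    """
    atom_names = list(_BACKBONE) if spec.with_backbone else ["CA"]
    coords = []
    meta = []
    for i in range(spec.n_res):
        phi0 = math.radians(spec.twist_per_res * i)
        z0 = spec.rise_per_res * i
        for name in atom_names:
            element, radius, phase, dz = _BACKBONE[name]
            if name == "CA":
                radius = spec.ca_radius
            phi = phi0 + math.radians(phase)
            coords.append(
                [radius * math.cos(phi), radius * math.sin(phi), z0 + dz]
            )
            meta.append((i, name, element))
    coords = np.array(coords)

    if spec.bend_angle > 0:
        hinge_ca = coords[
            [k for k, (i, n, _) in enumerate(meta) if i == spec.hinge_index and n == "CA"][0]
        ].copy()
        rot = _rotation_about(np.array([1.0, 0.0, 0.0]), spec.bend_angle)
        moving = np.array([i > spec.hinge_index for i, _, _ in meta])
        coords[moving] = (coords[moving] - hinge_ca) @ rot.T + hinge_ca

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)

    coords = coords @ _align_z_to(np.array(spec.axis)).T

    atoms = [
        Atom(
            chain_id=spec.chain_id,
            res_seq=spec.start_res + i,
            res_name=spec.res_name,
            atom_name=name,
            element=element,
            coord=tuple(float(x) for x in c),
        )
        for (i, name, element), c in zip(meta, coords)
    ]
    return Structure(atoms, title=f"synthetic helix n={spec.n_res}")


def make_two_bundle(
    separation: float,
    n_helices_per_bundle: int = 3,
    seed: int = 0,
    n_res: int = 20,
) -> tuple[Structure, AtomSelection, AtomSelection]:
    """Two toy helix bundles with an exact Cα-centroid separation.

    Returns ``(structure, sel_a, sel_b)`` where the Cα centroids of the
    two selections are exactly ``separation`` Å apart (bundle B is
    translated along +x to realize the distance to machine precision).
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if n_helices_per_bundle < 1:
        raise ValueError("need at least one helix per bundle")
    rng = np.random.default_rng(seed)

    def build_bundle(chain_id: str, start_res: int) -> list[Atom]:
        atoms: list[Atom] = []
        for h in range(n_helices_per_bundle):
            angle = 2 * math.pi * h / n_helices_per_bundle
            offset = np.array([6.0 * math.cos(angle), 6.0 * math.sin(angle), 0.0])
            offset += rng.normal(0.0, 0.3, 3)  # break exact symmetry
            helix = make_helix(
                HelixSpec(
                    n_res=n_res,
                    start_res=start_res + h * (n_res + 5),
                    chain_id=chain_id,
                    with_backbone=False,
                    seed=seed + h,
                )
            )
            for a in helix.atoms:
                c = np.array(a.coord) + offset
                atoms.append(
                    Atom(
                        chain_id=a.chain_id,
                        res_seq=a.res_seq,
                        res_name=a.res_name,
                        atom_name=a.atom_name,
                        element=a.element,
                        coord=tuple(float(x) for x in c),
                    )
                )
        return atoms

    span = n_helices_per_bundle * (n_res + 5)
    atoms_a = build_bundle("A", 1)
    atoms_b = build_bundle("B", 1001)
    sel_a = AtomSelection.ca(ranges=[(1, span)], chains={"A"})
    sel_b = AtomSelection.ca(ranges=[(1001, 1000 + span)], chains={"B"})

    ca = np.array([a.coord for a in atoms_a if a.atom_name == "CA"]).mean(axis=0)
    cb = np.array([a.coord for a in atoms_b if a.atom_name == "CA"]).mean(axis=0)
    shift = ca + np.array([separation, 0.0, 0.0]) - cb
    atoms_b = [
        Atom(
            chain_id=a.chain_id,
            res_seq=a.res_seq,
            res_name=a.res_name,
            atom_name=a.atom_name,
            element=a.element,
            coord=tuple(float(x) for x in (np.array(a.coord) + shift)),
        )
        for a in atoms_b
    ]
    return Structure(atoms_a + atoms_b, title="two-bundle toy"), sel_a, sel_b


def make_cavity(
    inner_side: float,
    wall_atom_spacing: float = 0.4,
    wall_radius: float = 1.70,
) -> tuple[Structure, np.ndarray]:
    """A cubic shell of pseudo-atoms enclosing an empty cube.

    Wall-atom centres sit on the six planes at ±(inner_side/2 + radius),
    so that for probe 0 the enclosed free volume is analytically
    ``inner_side ** 3``.  Returns the shell structure and a seed point at
    the cavity centre.

    Raises
    ------
    ValueError
        If ``wall_atom_spacing`` exceeds 1.2 Å (the wall would leak).
    """
    if wall_atom_spacing > 1.2:
        raise ValueError(
            f"wall_atom_spacing {wall_atom_spacing} > 1.2 Å would leak"
        )
    half = inner_side / 2.0 + wall_radius
    n = int(math.ceil(2 * half / wall_atom_spacing)) + 1
    ticks = np.linspace(-half, half, n)
    centres: list[tuple[float, float, float]] = []
    for fixed_axis in range(3):
        for sign in (-1.0, 1.0):
            for u in ticks:
                for v in ticks:
                    p = [0.0, 0.0, 0.0]
                    p[fixed_axis] = sign * half
                    p[(fixed_axis + 1) % 3] = float(u)
                    p[(fixed_axis + 2) % 3] = float(v)
                    centres.append(tuple(p))
    # drop duplicate edge/corner points
    unique = sorted(set((round(x, 6), round(y, 6), round(z, 6)) for x, y, z in centres))
    atoms = [
        Atom(
            chain_id="W",
            res_seq=i + 1,
            res_name="CAV",
            atom_name="C",
            element="C",
            coord=c,
            hetero=True,
        )
        for i, c in enumerate(unique)
    ]
    return Structure(atoms, title="cavity shell"), np.zeros(3)


@dataclass
class TrajectorySpec:
    """Interpolation trajectory between two conformations plus noise."""

    start: Structure
    end: Structure
    n_frames: int = 50
    noise_sigma: float = 0.0
    seed: int = 0
    moving_selection: AtomSelection | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if [a.key for a in self.start.atoms] != [a.key for a in self.end.atoms]:
            raise ValueError("start and end structures must share one topology")


def make_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Frame k = linear interpolation start→end at fraction k/(n−1), plus
    iid Gaussian coordinate noise of ``noise_sigma``.

    When ``moving_selection`` is given, only those atoms interpolate; the
    rest stay at their start coordinates (motion localized by
    construction).
    """
    x0 = spec.start.coords
    x1 = spec.end.coords
    delta = x1 - x0
    if spec.moving_selection is not None:
        resolved = resolve(spec.moving_selection, spec.start)
        keys = set(resolved.keys)
        mask = np.array([a.key in keys for a in spec.start.atoms])
        delta = np.where(mask[:, None], delta, 0.0)
    rng = np.random.default_rng(spec.seed)
    frames = []
    for k in range(spec.n_frames):
        f = x0 + delta * (k / (spec.n_frames - 1))
        if spec.noise_sigma > 0:
            f = f + rng.normal(0.0, spec.noise_sigma, f.shape)
        frames.append(f)
    return Trajectory(spec.start, frames)


def plant_site(
    entries: list[tuple[str, int, str, str, str, tuple[float, float, float]]],
) -> Structure:
    """Place atoms verbatim: entries of
    ``(chain, res_seq, res_name, atom_name, element, (x, y, z))``.

    Residue names outside the standard set are stored as HETATM records
    (NO3, HOH, ...).  Duplicate atom keys are an error.
    """
    if not entries:
        raise ValueError("empty site geometry")
    atoms = []
    seen = set()
    hetero_names = {"NO3", "NO2", "HOH", "WAT"}
    for chain, res_seq, res_name, atom_name, element, coord in entries:
        atom = Atom(
            chain_id=chain,
            res_seq=int(res_seq),
            res_name=res_name,
            atom_name=atom_name,
            element=element,
            coord=tuple(float(x) for x in coord),
            hetero=res_name in hetero_names,
        )
        if atom.key in seen:
            raise ValueError(f"duplicate atom key {atom.key}")
        seen.add(atom.key)
        atoms.append(atom)
    return Structure(atoms, title="planted site")
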