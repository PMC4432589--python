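"""Selection-restricted rigid-body superposition and RMSD.

Implements the classic SVD-based least-squares fit (Kabsch) with proper
rotation enforced, atom pairing over commonly resolved residues, and
fit-then-measure RMSD between two structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import AtomSelection, SelectionError, Structure, resolve

__all__ = [
    "SuperpositionResult",
    "PairedAtoms",
    "pair_common_atoms",
    "kabsch_fit",
    "rmsd_between",
    "superpose_structure",
]


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping Y onto X, with the post-fit RMSD."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int
    fit_selection: AtomSelection | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class PairedAtoms:
    """Equal-length coordinate sets paired by (chain, res_seq, ins, atom)."""

    x: np.ndarray  # coords from structure a
    y: np.ndarray  # coords from structure b
    keys: list[tuple[str, int, str, str]]
    n_dropped: int

    @property
    def n_pairs(self) -> int:
        return len(self.keys)


def pair_common_atoms(
    a: Structure,
    b: Structure,
    sel: AtomSelection,
    chain_map: dict[str, str] | None = None,
) -> PairedAtoms:
    """Pair atoms of two structures resolved under one selection.

    Atoms are matched by (chain, res_seq, ins_code, atom_name) after
    applying ``chain_map`` (a→b chain renaming, e.g. ``{"A": "B"}`` to
    compare the two molecules of one asymmetric unit).  Atoms resolved in
    only one structure are dropped and counted.

    Raises
    ------
    SelectionError
        If fewer than 3 common pairs remain.
    """
    chain_map = chain_map or {}
    ra = resolve(sel, a)
    sel_b = sel
    if chain_map and sel.chains != "all":
        sel_b = AtomSelection.make(
            chains={chain_map.get(c, c) for c in sel.chains},
            ranges=sel.ranges,
            atom_names=sel.atom_names,
            res_names=sel.res_names,
        )
    rb = resolve(sel_b, b)

    def mapped_key(atom):
        c, r, i, n = atom.key
        return (chain_map.get(c, c), r, i, n)

    index_b = {atom.key: atom for atom in rb.atoms}
    xs, ys, keys = [], [], []
    n_dropped = 0
    matched = set()
    for atom in ra.atoms:
        k = mapped_key(atom)
        other = index_b.get(k)
        if other is None:
            n_dropped += 1
            continue
        xs.append(atom.coord)
        ys.append(other.coord)
        keys.append(atom.key)
        matched.add(k)
    n_dropped += sum(1 for k in index_b if k not in matched)
    if len(keys) < 3:
        raise SelectionError(
            f"only {len(keys)} common atom pairs (need >= 3); "
            f"{n_dropped} unpaired"
        )
    return PairedAtoms(
        np.array(xs, dtype=float), np.array(ys, dtype=float), keys, n_dropped
    )


def kabsch_fit(x: np.ndarray, y: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of point set ``y`` onto ``x``.

    Returns the proper rotation R and translation t minimising
    ``|x - (R y + t)|`` in the least-squares sense, plus the post-fit RMSD.
    Reflections are excluded by flipping the smallest singular vector when
    ``det < 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be (n, 3); got {x.shape} vs {y.shape}")
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 points, got {n}")
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2 or np.linalg.matrix_rank(y0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    h = y0.T @ x0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = xc - rotation @ yc
    diff = x - (y @ rotation.T + translation)
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(rotation, translation, rmsd, n)


def rmsd_between(
    a: Structure,
    b: Structure,
    fit_sel: AtomSelection,
    measure_sel: AtomSelection | None = None,
    chain_map: dict[str, str] | None = None,
    trim_to: int | None = None,
) -> tuple[float, SuperpositionResult, int]:
    """Fit ``b`` onto ``a`` over ``fit_sel`` pairs, measure RMSD over
    ``measure_sel`` pairs (defaults to the fit selection).

    ``trim_to`` iteratively discards the worst-deviating pair (refitting
    each round) until at most that many pairs remain; the achieved pair
    count is returned alongside the RMSD so callers can report it.

    Returns ``(rmsd, fit_result, n_measured_pairs)``.
    """
    measure_sel = measure_sel if measure_sel is not None else fit_sel
    pairs = pair_common_atoms(a, b, fit_sel, chain_map)
    x, y = pairs.x, pairs.y
    if trim_to is not None and trim_to >= 3:
        while x.shape[0] > trim_to:
            fit = kabsch_fit(x, y)
            dev = np.linalg.norm(x - fit.apply(y), axis=1)
            worst = int(np.argmax(dev))
            x = np.delete(x, worst, axis=0)
            y = np.delete(y, worst, axis=0)
    fit = kabsch_fit(x, y)
    fit.fit_selection = fit_sel

    if measure_sel is fit_sel and trim_to is None:
        return fit.rmsd, fit, pairs.n_pairs

    mpairs = pair_common_atoms(a, b, measure_sel, chain_map)
    if trim_to is not None and measure_sel is fit_sel:
        # measure over the trimmed fit set itself
        diff = x - fit.apply(y)
        rmsd = float(np.sqrt((diff**2).sum() / x.shape[0]))
        return rmsd, fit, x.shape[0]
    diff = mpairs.x - fit.apply(mpairs.y)
    rmsd = float(np.sqrt((diff**2).sum() / mpairs.n_pairs))
    return rmsd, fit, mpairs.n_pairs


def superpose_structure(
    ref: Structure,
    mobile: Structure,
    fit_sel: AtomSelection,
    chain_map: dict[str, str] | None = None,
) -> tuple[Structure, SuperpositionResult]:
    """Return ``mobile`` rigidly transformed onto ``ref`` over ``fit_sel``."""
    pairs = pair_common_atoms(ref, mobile, fit_sel, chain_map)
    fit = kabsch_fit(pairs.x, pairs.y)
    fit.fit_selection = fit_sel
    return mobile.transformed(fit.rotation, fit.translation), fit
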