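"""Trajectory statistics: RMSD series, per-residue RMSF and the
inter-bundle centroid-distance order parameter."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import AtomSelection, Structure, Trajectory, resolve
from .superpose import kabsch_fit

__all__ = [
    "SeriesResult",
    "RmsfResult",
    "rmsd_series",
    "rmsf",
    "bundle_distance_series",
    "crystal_reference_distances",
]

ALL_CA = AtomSelection.ca()


@dataclass
class SeriesResult:
    name: str
    times: np.ndarray
    values: np.ndarray
    units: str = "Å"
    reference_lines: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


@dataclass
class RmsfResult:
    residue_keys: list[tuple[str, int, str]]
    rmsf: np.ndarray

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if len(self.residue_keys) != self.rmsf.shape[0]:
            raise ValueError("one RMSF value per residue required")


def _indices(traj: Trajectory, sel: AtomSelection) -> np.ndarray:
    resolved = resolve(sel, traj.topology)
    index_of = {a.key: i for i, a in enumerate(traj.topology.atoms)}
    return np.array([index_of[k] for k in resolved.keys], dtype=int)


def rmsd_series(
    traj: Trajectory,
    ref: Structure,
    fit_sel: AtomSelection = ALL_CA,
    measure_sel: AtomSelection | None = None,
) -> SeriesResult:
    """Per-frame RMSD from a reference after per-frame superposition.

    Each frame is rigidly fitted to ``ref`` over ``fit_sel`` and the RMSD
    is measured over ``measure_sel`` (default: the fit selection).
    """
    measure_sel = measure_sel if measure_sel is not None else fit_sel
    ref_fit = resolve(fit_sel, ref).coords
    ref_measure = resolve(measure_sel, ref).coords
    idx_fit = _indices(traj, fit_sel)
    idx_measure = _indices(traj, measure_sel)
    if ref_fit.shape[0] != idx_fit.shape[0] or ref_measure.shape[0] != idx_measure.shape[0]:
        raise ValueError("selection resolves differently in reference and topology")
    values = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        fit = kabsch_fit(ref_fit, frame[idx_fit])
        diff = ref_measure - fit.apply(frame[idx_measure])
        values[k] = np.sqrt((diff**2).sum() / diff.shape[0])
    return SeriesResult("rmsd", traj.times(), values)


def rmsf(
    traj: Trajectory,
    fit_sel: AtomSelection = ALL_CA,
    measure_sel: AtomSelection | None = None,
    reference: str = "mean",
) -> RmsfResult:
    """Per-residue RMS fluctuation of ``measure_sel`` atoms.

    Frames are first aligned on ``fit_sel``.  With ``reference="mean"``
    (default) the alignment target is the time-mean structure, obtained by
    a two-pass procedure: align all frames to frame 0, compute the mean,
    re-align to that mean.  With ``reference="first"`` frames are aligned
    to frame 0 and fluctuations are still taken about the time-mean
    positions of the aligned frames.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    if reference not in ("mean", "first"):
        raise ValueError(f"unknown reference mode {reference!r}")
    measure_sel = measure_sel if measure_sel is not None else fit_sel
    idx_fit = _indices(traj, fit_sel)
    idx_measure = _indices(traj, measure_sel)

    def align_all(target_fit: np.ndarray) -> np.ndarray:
        out = np.empty((traj.n_frames, idx_measure.shape[0], 3))
        for k, frame in enumerate(traj.frames):
            fit = kabsch_fit(target_fit, frame[idx_fit])
            out[k] = fit.apply(frame[idx_measure])
        return out

    aligned = align_all(traj.frames[0][idx_fit])
    if reference == "mean":
        # second pass: refit every frame onto the mean of the first pass
        mean_full = np.empty((traj.n_frames, idx_fit.shape[0], 3))
        for k, frame in enumerate(traj.frames):
            fit = kabsch_fit(traj.frames[0][idx_fit], frame[idx_fit])
            mean_full[k] = fit.apply(frame[idx_fit])
        aligned = align_all(mean_full.mean(axis=0))

    mean_pos = aligned.mean(axis=0)
    per_atom = np.sqrt(((aligned - mean_pos) ** 2).sum(axis=2).mean(axis=0))

    # average atom RMSF within each residue of the measure selection
    atoms = resolve(measure_sel, traj.topology).atoms
    residue_keys: list[tuple[str, int, str]] = []
    sums: dict[tuple[str, int, str], list[float]] = {}
    for a, v in zip(atoms, per_atom):
        rk = a.residue_key
        if rk not in sums:
            sums[rk] = []
            residue_keys.append(rk)
        sums[rk].append(float(v))
    values = np.array([np.mean(sums[rk]) for rk in residue_keys])
    return RmsfResult(residue_keys, values)


def bundle_distance_series(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
) -> SeriesResult:
    """Distance between the Cα centroids of two selections, per frame.

    This is an internal coordinate: no superposition is applied, so the
    series is invariant under arbitrary per-frame rigid motion.
    """
    idx_a = _indices(traj, sel_a)
    idx_b = _indices(traj, sel_b)
    values = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        values[k] = np.linalg.norm(
            frame[idx_a].mean(axis=0) - frame[idx_b].mean(axis=0)
        )
    return SeriesResult("bundle_distance", traj.times(), values)


def crystal_reference_distances(
    structs: dict[str, Structure],
    sel_a: AtomSelection,
    sel_b: AtomSelection,
) -> dict[str, float]:
    """Same centroid distance evaluated on static structures.

    Returns ``{name: distance}`` for use as ``reference_lines`` of a
    :class:`SeriesResult`.
    """
    out = {}
    for name, s in structs.items():
        ca = resolve(sel_a, s).coords.mean(axis=0)
        cb = resolve(sel_b, s).coords.mean(axis=0)
        out[name] = float(np.linalg.norm(ca - cb))
    return out
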