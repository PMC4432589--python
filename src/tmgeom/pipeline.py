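"""End-to-end state-comparison pipeline over deposited structures."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import defaults
from .gates import ContactSpec, gate_state
from .helix import HelixSegment, bend_report
from .report import AnalysisReport
from .sites import SiteResidues, site_compare
from .structure import AtomSelection, Structure, read_pdb
from .superpose import rmsd_between
from .trajstats import crystal_reference_distances

log = logging.getLogger("tmgeom.pipeline")

__all__ = ["PipelineConfig", "run_state_comparison"]

LIGAND_SEL = AtomSelection.make(res_names={"NO3", "NO2"})


@dataclass
class PipelineConfig:
    """Inputs of the reproduction pipeline.

    At least the occluded and one inward-open structure path must be set;
    the residue tables default to the deposited transporter's constants.
    """

    occluded: Path | None = None
    inward_open: Path | None = None
    apo: Path | None = None
    out_dir: Path = Path("tmgeom-report")
    segments: list[HelixSegment] = field(
        default_factory=lambda: list(defaults.DEFAULT_SEGMENTS)
    )
    layers: list[ContactSpec] = field(
        default_factory=lambda: list(defaults.DEFAULT_LAYERS)
    )
    site_residues: SiteResidues = field(default_factory=SiteResidues)
    global_fit: AtomSelection = defaults.N_BUNDLE_FIT
    sel_a: AtomSelection = defaults.TM45_CYTOSOLIC
    sel_b: AtomSelection = defaults.TM1011_CYTOSOLIC
    pocket_spacing: float = 0.25
    pocket_probe: float = 1.4
    occluded_chain_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.occluded is None and self.inward_open is None and self.apo is None:
            raise ValueError("at least one structure path is required")


def _single_chain(s: Structure, chain: str) -> Structure:
    atoms = [a for a in s.atoms if a.chain_id == chain]
    return Structure(atoms, model_id=s.model_id, title=s.title)


def run_state_comparison(cfg: PipelineConfig) -> AnalysisReport:
    """Run every comparison stage and write one report directory.

    Per-stage failures are logged and recorded as failed rows; the
    returned report carries a ``n_failed`` entry so callers can exit
    nonzero when anything went wrong.  The run is deterministic: no stage
    uses randomness.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport(name="state_comparison")
    n_failed = 0

    structures: dict[str, Structure] = {}
    for name, path in (
        ("occluded", cfg.occluded),
        ("inward_open", cfg.inward_open),
        ("apo", cfg.apo),
    ):
        if path is None:
            continue
        try:
            structures[name] = read_pdb(path)
        except Exception as exc:
            log.error("loading %s (%s) failed: %s", name, path, exc)
            report.add(name=f"load:{name}", value="failed", status=str(exc))
            n_failed += 1

    occ = structures.get("occluded")
    inw = structures.get("inward_open")
    apo = structures.get("apo")

    # -- intra-crystal RMSD between the two occluded molecules -------------
    if occ is not None and cfg.occluded_chain_pair:
        ca, cb = cfg.occluded_chain_pair
        try:
            sel = AtomSelection.ca(chains={ca})
            value, _, n = rmsd_between(
                _single_chain(occ, ca), _single_chain(occ, cb),
                sel, chain_map={ca: cb},
            )
            report.add(name="rmsd:occluded_molA_vs_molB", value=value, units="Å",
                       n_atoms=n, operation="rmsd_between(all CA)")
        except Exception as exc:
            log.error("mol A/B RMSD failed: %s", exc)
            report.add(name="rmsd:occluded_molA_vs_molB", value=float("nan"),
                       units="Å", status=str(exc))
            n_failed += 1

    # -- apo vs nitrate-bound inward-open RMSD -----------------------------
    if apo is not None and inw is not None:
        try:
            sel = AtomSelection.ca()
            value, _, n = rmsd_between(apo, inw, sel)
            report.add(name="rmsd:apo_vs_bound_inward", value=value, units="Å",
                       n_atoms=n, operation="rmsd_between(common CA)")
        except Exception as exc:
            log.error("apo/bound RMSD failed: %s", exc)
            n_failed += 1

    # -- hinge bend angles -------------------------------------------------
    if occ is not None and inw is not None:
        bends = bend_report(occ, inw, cfg.segments, cfg.global_fit)
        bends.to_tsv(cfg.out_dir / "bend_angles.tsv")
        for row in bends.rows:
            report.add(name=f"bend:{row['name']}", value=row["value"],
                       units="deg", status=row.get("status", ""))

    # -- gate states -------------------------------------------------------
    for name, s in structures.items():
        try:
            verdict = gate_state(s, cfg.layers)
            verdict.report.to_tsv(cfg.out_dir / f"gates_{name}.tsv")
            report.add(name=f"gate:{name}", value=verdict.state, units="",
                       layers_formed=sum(verdict.layers_formed.values()))
        except Exception as exc:
            log.error("gate analysis of %s failed: %s", name, exc)
            n_failed += 1

    # -- binding-site geometry and pocket volumes --------------------------
    if occ is not None and inw is not None:
        try:
            sites = site_compare(
                occ, inw, LIGAND_SEL, cfg.site_residues,
                spacing=cfg.pocket_spacing, probe=cfg.pocket_probe,
            )
            sites.to_tsv(cfg.out_dir / "site_compare.tsv")
            for row in sites.rows:
                report.add(name=f"site:{row['name']}", value=row["value"],
                           units=row["units"], status=row.get("status", ""))
        except Exception as exc:
            log.error("site comparison failed: %s", exc)
            n_failed += 1

    # -- crystal reference centroid distances ------------------------------
    try:
        refs = crystal_reference_distances(
            {k: v for k, v in structures.items()}, cfg.sel_a, cfg.sel_b
        )
        for name, value in refs.items():
            report.add(name=f"bundle_distance:{name}", value=value, units="Å")
    except Exception as exc:
        log.error("reference distances failed: %s", exc)
        n_failed += 1

    report.add(name="n_failed", value=n_failed, units="")
    report.to_tsv(cfg.out_dir / "state_comparison.tsv")
    report.to_json(cfg.out_dir / "state_comparison.json")
    return report
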