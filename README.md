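# tmgeom

Geometric analysis of membrane-transporter conformational states, built
around the comparisons used to characterise an MFS nitrate/nitrite
antiporter's occluded and inward-open crystal structures:

- **structure model + PDB I/O** (`tmgeom.structure`) — ordered atom lists,
  declarative atom selections, multi-model PDB trajectories; parsing backed
  by biotite with highest-occupancy alt-loc resolution.
- **superposition** (`tmgeom.superpose`) — atom pairing over commonly
  resolved residues, SVD least-squares rigid fit (proper rotations only),
  fit-then-measure RMSD, optional worst-pair trimming.
- **helix geometry** (`tmgeom.helix`) — hinge-glycine bend angles between
  states from window-averaged Cα principal axes after a global fit on the
  static bundle.
- **gate analysis** (`tmgeom.gates`) — hydrophobic contacts, heavy-atom
  hydrogen bonds and water bridges; layer-based closed/open classification
  of the cytoplasmic gate (layers C1–C3).
- **binding site** (`tmgeom.sites`) — recognition-site distances (bidentate
  arginine salt bridge, tyrosine hydroxyl network, asparagine amide,
  aromatic sandwich) and grid flood-fill pocket volumes.
- **trajectory statistics** (`tmgeom.trajstats`) — RMSD series, per-residue
  RMSF, inter-bundle centroid-distance order parameter, crystal reference
  distances.
- **synthetic data** (`tmgeom.synth`) — generators with known ground truth
  (bent helices, two-bundle toys, analytic cavities, interpolation
  trajectories, planted interaction sites) so every stage is testable
  without downloads.
- **CLI + pipeline** (`tmgeom.cli`, `tmgeom.pipeline`) — subcommands and an
  end-to-end state-comparison report.

## CLI

```sh
tmgeom superpose --ref occluded.pdb --mobile inward.pdb --fit "1-233:CA"
tmgeom bend --ref occluded.pdb --alt inward.pdb --fit "1-233:CA"
tmgeom gates --structure occluded.pdb --report gates.tsv
tmgeom site --structure occluded.pdb --ligand NO3 --pocket --seed auto
tmgeom traj --topology ref.pdb --frames traj.pdb --stats rmsd,rmsf,bundle
tmgeom synth helix --bend-angle 30 --out bent.pdb
tmgeom reproduce --occluded 4u4w.pdb --inward-open 4u4t.pdb --apo 4u4v.pdb
```

Selections use `RANGES:ATOMS` syntax (`1-233:CA`, `369-380,399-409:CA`,
`all:all`).

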