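"""Default residue tables for the nitrate/nitrite antiporter analyses.

Author residue numbering of the deposited *E. coli* transporter
structures.  Helix-half boundaries are configurable: only the cytosolic
segment ranges and hinge glycines are fixed by the deposition; the static
halves are conservative periplasmic-side remainders.
"""

from __future__ import annotations

from .gates import ContactSpec, ResidueSpec
from .helix import HelixSegment
from .sites import SiteResidues
from .structure import AtomSelection

__all__ = [
    "N_BUNDLE_FIT",
    "DEFAULT_SEGMENTS",
    "DEFAULT_LAYERS",
    "DEFAULT_SITE_RESIDUES",
    "TM45_CYTOSOLIC",
    "TM1011_CYTOSOLIC",
]

#: Global superposition selection: Cα of the N-bundle residues.
N_BUNDLE_FIT = AtomSelection.ca(ranges=[(1, 233)])

#: Hinge-bent helices of the C bundle.  Moving halves follow the
#: residue-exact cytosolic segments used for the centroid-distance order
#: parameter; static halves and the TM7 boundaries are defaults, not
#: deposited facts, and can be overridden per run.
DEFAULT_SEGMENTS = [
    HelixSegment(
        name="TM7",
        full_range=(248, 284),
        hinge_residues=(268,),
        moving_half=(269, 284),
        static_half=(254, 267),
    ),
    HelixSegment(
        name="TM10",
        full_range=(348, 381),
        hinge_residues=(363, 365, 367),
        moving_half=(369, 380),
        static_half=(348, 362),
    ),
    HelixSegment(
        name="TM11",
        full_range=(396, 430),
        hinge_residues=(408, 414, 417, 418),
        moving_half=(399, 409),
        static_half=(413, 428),
    ),
]


def _group(*residues: int | tuple[int, str]) -> tuple[ResidueSpec, ...]:
    out = []
    for r in residues:
        if isinstance(r, tuple):
            out.append(ResidueSpec(r[0], r[1]))
        else:
            out.append(ResidueSpec(r))
    return tuple(out)


#: Cytoplasmic gate layers C1–C3 (text-named interactions only).
DEFAULT_LAYERS = [
    ContactSpec(
        layer="C1",
        group_n=_group((147, "side-chain"), (151, "side-chain"), (167, "side-chain")),
        group_c=_group((370, "side-chain"), (407, "side-chain")),
        kind="hydrophobic",
        label="F147/M151/L167~F370/L407",
    ),
    ContactSpec(
        layer="C1",
        group_n=_group((148, "main-chain")),
        group_c=_group((404, "main-chain")),
        kind="water_bridge",
        label="A148~water~A404",
    ),
    ContactSpec(
        layer="C2",
        group_n=_group((156, "side-chain"), (159, "main-chain"),
                       (160, "main-chain"), (161, "main-chain")),
        group_c=_group((382, "side-chain"), (396, "side-chain"), (400, "side-chain")),
        kind="hydrophobic",
        label="F156/P159-Q161~M382/M396/A400",
    ),
    ContactSpec(
        layer="C2",
        group_n=_group((378, "side-chain")),
        group_c=_group((158, "main-chain"), (160, "main-chain")),
        kind="hbond",
        label="R378~F158/K160 carbonyls",
    ),
    ContactSpec(
        layer="C2",
        group_n=_group((400, "main-chain")),
        group_c=_group((155, "side-chain")),
        kind="hbond",
        label="A400 carbonyl~S155 OG",
    ),
    ContactSpec(
        layer="C3",
        group_n=_group(20, 21),
        group_c=_group(392, 393, 396),
        kind="hydrophobic",
        label="P20/E21~D392/E393/M396",
    ),
]

DEFAULT_SITE_RESIDUES = SiteResidues()

#: Cytosolic-segment selections for the inter-bundle centroid distance.
TM45_CYTOSOLIC = AtomSelection.ca(ranges=[(148, 171)])
TM1011_CYTOSOLIC = AtomSelection.ca(ranges=[(369, 380), (399, 409)])
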