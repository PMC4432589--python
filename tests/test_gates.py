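import numpy as np
import pytest

from tmgeom.gates import (
    ContactSpec,
    ResidueSpec,
    find_contacts,
    find_hbonds,
    find_water_bridges,
    gate_state,
)
from tmgeom.structure import SelectionError
from tmgeom.synth import plant_site


def _pair_structure(distance):
    return plant_site(
        [
            ("A", 10, "LEU", "CD1", "C", (0.0, 0.0, 0.0)),
            ("A", 50, "PHE", "CZ", "C", (distance, 0.0, 0.0)),
        ]
    )


class TestFindContacts:
    def test_hit_within_cutoff(self):
        s = _pair_structure(3.0)
        hits = find_contacts(s, [ResidueSpec(10)], [ResidueSpec(50)], cutoff=4.5)
        assert len(hits) == 1
        assert hits[0].distance == pytest.approx(3.0)

    def test_no_hit_beyond_cutoff(self):
        s = _pair_structure(3.0)
        assert find_contacts(s, [ResidueSpec(10)], [ResidueSpec(50)], cutoff=2.5) == []

    def test_symmetric_pair_set(self):
        s = _pair_structure(3.0)
        ab = find_contacts(s, [ResidueSpec(10)], [ResidueSpec(50)], 4.5)
        ba = find_contacts(s, [ResidueSpec(50)], [ResidueSpec(10)], 4.5)
        assert {(h.atom_a, h.atom_b) for h in ab} == {
            (h.atom_b, h.atom_a) for h in ba
        }

    def test_monotone_in_cutoff(self, rng):
        entries = [
            ("A", 1, "LEU", f"C{i}", "C", tuple(rng.uniform(-3, 3, 3)))
            for i in range(1, 6)
        ] + [
            ("A", 2, "PHE", f"C{i}", "C", tuple(rng.uniform(-3, 3, 3)))
            for i in range(1, 6)
        ]
        s = plant_site(entries)
        counts = [
            len(find_contacts(s, [ResidueSpec(1)], [ResidueSpec(2)], c))
            for c in (2.0, 3.0, 4.0, 5.0, 8.0)
        ]
        assert counts == sorted(counts)

    def test_empty_group_resolution(self):
        s = _pair_structure(3.0)
        with pytest.raises(SelectionError):
            find_contacts(s, [ResidueSpec(999)], [ResidueSpec(50)], 4.5)

    def test_scope_filtering(self):
        s = plant_site(
            [
                ("A", 10, "ALA", "O", "O", (0.0, 0.0, 0.0)),    # main chain
                ("A", 10, "ALA", "CB", "C", (0.0, 1.0, 0.0)),   # side chain
                ("A", 50, "SER", "OG", "O", (2.8, 0.0, 0.0)),
            ]
        )
        main = find_contacts(s, [ResidueSpec(10, "main-chain")], [ResidueSpec(50)], 4.5)
        assert {h.atom_a[3] for h in main} == {"O"}
        side = find_contacts(s, [ResidueSpec(10, "side-chain")], [ResidueSpec(50)], 4.5)
        assert {h.atom_a[3] for h in side} == {"CB"}


class TestFindHbonds:
    def test_planted_no_pair_detected(self):
        s = plant_site(
            [
                ("A", 1, "ARG", "NH1", "N", (0.0, 0.0, 0.0)),
                ("A", 2, "PHE", "O", "O", (2.8, 0.0, 0.0)),
            ]
        )
        hits = find_hbonds(s, [ResidueSpec(1)], [ResidueSpec(2)], 3.5)
        assert len(hits) == 1

    def test_beyond_dmax_not_detected(self):
        s = plant_site(
            [
                ("A", 1, "ARG", "NH1", "N", (0.0, 0.0, 0.0)),
                ("A", 2, "PHE", "O", "O", (4.2, 0.0, 0.0)),
            ]
        )
        assert find_hbonds(s, [ResidueSpec(1)], [ResidueSpec(2)], 3.5) == []

    def test_carbon_not_hbond_capable(self):
        s = plant_site(
            [
                ("A", 1, "LEU", "CD1", "C", (0.0, 0.0, 0.0)),
                ("A", 2, "PHE", "O", "O", (2.8, 0.0, 0.0)),
            ]
        )
        with pytest.raises(SelectionError):
            find_hbonds(s, [ResidueSpec(1)], [ResidueSpec(2)], 3.5)

    def test_planted_recall_no_spurious(self, rng):
        # plant 5 donor/acceptor pairs at 2.6-3.2 Å and 5 far decoys
        entries = []
        for i in range(5):
            base = rng.uniform(-20, 20, 3)
            d = 2.6 + 0.15 * i
            entries.append(("A", 100 + i, "ARG", "NH1", "N", tuple(base)))
            entries.append(
                ("A", 200 + i, "ALA", "O", "O", tuple(base + np.array([d, 0, 0])))
            )
        for i in range(5):
            base = rng.uniform(40, 80, 3)
            entries.append(("A", 300 + i, "ARG", "NH2", "N", tuple(base)))
            entries.append(
                ("A", 400 + i, "ALA", "O", "O", tuple(base + np.array([5.0, 0, 0])))
            )
        s = plant_site(entries)
        donors = [ResidueSpec(100 + i) for i in range(5)] + [
            ResidueSpec(300 + i) for i in range(5)
        ]
        acceptors = [ResidueSpec(200 + i) for i in range(5)] + [
            ResidueSpec(400 + i) for i in range(5)
        ]
        hits = find_hbonds(s, donors, acceptors, 3.5)
        found = {(h.atom_a[1], h.atom_b[1]) for h in hits}
        assert found == {(100 + i, 200 + i) for i in range(5)}


class TestWaterBridges:
    def test_planted_bridge(self):
        s = plant_site(
            [
                ("A", 148, "ALA", "O", "O", (0.0, 0.0, 0.0)),
                ("A", 404, "ALA", "O", "O", (5.0, 0.0, 0.0)),
                ("W", 700, "HOH", "O", "O", (2.5, 0.8, 0.0)),
            ]
        )
        hits = find_water_bridges(s, [ResidueSpec(148)], [ResidueSpec(404)], 3.5)
        assert len(hits) == 1
        assert hits[0].water_key == ("W", 700, "")

    def test_no_waters_empty(self):
        s = plant_site(
            [
                ("A", 148, "ALA", "O", "O", (0.0, 0.0, 0.0)),
                ("A", 404, "ALA", "O", "O", (5.0, 0.0, 0.0)),
            ]
        )
        assert find_water_bridges(s, [ResidueSpec(148)], [ResidueSpec(404)], 3.5) == []

    def test_one_leg_too_long_no_bridge(self):
        s = plant_site(
            [
                ("A", 148, "ALA", "O", "O", (0.0, 0.0, 0.0)),
                ("A", 404, "ALA", "O", "O", (8.0, 0.0, 0.0)),
                ("W", 700, "HOH", "O", "O", (2.5, 0.0, 0.0)),
            ]
        )
        assert find_water_bridges(s, [ResidueSpec(148)], [ResidueSpec(404)], 3.5) == []


def _layer_specs():
    return [
        ContactSpec("C1", (ResidueSpec(10),), (ResidueSpec(50),), "hydrophobic"),
        ContactSpec("C2", (ResidueSpec(11),), (ResidueSpec(51),), "hbond"),
    ]


class TestGateState:
    def _closed_structure(self):
        return plant_site(
            [
                ("A", 10, "LEU", "CD1", "C", (0.0, 0.0, 0.0)),
                ("A", 50, "PHE", "CZ", "C", (3.5, 0.0, 0.0)),
                ("A", 11, "ARG", "NH1", "N", (0.0, 5.0, 0.0)),
                ("A", 51, "ALA", "O", "O", (2.9, 5.0, 0.0)),
            ]
        )

    def test_closed_when_all_layers_formed(self):
        verdict = gate_state(self._closed_structure(), _layer_specs())
        assert verdict.state == "closed"
        assert verdict.layers_formed == {"C1": True, "C2": True}

    def test_open_when_contacts_broken(self):
        s = plant_site(
            [
                ("A", 10, "LEU", "CD1", "C", (0.0, 0.0, 0.0)),
                ("A", 50, "PHE", "CZ", "C", (12.0, 0.0, 0.0)),
                ("A", 11, "ARG", "NH1", "N", (0.0, 5.0, 0.0)),
                ("A", 51, "ALA", "O", "O", (12.0, 5.0, 0.0)),
            ]
        )
        verdict = gate_state(s, _layer_specs())
        assert verdict.state == "open"
        assert not any(verdict.layers_formed.values())

    def test_unresolved_layer_counts_open(self):
        s = plant_site([("A", 10, "LEU", "CD1", "C", (0.0, 0.0, 0.0))])
        specs = [
            ContactSpec("C1", (ResidueSpec(10),), (ResidueSpec(99),), "hydrophobic")
        ]
        verdict = gate_state(s, specs)
        assert verdict.state == "open"
        assert any(
            r.get("status") == "unresolved" for r in verdict.report.rows
        )

    def test_empty_specs_rejected(self):
        with pytest.raises(ValueError):
            gate_state(self._closed_structure(), [])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ContactSpec("C1", (), (ResidueSpec(1),), "hydrophobic")
        with pytest.raises(ValueError):
            ContactSpec("C1", (ResidueSpec(1),), (ResidueSpec(2),), "magnetic")
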