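import math

import numpy as np
import pytest

from tmgeom.sites import (
    PocketResult,
    SiteResidues,
    pocket_volume,
    ring_geometry,
    site_compare,
    site_geometry,
)
from tmgeom.structure import AtomSelection
from tmgeom.synth import make_cavity, plant_site

from .conftest import random_rotation

NO3_SEL = AtomSelection.make(res_names={"NO3"})


def _toy_site(site_a=3.0, site_b=2.4):
    """Ligand NO3 at the origin with recognition residues planted around it."""
    return plant_site(
        [
            ("A", 500, "NO3", "N", "N", (0.0, 0.0, 0.0)),
            ("A", 500, "NO3", "O1", "O", (1.25, 0.0, 0.0)),
            ("A", 500, "NO3", "O2", "O", (-0.62, 1.08, 0.0)),
            ("A", 500, "NO3", "O3", "O", (-0.62, -1.08, 0.0)),
            ("A", 89, "ARG", "NH1", "N", (1.25 + site_a, 0.0, 0.0)),
            ("A", 89, "ARG", "NH2", "N", (1.25 + site_a + 0.4, 1.0, 0.0)),
            ("A", 263, "TYR", "OH", "O", (-0.62, 1.08 + site_b, 0.0)),
            ("A", 305, "ARG", "NH1", "N", (-0.62, 1.08 + site_b + 2.9, 0.0)),
            ("A", 366, "SER", "OG", "O", (-0.62, 1.08 + site_b + 2.9, 2.7)),
            ("A", 175, "ASN", "ND2", "N", (-0.62, -1.08 - 3.1, 0.0)),
        ]
    )


class TestSiteGeometry:
    def test_planted_site_a_distance(self):
        geo = site_geometry(_toy_site(site_a=3.0), NO3_SEL)
        assert geo.site_a_nh1 == pytest.approx(3.0, abs=1e-9)
        assert geo.site_a_min == pytest.approx(3.0, abs=1e-9)

    def test_planted_site_b_and_network(self):
        geo = site_geometry(_toy_site(site_b=2.4), NO3_SEL)
        assert geo.site_b_min == pytest.approx(2.4, abs=1e-9)
        assert geo.site_b_network_tyr_arg == pytest.approx(2.9, abs=1e-9)
        assert geo.site_b_network_arg_ser == pytest.approx(2.7, abs=1e-9)

    def test_site_c_distance(self):
        geo = site_geometry(_toy_site(), NO3_SEL)
        assert geo.site_c == pytest.approx(3.1, abs=1e-9)

    def test_apo_reports_network_only(self):
        geo = site_geometry(_toy_site(), ligand_sel=None)
        assert geo.site_a_min is None
        assert geo.site_b_min is None
        assert geo.site_b_network_tyr_arg == pytest.approx(2.9, abs=1e-9)

    def test_rigid_transform_invariance(self, rng):
        s = _toy_site()
        r = random_rotation(rng)
        t = rng.normal(size=3) * 10
        moved = s.transformed(r, t)
        a = site_geometry(s, NO3_SEL)
        b = site_geometry(moved, NO3_SEL)
        assert b.site_a_min == pytest.approx(a.site_a_min, abs=1e-9)
        assert b.site_b_min == pytest.approx(a.site_b_min, abs=1e-9)

    def test_multi_residue_ligand_rejected(self):
        s = plant_site(
            [
                ("A", 500, "NO3", "N", "N", (0.0, 0.0, 0.0)),
                ("A", 501, "NO3", "N", "N", (5.0, 0.0, 0.0)),
                ("A", 89, "ARG", "NH1", "N", (3.0, 0.0, 0.0)),
            ]
        )
        with pytest.raises(ValueError):
            site_geometry(s, NO3_SEL)


def _hexagon(radius=1.39, z=0.0):
    return np.array(
        [
            [radius * math.cos(k * math.pi / 3), radius * math.sin(k * math.pi / 3), z]
            for k in range(6)
        ]
    )


class TestRingGeometry:
    def test_parallel_planes(self):
        dist, angle = ring_geometry(_hexagon(z=0.0), _hexagon(z=3.5))
        assert dist == pytest.approx(3.5, abs=1e-9)
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_planes(self):
        ring = _hexagon()
        ligand = np.array([[0.0, 0.0, 4.0], [0.0, 1.0, 5.0], [0.0, -1.0, 5.0]])
        _, angle = ring_geometry(ring, ligand)
        assert angle == pytest.approx(90.0, abs=1e-6)

    def test_angle_folded_into_0_90(self, rng):
        for _ in range(10):
            r = random_rotation(rng)
            ligand = _hexagon(z=3.0) @ r.T
            _, angle = ring_geometry(_hexagon(), ligand)
            assert 0.0 <= angle <= 90.0

    def test_wrong_ring_size(self):
        with pytest.raises(ValueError):
            ring_geometry(_hexagon()[:5], _hexagon(z=3.0))


class TestPocketVolume:
    def test_cavity_analytic_volume(self):
        shell, seed = make_cavity(4.0)
        res = pocket_volume(
            shell, seed, spacing=0.25, probe=0.0, exclude_res_names=frozenset()
        )
        one_shell = (4.0 + 2 * 0.25) ** 3 - 4.0**3
        assert abs(res.volume - 64.0) <= one_shell
        assert not res.open_pocket
        assert res.volume == pytest.approx(
            res.n_grid_points * res.grid_spacing**3, abs=1e-9
        )

    def test_probe_larger_than_cavity(self):
        shell, seed = make_cavity(4.0)
        with pytest.raises(ValueError):
            # a 3 Å probe swells every wall sphere past the centre: the seed
            # itself is engulfed
            pocket_volume(shell, seed, spacing=0.25, probe=3.0,
                          exclude_res_names=frozenset())

    def test_monotone_in_probe_radius(self):
        shell, seed = make_cavity(6.0)
        volumes = [
            pocket_volume(
                shell, seed, spacing=0.25, probe=p, exclude_res_names=frozenset()
            ).volume
            for p in (0.0, 0.5, 1.0, 1.4)
        ]
        assert all(b <= a for a, b in zip(volumes, volumes[1:]))

    def test_grid_convergence(self):
        shell, seed = make_cavity(4.0)
        v_coarse = pocket_volume(
            shell, seed, spacing=0.5, probe=0.0, exclude_res_names=frozenset()
        ).volume
        v_fine = pocket_volume(
            shell, seed, spacing=0.25, probe=0.0, exclude_res_names=frozenset()
        ).volume
        assert abs(v_fine - v_coarse) / v_fine < 0.20

    def test_flood_fill_equals_direct_enumeration(self):
        # fully enclosed cavity: every free point inside the box belongs to
        # either the sealed interior or the outside region; enumerate directly
        shell, seed = make_cavity(4.0)
        spacing = 0.5
        res = pocket_volume(
            shell, seed, spacing=spacing, probe=0.0, exclude_res_names=frozenset(),
            half_width=3.0,
        )
        coords = shell.coords
        n_free_inner = 0
        half_inner = 2.0 + spacing / 2
        ticks = np.arange(-3.0, 3.0 + spacing / 2, spacing)
        for x in ticks:
            for y in ticks:
                for z in ticks:
                    p = np.array([x, y, z])
                    if np.max(np.abs(p)) > half_inner:
                        continue
                    d = np.linalg.norm(coords - p, axis=1)
                    if (d > 1.70).all():
                        n_free_inner += 1
        assert res.n_grid_points == n_free_inner

    def test_seed_inside_atom_sphere_rejected(self):
        shell, _ = make_cavity(4.0)
        bad_seed = np.array(shell.atoms[0].coord)
        with pytest.raises(ValueError, match="seed"):
            pocket_volume(shell, bad_seed, spacing=0.5, probe=0.0,
                          exclude_res_names=frozenset())

    def test_open_pocket_flagged(self):
        # a single atom far from the seed leaves the fill reaching the bounds
        s = plant_site([("A", 1, "ALA", "CA", "C", (5.0, 5.0, 5.0))])
        res = pocket_volume(s, np.zeros(3), spacing=0.5, probe=0.0, half_width=4.0)
        assert res.open_pocket


class TestSiteCompare:
    def test_identical_structures_zero_delta(self):
        s = _toy_site()
        report = site_compare(s, s, NO3_SEL, pocket=False)
        assert report.get("delta:site_a_min") == pytest.approx(0.0, abs=1e-12)
        assert report.get("delta:site_b_min") == pytest.approx(0.0, abs=1e-12)

    def test_planted_widening(self):
        occ = _toy_site(site_a=2.7, site_b=2.4)
        inw = _toy_site(site_a=3.1, site_b=3.9)
        report = site_compare(occ, inw, NO3_SEL, pocket=False)
        assert report.get("occluded:site_a_min") == pytest.approx(2.7, abs=1e-9)
        assert report.get("inward_open:site_a_min") == pytest.approx(3.1, abs=1e-9)
        assert report.get("delta:site_b_min") == pytest.approx(1.5, abs=1e-9)

    def test_apo_rows_empty_but_network_populated(self):
        s = _toy_site()
        report = site_compare(s, s, ligand_sel=None, pocket=False)
        assert np.isnan(report.get("occluded:site_a_min"))
        assert report.get("occluded:site_b_network_tyr_arg") == pytest.approx(
            2.9, abs=1e-9
        )
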