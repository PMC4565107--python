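"""Power-diagram construction, area aggregation and the Monte-Carlo oracle."""

import numpy as np
import pytest

from vorbind import structure_model as sm
from vorbind import synthetic_fixtures as fx
from vorbind import tessellation as tv


def _site(xyz, w, owner=None):
    return tv.WeightedSite(tuple(xyz), w, owner)


def two_atom_sites():
    # centers 3 A apart on x, weights 4 and 1 -> radical plane at x = 2
    return [_site((0, 0, 0), 4.0, (("X", "1"), 0)),
            _site((3, 0, 0), 1.0, (("X", "2"), 0))]


class TestBuildTessellation:
    def test_single_atom_cell_fills_box(self):
        tess = tv.build_tessellation([_site((0, 0, 0), 2.89)], padding=0.5)
        assert tess.cells[0].volume == pytest.approx(1.0, rel=1e-12)
        faces = tess.cells[0].faces
        assert len(faces) == 6
        assert all(f.neighbor == tv.BOUNDARY for f in faces)
        assert sum(f.area for f in faces) == pytest.approx(6.0, rel=1e-12)

    def test_equal_weights_symmetric_split(self):
        sites = [_site((-1, 0, 0), 2.0), _site((1, 0, 0), 2.0)]
        tess = tv.build_tessellation(sites, padding=4.0)
        assert tess.cells[0].volume == pytest.approx(tess.cells[1].volume, rel=1e-10)

    def test_radical_plane_closed_form(self):
        # x* = (d^2 + w1 - w2) / (2 d) = (9 + 4 - 1) / 6 = 2.0 from site 1
        tess = tv.build_tessellation(two_atom_sites(), padding=5.0)
        # box x in [-5, 8]; cell 0 spans [-5, 2] of a 10 x 10 section
        assert tess.cells[0].volume == pytest.approx(7 * 10 * 10, rel=1e-10)
        assert tess.cells[1].volume == pytest.approx(6 * 10 * 10, rel=1e-10)
        assert tess.face_area(0, 1) == pytest.approx(100.0, rel=1e-10)

    def test_duplicate_centers_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            tv.build_tessellation([_site((0, 0, 0), 1.0), _site((0, 0, 0), 2.0)])

    def test_degenerate_lattice_resolved_by_jitter(self):
        # perfectly regular cube corners are cospherical; must still build
        sites = fx.make_lattice_atoms(8, spacing=2.0, jitter=0.0, seed=0)
        tess = tv.build_tessellation(sites, padding=2.0)
        assert tess.total_cell_volume() == pytest.approx(tess.box_volume, rel=1e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_volume_conservation_and_face_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        sites = fx.make_lattice_atoms(int(rng.integers(5, 51)), spacing=3.0,
                                      jitter=0.4, seed=seed)
        tess = tv.build_tessellation(sites)
        assert tess.total_cell_volume() == pytest.approx(tess.box_volume, rel=1e-3)
        for i, cell in enumerate(tess.cells):
            for f in cell.faces:
                if f.neighbor != tv.BOUNDARY:
                    assert abs(f.area - tess.face_area(f.neighbor, i)) < 1e-6

    def test_equal_weight_diagram_is_ordinary_voronoi(self):
        # with equal weights the power diagram does not depend on the weight
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 9, (12, 3))
        t1 = tv.build_tessellation([_site(p, 1.0) for p in pts], padding=3.0)
        t2 = tv.build_tessellation([_site(p, 2.9) for p in pts], padding=3.0)
        for c1, c2 in zip(t1.cells, t2.cells):
            assert c1.volume == pytest.approx(c2.volume, rel=1e-9)

    def test_scaling_law(self):
        sites = fx.make_lattice_atoms(10, spacing=3.0, jitter=0.3, seed=4)
        t1 = tv.build_tessellation(sites, padding=4.0)
        s = 2.0
        scaled = [tv.WeightedSite(tuple(np.asarray(x.center) * s), x.weight * s * s, x.owner)
                  for x in sites]
        t2 = tv.build_tessellation(scaled, padding=4.0 * s)
        for c1, c2 in zip(t1.cells, t2.cells):
            assert c2.volume == pytest.approx(c1.volume * s ** 3, rel=1e-9)
            for f1, f2 in zip(c1.faces, c2.faces):
                assert f2.neighbor == f1.neighbor
                assert f2.area == pytest.approx(f1.area * s ** 2, rel=1e-9)


class TestResidueAreas:
    def _structure(self, residues):
        return sm.Structure([sm.Subunit("X", residues)])

    def test_single_residue_surface_equals_total(self):
        res = sm.Residue("X", "1", "ALA", [sm.Atom("CA", "C", (0, 0, 0), True)])
        st = self._structure([res])
        tess = tv.build_tessellation(tv.sites_from_structure(st))
        areas = tv.residue_areas(tess, st)[("X", "1")]
        assert areas.contact == {}
        assert areas.surface == pytest.approx(areas.total, rel=1e-12)

    def test_two_residue_contact_symmetry(self):
        tess = tv.build_tessellation(two_atom_sites(), padding=5.0)
        r1 = sm.Residue("X", "1", "ALA", [sm.Atom("CA", "C", (0, 0, 0), True)])
        r2 = sm.Residue("X", "2", "GLY", [sm.Atom("CA", "C", (3, 0, 0), True)])
        areas = tv.residue_areas(tess, self._structure([r1, r2]))
        a12 = areas[("X", "1")].contact[("X", "2")]
        a21 = areas[("X", "2")].contact[("X", "1")]
        assert a12 == a21  # exact, by shared-face construction
        assert a12 == pytest.approx(100.0, rel=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_area_identity_on_random_fixtures(self, seed, toy_complex):
        sub_a, _, _ = toy_complex
        rng = np.random.default_rng(seed)
        picks = rng.choice(len(sub_a.residues), size=5, replace=False)
        st = sm.Structure([sm.Subunit("A", [sub_a.residues[i] for i in sorted(picks)])])
        tess = tv.build_tessellation(tv.sites_from_structure(st))
        areas = tv.residue_areas(tess, st)
        for a in areas.values():
            assert a.surface + sum(a.contact.values()) == pytest.approx(a.total, abs=1e-6)
            assert a.surface >= 0 and a.total >= 0
        for k, a in areas.items():
            for other, val in a.contact.items():
                assert areas[other].contact[k] == val

    def test_orphan_site_rejected(self):
        tess = tv.build_tessellation(two_atom_sites())
        lone = sm.Residue("X", "1", "ALA", [sm.Atom("CA", "C", (0, 0, 0), True)])
        with pytest.raises(ValueError, match="orphan"):
            tv.residue_areas(tess, self._structure([lone]))


class TestMonteCarloOracle:
    def test_single_cell_volume_is_box(self):
        sites = [_site((0, 0, 0), 2.0)]
        vol, se, _, _ = tv.mc_area_oracle(sites, (-2, -2, -2), (2, 2, 2),
                                          n_samples=10 ** 5, seed=0)
        assert vol[0] == pytest.approx(64.0)
        assert se[0] == 0.0

    def test_symmetric_split_and_face_area(self):
        sites = two_atom_sites()
        tess = tv.build_tessellation(sites, padding=5.0)
        vol, se, faces, fse = tv.mc_area_oracle(
            sites, tess.box_lo, tess.box_hi, n_samples=4 * 10 ** 5, seed=1)
        assert abs(vol[0] - 700.0) < 3 * se[0]
        assert abs(vol[1] - 600.0) < 3 * se[1]
        # analytic cross-section of the box at x = 2 is 10 x 10
        assert abs(faces[(0, 1)] - 100.0) < 3 * fse[(0, 1)]

    def test_sample_floor_enforced(self):
        with pytest.raises(ValueError):
            tv.mc_area_oracle(two_atom_sites(), (0, 0, 0), (1, 1, 1),
                              n_samples=10 ** 4, seed=0)


def test_tsv_export_round_numbers(toy_complex):
    sub_a, _, _ = toy_complex
    st = sm.Structure([sm.Subunit("A", sub_a.residues[:4])])
    tess = tv.build_tessellation(tv.sites_from_structure(st))
    areas = tv.residue_areas(tess, st)
    res_tsv, pair_tsv = tv.residue_areas_to_tsv(areas)
    assert res_tsv.startswith("chain\tresid\ttotal_A2\tsurface_A2")
    assert len(res_tsv.strip().splitlines()) == 5
    assert pair_tsv.startswith("chain_a")
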