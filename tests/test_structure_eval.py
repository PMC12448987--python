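import numpy as np
import pytest

from hasites.attention_store import AttentionTensor, ContactMap
from hasites.structure_eval import (
    ResidueCoordinates,
    attention_contact_spearman,
    distance_fractions,
    load_ca_coordinates,
    mann_whitney_u,
    nearest_active_distance,
    proximity_analysis,
    random_site_baseline,
)

RESIDUES = [("ALA", 1, (0.0, 0.0, 0.0)), ("GLY", 2, (3.0, 4.0, 0.0)), ("SER", 3, (6.0, 8.0, 0.0))]


def write_pdb(path, residues=RESIDUES):
    lines = []
    for serial, (resname, resid, (x, y, z)) in enumerate(residues, start=1):
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname:>3s} A{resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
        )
    path.write_text("\n".join(lines) + "\n")


def write_cif(path, residues=RESIDUES):
    header = """data_fixture
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.auth_atom_id
_atom_site.pdbx_PDB_model_num
"""
    rows = [
        f"ATOM {i} C CA . {resname} A 1 {resid} ? {x:.3f} {y:.3f} {z:.3f} 1.00 0.00 "
        f"{resid} {resname} A CA 1"
        for i, (resname, resid, (x, y, z)) in enumerate(residues, start=1)
    ]
    path.write_text(header + "\n".join(rows) + "\n")


def straight_coords(n, spacing=3.8):
    return ResidueCoordinates(
        "line", {i + 1: np.array([i * spacing, 0.0, 0.0]) for i in range(n)}
    )


class TestLoadCACoordinates:
    def test_minimal_pdb(self, tmp_path):
        write_pdb(tmp_path / "m.pdb")
        rc = load_ca_coordinates(tmp_path / "m.pdb")
        assert rc.positions() == [1, 2, 3]
        np.testing.assert_allclose(rc.coords[2], [3.0, 4.0, 0.0])

    def test_numbering_gap_preserved(self, tmp_path):
        write_pdb(tmp_path / "g.pdb", [RESIDUES[0], RESIDUES[2]])
        rc = load_ca_coordinates(tmp_path / "g.pdb")
        assert rc.positions() == [1, 3]
        assert 2 not in rc.coords

    def test_cif_and_pdb_agree(self, tmp_path):
        write_pdb(tmp_path / "m.pdb")
        write_cif(tmp_path / "m.cif")
        a = load_ca_coordinates(tmp_path / "m.pdb")
        b = load_ca_coordinates(tmp_path / "m.cif")
        assert a.positions() == b.positions()
        for p in a.positions():
            np.testing.assert_allclose(a.coords[p], b.coords[p], atol=1e-3)

    def test_sequence_check_aborts_on_mismatch(self, tmp_path):
        write_pdb(tmp_path / "m.pdb")
        rc = load_ca_coordinates(tmp_path / "m.pdb", expect_sequence="AGS")
        assert rc.positions() == [1, 2, 3]
        with pytest.raises(ValueError, match="refusing"):
            load_ca_coordinates(tmp_path / "m.pdb", expect_sequence="AAS")

    def test_no_ca_atoms(self, tmp_path):
        (tmp_path / "e.pdb").write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        )
        with pytest.raises(ValueError, match="CA"):
            load_ca_coordinates(tmp_path / "e.pdb")


class TestNearestActiveDistance:
    def test_three_four_five_triangle(self, tmp_path):
        write_pdb(tmp_path / "m.pdb")
        rc = load_ca_coordinates(tmp_path / "m.pdb")
        rep = nearest_active_distance([1], [2], rc)
        assert rep.per_site_distance[1] == pytest.approx(5.0)

    def test_overlapping_site_zero(self):
        rc = straight_coords(5)
        rep = nearest_active_distance([3], [3], rc)
        assert rep.protein_min_distance == 0.0

    def test_protein_min_is_minimum(self):
        rc = straight_coords(10)
        rep = nearest_active_distance([1, 5], [6], rc)
        assert rep.protein_min_distance == pytest.approx(3.8)

    def test_positions_without_coordinates_dropped_with_warning(self):
        rc = straight_coords(4)
        with pytest.warns(UserWarning, match="dropped"):
            rep = nearest_active_distance([1, 99], [4], rc)
        assert set(rep.per_site_distance) == {1}

    def test_nothing_usable_errors(self):
        rc = straight_coords(4)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no HA or active"):
                nearest_active_distance([99], [4], rc)

    def test_rigid_motion_invariance(self, rng):
        rc = straight_coords(8)
        rep1 = nearest_active_distance([2, 5], [7], rc)
        # random rotation + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(size=3) * 50
        moved = ResidueCoordinates(
            "m", {p: q @ c + shift for p, c in rc.coords.items()}
        )
        rep2 = nearest_active_distance([2, 5], [7], moved)
        for p in rep1.per_site_distance:
            assert rep1.per_site_distance[p] == pytest.approx(
                rep2.per_site_distance[p]
            )


class TestRandomSiteBaseline:
    def test_seeded_reproducibility(self):
        rc = straight_coords(30)
        a = random_site_baseline(rc, [5, 10], 6, seed=3)
        assert a == random_site_baseline(rc, [5, 10], 6, seed=3)

    def test_active_sites_never_sampled(self):
        rc = straight_coords(10)
        active = [1, 2, 3]
        for seed in range(5):
            d = random_site_baseline(rc, active, 7, seed=seed)
            assert len(d) == 7
            assert all(x > 0 for x in d)  # sampled sites are never active sites

    def test_insufficient_residues(self):
        rc = straight_coords(4)
        with pytest.raises(ValueError, match="sample"):
            random_site_baseline(rc, [1, 2], 3, seed=0)


class TestMannWhitney:
    def test_exact_separated_triples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_swap_symmetry(self, rng):
        a = list(rng.random(8))
        b = list(rng.random(6))
        ua, _ = mann_whitney_u(a, b)
        ub, _ = mann_whitney_u(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_large_samples_use_normal_approximation(self, rng):
        a = list(rng.normal(0, 1, 50))
        b = list(rng.normal(1, 1, 50))
        _, p = mann_whitney_u(a, b)
        assert 0 < p < 1


class TestProximityAnalysis:
    def test_full_report(self):
        rc = straight_coords(40)
        rep = proximity_analysis([5, 6], [5, 20], rc, seed=0)
        assert rep.mwu_p is not None
        assert len(rep.random_baseline) == 2
        assert rep.protein_min_distance == 0.0

    def test_distance_fractions(self):
        fr = distance_fractions([1.0, 5.0, 9.0, 30.0])
        assert fr[4.0] == 0.25 and fr[8.0] == 0.5 and fr[12.0] == 0.75


class TestAttentionContactSpearman:
    def _tensor_from_layers(self, layers):
        return AttentionTensor("p", np.stack(layers)[:, None], {"renormalized": True})

    def test_contact_aligned_layer_scores_one(self, rng):
        n = 12
        cm_vals = rng.random((n, n))
        cm_vals = (cm_vals + cm_vals.T) / 2
        cm = ContactMap("p", cm_vals / cm_vals.max())
        aligned = cm.values + 0.001
        noise = rng.random((n, n))
        t = self._tensor_from_layers([noise, aligned])
        rhos, best = attention_contact_spearman(t, cm, [2, 5])
        assert best == 1
        assert rhos[1] == pytest.approx(1.0)

    def test_reversed_layer_scores_minus_one(self, rng):
        n = 10
        cm_vals = rng.random((n, n))
        cm_vals = (cm_vals + cm_vals.T) / 2
        cm = ContactMap("p", cm_vals / cm_vals.max())
        t = self._tensor_from_layers([1.0 - cm.values])
        rhos, _ = attention_contact_spearman(t, cm, [1])
        assert rhos[0] == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self, rng):
        n = 10
        cm_vals = rng.random((n, n))
        cm_vals = (cm_vals + cm_vals.T) / 2
        cm = ContactMap("p", cm_vals / cm_vals.max())
        layer = rng.random((n, n))
        r1, _ = attention_contact_spearman(self._tensor_from_layers([layer]), cm, [3])
        r2, _ = attention_contact_spearman(
            self._tensor_from_layers([np.exp(2 * layer)]), cm, [3]
        )
        assert r1[0] == pytest.approx(r2[0])

    def test_constant_layer_reported_missing(self, rng):
        n = 8
        cm_vals = rng.random((n, n))
        cm_vals = (cm_vals + cm_vals.T) / 2
        cm = ContactMap("p", cm_vals / cm_vals.max())
        t = self._tensor_from_layers([np.full((n, n), 0.5), cm.values])
        rhos, best = attention_contact_spearman(t, cm, [1])
        assert np.isnan(rhos[0]) and best == 1

    def test_dimension_mismatch(self, rng):
        cm = ContactMap("p", np.eye(5))
        t = self._tensor_from_layers([rng.random((4, 4))])
        with pytest.raises(ValueError, match="disagree"):
            attention_contact_spearman(t, cm, [1])
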