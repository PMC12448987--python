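import numpy as np
import pytest

from hasites.convergence import identify_ha_sites
from hasites.layer_profile import build_heatmap
from hasites.similarity import ha_trajectories, protein_distance
from hasites.synthetic import (
    SyntheticSpec,
    _site_weights,
    contact_map_from_structure,
    make_attention_tensor,
    make_embeddings,
    make_family,
    make_structure,
    with_contact_final_layer,
    write_ground_truth,
)


class TestSpecValidation:
    def test_site_out_of_range(self):
        with pytest.raises(ValueError, match="planted"):
            SyntheticSpec(n=50, planted_sites=(10, 60))

    def test_conv_layer_bounds(self):
        with pytest.raises(ValueError, match="conv_layer"):
            SyntheticSpec(conv_layer=33)

    def test_concentration_bounds(self):
        with pytest.raises(ValueError, match="concentration"):
            SyntheticSpec(concentration=0.0)


class TestMakeAttentionTensor:
    def test_rows_sum_to_one(self, planted_tensor):
        sums = planted_tensor.values.sum(axis=3)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert planted_tensor.values.min() >= 0

    def test_passes_store_invariants(self, planted_tensor):
        assert planted_tensor.validate() == []

    def test_seed_determinism(self):
        a = make_attention_tensor(SyntheticSpec(seed=11))
        b = make_attention_tensor(SyntheticSpec(seed=11))
        np.testing.assert_array_equal(a.values, b.values)
        c = make_attention_tensor(SyntheticSpec(seed=12))
        assert not np.array_equal(a.values, c.values)

    def test_noise_free_profile_closed_form(self):
        """With zero noise, the convergence-layer profile matches the
        closed-form column sums of the constructed rows: the strongest
        planted site is exactly 1, the other planted sites follow the
        geometric share ratio, and the background is bounded well below."""
        spec = SyntheticSpec(noise_sigma=0.0, conv_layer=5, seed=0)
        hm = build_heatmap(make_attention_tensor(spec))
        row = hm.matrix[5]
        planted = np.asarray(spec.planted_sites) - 1
        n, c = spec.n, spec.concentration
        w = _site_weights(len(planted), spec.site_decay)
        col = c * w * n + (1 - c)  # planted column sums
        expected = col / col[0]
        np.testing.assert_allclose(row[planted], expected, atol=1e-12)
        background = np.delete(row, planted)
        bound = (1 - c) / col[0]
        np.testing.assert_allclose(background, bound, atol=1e-12)
        assert bound < 0.05

    def test_early_layers_near_uniform(self, planted_tensor, planted_spec):
        hm = build_heatmap(planted_tensor)
        early = hm.matrix[: planted_spec.conv_layer]
        assert early.min() > 0.9  # all residues near-equal importance

    def test_last_layer_without_contacts_is_banded(self, planted_spec):
        t = make_attention_tensor(planted_spec)
        last = t.values[-1, 0]
        n, w = planted_spec.n, planted_spec.band_width
        i = n // 2
        inside = last[i, i - w : i + w + 1].min()
        outside = np.delete(last[i], np.arange(i - w, i + w + 1) % n).max()
        assert inside > 10 * outside


class TestMakeFamily:
    def test_member_count_and_shared_truth(self):
        fam = make_family(4, seed=3, family_id="F")
        assert len(fam) == 4
        truths = {tuple(t.model_meta["planted_sites"]) for _, t, _ in fam}
        layers = {t.model_meta["conv_layer"] for _, t, _ in fam}
        assert len(truths) == 1 and len(layers) == 1
        assert all(r.family_id == "F" for r, _, _ in fam)

    def test_zero_jitter_members_identical_heatmaps(self):
        fam = make_family(3, trajectory_jitter=0.0, seed=5)
        hms = [build_heatmap(t).matrix for _, t, _ in fam]
        np.testing.assert_array_equal(hms[0], hms[1])
        np.testing.assert_array_equal(hms[0], hms[2])

    def test_disjoint_families_separate_in_ha_distance(self):
        """Across 5 seeds, inter-family HA distances exceed intra-family."""
        for seed in range(5):
            f1 = make_family(3, planted_sites=(20, 50, 80), conv_layer=9,
                             seed=seed, family_id="A", with_embeddings=False)
            f2 = make_family(3, planted_sites=(35, 65, 95), conv_layer=12,
                             seed=seed + 100, family_id="B", with_embeddings=False)
            sets = {}
            for _, t, _ in f1 + f2:
                hm = build_heatmap(t)
                res = identify_ha_sites(hm)
                sets[t.protein_id] = ha_trajectories(hm, res.ha_sites)
            intra, inter = [], []
            ids1 = [t.protein_id for _, t, _ in f1]
            ids2 = [t.protein_id for _, t, _ in f2]
            for i, a in enumerate(ids1):
                for b in ids1[i + 1 :]:
                    intra.append(protein_distance(sets[a], sets[b]))
                for b in ids2:
                    inter.append(protein_distance(sets[a], sets[b]))
            assert np.mean(inter) > np.mean(intra)

    def test_embeddings_share_dimension_and_cls(self):
        fam = make_family(2, seed=0)
        for _, _, emb in fam:
            assert emb is not None
            assert emb.cls_vector is not None
            assert emb.d == fam[0][2].d


class TestMakeStructure:
    def test_consecutive_ca_spacing(self):
        rc, _ = make_structure(30, (5, 20), seed=1)
        xyz = np.vstack([rc.coords[p] for p in rc.positions()])
        gaps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        np.testing.assert_allclose(gaps, 3.8, atol=1e-6)

    def test_zero_offset_active_equals_planted(self):
        _, active = make_structure(40, (7, 30), active_offset_A=0.0, seed=2)
        assert active == [7, 30]

    def test_offset_bound_holds(self):
        """Each planted site has a nearby active site within the offset."""
        for seed in range(5):
            rc, active = make_structure(60, (10, 25, 50), active_offset_A=4.0, seed=seed)
            for p in (10, 25, 50):
                dmin = min(
                    np.linalg.norm(rc.coords[p] - rc.coords[a]) for a in active
                )
                assert dmin <= 4.0 + 1e-9

    def test_too_short_chain(self):
        with pytest.raises(ValueError, match="3 residues"):
            make_structure(2, (1,), seed=0)


class TestContactMap:
    def test_symmetric_unit_interval(self):
        rc, _ = make_structure(25, (5,), seed=3)
        cm = contact_map_from_structure(rc)
        assert cm.validate() == []
        assert cm.values.max() <= 1.0

    def test_contact_final_layer_maximizes_contact_correlation(self):
        """When the last layer mirrors the contact map, the per-layer
        attention/contact correlation peaks at the last layer."""
        from hasites.structure_eval import attention_contact_spearman

        spec = SyntheticSpec(seed=4)
        rc, _ = make_structure(spec.n, spec.planted_sites, seed=4)
        spec2 = with_contact_final_layer(spec, rc)
        t = make_attention_tensor(spec2)
        cm = contact_map_from_structure(rc)
        rhos, best = attention_contact_spearman(t, cm, list(spec.planted_sites))
        assert best == spec.L - 1
        assert rhos[-1] > np.nanmax(rhos[:-1])


class TestGroundTruthSidecar:
    def test_json_round_trip(self, tmp_path, planted_spec):
        import json

        write_ground_truth(planted_spec, tmp_path / "t.json")
        data = json.loads((tmp_path / "t.json").read_text())
        assert data["planted_sites"] == list(planted_spec.planted_sites)
        assert data["conv_layer"] == planted_spec.conv_layer
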