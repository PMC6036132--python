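import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmscreen.chem_core import Molecule
from pharmscreen.pharmacophore import FeatureKind, LigandFeatureSet, PharmacophoreFeature
from pharmscreen.prioritization import (
    RDF_LENGTH,
    RDF_RADII,
    chemspace_project,
    cluster_by_pharmacophore,
    cosine_similarity,
    pains_screen,
    pharmacophore_rdf,
    shape_color_scores,
    ward_cluster,
)

KINDS = list(FeatureKind)


def cloud(mid, feats):
    return LigandFeatureSet(mid, 0, [PharmacophoreFeature(k, c) for k, c in feats])


def random_cloud(rng, mid="f", n=None):
    n = n or int(rng.integers(2, 7))
    return cloud(mid, [(KINDS[rng.integers(len(KINDS))], rng.uniform(-6, 6, 3))
                       for _ in range(n)])


class TestRDF:
    def test_two_acceptors_peak_at_their_distance(self):
        fs = cloud("x", [(FeatureKind.HBA, [0, 0, 0]), (FeatureKind.HBA, [3.0, 0, 0])])
        v = pharmacophore_rdf(fs)
        assert v.shape == (RDF_LENGTH,)
        assert (v >= 0).all()
        blocks = set(np.nonzero(v > 1e-6)[0] // len(RDF_RADII))
        assert len(blocks) == 1                       # only the HBA-HBA block
        assert RDF_RADII[np.argmax(v) % len(RDF_RADII)] == pytest.approx(3.0)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        fs = random_cloud(rng)
        R = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        t = rng.normal(size=3) * 8
        moved = cloud("m", [(f.kind, f.center @ R.T + t) for f in fs.features])
        np.testing.assert_allclose(pharmacophore_rdf(fs), pharmacophore_rdf(moved),
                                   atol=1e-9)

    def test_feature_order_invariance(self, rng):
        fs = random_cloud(rng)
        perm = cloud("p", [(f.kind, f.center) for f in reversed(fs.features)])
        np.testing.assert_allclose(pharmacophore_rdf(fs), pharmacophore_rdf(perm))

    def test_doubling_distances_shifts_peaks(self):
        fs = cloud("a", [(FeatureKind.HBA, [0, 0, 0]), (FeatureKind.HBA, [2.5, 0, 0])])
        doubled = cloud("b", [(FeatureKind.HBA, [0, 0, 0]), (FeatureKind.HBA, [5.0, 0, 0])])
        va, vb = pharmacophore_rdf(fs), pharmacophore_rdf(doubled)
        assert RDF_RADII[np.argmax(va) % len(RDF_RADII)] == pytest.approx(2.5)
        assert RDF_RADII[np.argmax(vb) % len(RDF_RADII)] == pytest.approx(5.0)

    def test_single_feature_zero_vector(self):
        with pytest.warns(UserWarning, match="single-feature"):
            v = pharmacophore_rdf(cloud("s", [(FeatureKind.HBA, [0, 0, 0])]))
        assert not v.any()


class TestCosine:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 0.5])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_blocks(self):
        assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == 0.0

    def test_closed_form(self):
        assert cosine_similarity(np.array([1.0, 1, 0]),
                                 np.array([1.0, 0, 0])) == pytest.approx(0.7071, abs=1e-4)

    def test_zero_vector_warns(self):
        with pytest.warns(UserWarning):
            assert cosine_similarity(np.zeros(3), np.ones(3)) == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10**9))
    def test_bounded_on_rdf_vectors(self, seed):
        rng = np.random.default_rng(seed)
        a = pharmacophore_rdf(random_cloud(rng, "a"))
        b = pharmacophore_rdf(random_cloud(rng, "b"))
        assert 0.0 <= cosine_similarity(a, b) <= 1.0


class TestPharmacophoreClustering:
    def test_duplicates_share_cluster(self, rng):
        fs = random_cloud(rng, "a", n=4)
        dup = cloud("b", [(f.kind, f.center) for f in fs.features])
        other = cloud("c", [(FeatureKind.AROMATIC, [0, 0, 0]),
                            (FeatureKind.AROMATIC, [8.0, 0, 0])])
        ca = cluster_by_pharmacophore([[fs], [dup], [other]], threshold=0.5)
        assert ca.labels["a"] == ca.labels["b"]

    def test_disjoint_kind_families_split(self):
        fam1 = [[cloud(f"x{i}", [(FeatureKind.HBA, [0, 0, 0]),
                                 (FeatureKind.HBA, [3.0 + 0.05 * i, 0, 0])])]
                for i in range(3)]
        fam2 = [[cloud(f"y{i}", [(FeatureKind.HYDROPHOBIC, [0, 0, 0]),
                                 (FeatureKind.HYDROPHOBIC, [3.0 + 0.05 * i, 0, 0])])]
                for i in range(3)]
        ca = cluster_by_pharmacophore(fam1 + fam2, threshold=0.9)
        xs = {ca.labels[f"x{i}"] for i in range(3)}
        ys = {ca.labels[f"y{i}"] for i in range(3)}
        assert len(xs) == 1 and len(ys) == 1 and xs != ys

    def test_singleton_library(self, rng):
        ca = cluster_by_pharmacophore([[random_cloud(rng, "only")]])
        assert ca.labels == {"only": 1}


class TestShapeScores:
    def test_self_combo_is_exactly_two(self, rng):
        coords = rng.normal(size=(15, 3)) * 3
        feats = [PharmacophoreFeature(FeatureKind.HBA, coords[0]),
                 PharmacophoreFeature(FeatureKind.HYDROPHOBIC, coords[7])]
        s = shape_color_scores(coords, feats, coords, feats)
        assert s.shape_tanimoto == 1.0
        assert s.color_tanimoto == 1.0
        assert s.tanimoto_combo == 2.0

    def test_distant_molecules_zero(self, rng):
        coords = rng.normal(size=(10, 3))
        feats = [PharmacophoreFeature(FeatureKind.HBA, coords[0])]
        far = coords + 50.0
        far_feats = [PharmacophoreFeature(FeatureKind.HBA, far[0])]
        s = shape_color_scores(coords, feats, far, far_feats)
        assert s.tanimoto_combo < 1e-6

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(9, 3)) + 0.5
        fa = [PharmacophoreFeature(FeatureKind.HBD, a[0])]
        fb = [PharmacophoreFeature(FeatureKind.HBD, b[0])]
        s1 = shape_color_scores(a, fa, b, fb)
        s2 = shape_color_scores(b, fb, a, fa)
        assert s1.shape_tanimoto == pytest.approx(s2.shape_tanimoto, rel=1e-12)
        assert s1.color_tanimoto == pytest.approx(s2.color_tanimoto, rel=1e-12)

    def test_bounds(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=(6, 3)) * 2, rng.normal(size=(7, 3)) * 2
            s = shape_color_scores(a, [], b, [])
            assert 0.0 <= s.shape_tanimoto <= 1.0
            assert 0.0 <= s.tanimoto_combo <= 2.0

    def test_refinement_recovers_displaced_pose(self, rng):
        coords = rng.normal(size=(10, 3)) * 2
        feats = [PharmacophoreFeature(FeatureKind.HBA, coords[0])]
        shifted = coords + [1.5, 0.0, 0.0]
        sf = [PharmacophoreFeature(FeatureKind.HBA, shifted[0])]
        plain = shape_color_scores(coords, feats, shifted, sf, refine=False)
        refined = shape_color_scores(coords, feats, shifted, sf, refine=True)
        assert refined.tanimoto_combo >= plain.tanimoto_combo
        assert refined.tanimoto_combo > 1.5


def synthetic_descriptor_table(n=40, seed=0):
    """Descriptor table whose variance is dominated by molecular size."""
    rng = np.random.default_rng(seed)
    size = rng.uniform(10, 60, n)
    df = pd.DataFrame({
        "molecular_weight": size * 13 + rng.normal(0, 5, n),
        "heavy_atom_count": size + rng.normal(0, 1, n),
        "rotatable_bonds": size / 5 + rng.normal(0, 1, n),
        "logp_estimate": rng.normal(3, 1, n),
        "aromatic_atom_fraction": rng.uniform(0, 1, n),
        "tpsa": rng.normal(80, 10, n),
    }, index=[f"m{i}" for i in range(n)])
    return df


class TestChemSpace:
    def test_loadings_orthonormal_and_variance_sorted(self):
        cs = chemspace_project(synthetic_descriptor_table())
        gram = cs.loadings.T @ cs.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert (np.diff(cs.explained_variance_ratio) <= 1e-12).all()

    def test_pc1_tracks_size(self):
        df = synthetic_descriptor_table()
        cs = chemspace_project(df)
        corr = np.corrcoef(cs.scores["PC1"], df["molecular_weight"])[0, 1]
        assert corr > 0.9          # sign convention makes it positive, not just large

    def test_constant_column_dropped(self):
        df = synthetic_descriptor_table()
        df["net_charge"] = 0.0
        with pytest.warns(UserWarning, match="constant"):
            cs = chemspace_project(df)
        assert "net_charge" not in cs.columns

    def test_too_small_input_fatal(self):
        with pytest.raises(ValueError):
            chemspace_project(synthetic_descriptor_table(n=3))


class TestWard:
    def test_k_equals_n_gives_singletons(self):
        df = synthetic_descriptor_table(n=8)
        cs = chemspace_project(df)
        labels = ward_cluster(cs.scores, k=8)
        assert len(set(labels.values())) == 8

    def test_two_blobs_split_perfectly(self, rng):
        a = rng.normal(0, 0.3, size=(15, 3))
        b = rng.normal(8, 0.3, size=(15, 3))
        scores = pd.DataFrame(np.vstack([a, b]),
                              index=[f"p{i}" for i in range(30)],
                              columns=["PC1", "PC2", "PC3"])
        labels = ward_cluster(scores, k=2)
        la = {labels[f"p{i}"] for i in range(15)}
        lb = {labels[f"p{i}"] for i in range(15, 30)}
        assert len(la) == 1 and len(lb) == 1 and la != lb

    def test_permutation_invariance_up_to_relabeling(self, rng):
        pts = rng.normal(size=(20, 3))
        idx = [f"m{i}" for i in range(20)]
        scores = pd.DataFrame(pts, index=idx, columns=["PC1", "PC2", "PC3"])
        perm = rng.permutation(20)
        labels_a = ward_cluster(scores, k=4)
        labels_b = ward_cluster(scores.iloc[perm], k=4)
        # same partition: group co-membership is preserved
        for i in range(20):
            for j in range(i + 1, 20):
                same_a = labels_a[idx[i]] == labels_a[idx[j]]
                same_b = labels_b[idx[i]] == labels_b[idx[j]]
                assert same_a == same_b

    def test_k_larger_than_n_fatal(self):
        scores = pd.DataFrame(np.zeros((3, 3)), columns=["PC1", "PC2", "PC3"])
        with pytest.raises(ValueError, match="exceeds"):
            ward_cluster(scores, k=9)


class TestPAINS:
    def test_catechol_flagged(self):
        # nordihydroguaiaretic acid carries two catechols, a canonical alert
        ndga = Molecule.from_smiles("CC(Cc1ccc(O)c(O)c1)C(C)Cc1ccc(O)c(O)c1", "ndga")
        res = pains_screen(ndga)
        assert not res.passed
        assert any("catechol" in a for a in res.alerts)
        # independent substructure oracle: the catechol motif is present
        from rdkit import Chem

        assert ndga.rdmol.HasSubstructMatch(Chem.MolFromSmarts("c1ccc(O)c(O)c1"))

    def test_octane_passes(self):
        assert pains_screen(Molecule.from_smiles("CCCCCCCC", "octane")).passed

    def test_flag_is_conformer_independent(self, lca):
        # the filter consumes 2D structure only; conformers play no role
        with_confs = pains_screen(lca)
        bare = pains_screen(Molecule.from_smiles(lca.smiles(), "lca_bare"))
        assert with_confs.alerts == bare.alerts
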