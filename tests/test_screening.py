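import itertools

import numpy as np
import pytest

from pharmscreen.pharmacophore import (
    FeatureKind,
    LigandFeatureSet,
    PharmacophoreFeature,
    PharmacophoreModel,
)
from pharmscreen.screening import (
    compute_enrichment,
    enumerate_correspondences,
    fit_score,
    kabsch_align,
    match,
    screen_library,
)

KINDS = list(FeatureKind)


def cloud(mid, feats, tol=1.5):
    return LigandFeatureSet(mid, 0, [PharmacophoreFeature(k, c, tol) for k, c in feats])


def model_of(feats, name="m", tol=1.5):
    return PharmacophoreModel(name, [PharmacophoreFeature(k, c, tol) for k, c in feats])


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        tr, rmsd = kabsch_align(pts, pts)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        tr, rmsd = kabsch_align(pts, pts + [1.0, -2.0, 3.0])
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-7)
        np.testing.assert_allclose(tr.translation, [-1.0, 2.0, -3.0], atol=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        ref, mov = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        tr, _ = kabsch_align(ref, mov)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_displaced_square_matches_grid_search_oracle(self):
        """Unit square vs square with one corner displaced 0.4 Å: the Kabsch
        RMSD equals a dense in-plane rotation grid search minimum."""
        ref = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        mov = ref.copy()
        mov[2] += [0.4 / np.sqrt(2), 0.4 / np.sqrt(2), 0.0]
        _, rmsd = kabsch_align(ref, mov)
        best = np.inf
        refc = ref - ref.mean(axis=0)
        movc = mov - mov.mean(axis=0)
        for theta in np.linspace(0, 2 * np.pi, 200001):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            best = min(best, np.sqrt(np.mean(np.sum((movc @ R.T - refc) ** 2, axis=1))))
        assert rmsd == pytest.approx(best, abs=1e-3)

    def test_under_three_pairs_translation_only(self):
        with pytest.warns(UserWarning, match="translation-only"):
            tr, _ = kabsch_align(np.array([[0., 0, 0], [1, 0, 0]]),
                                 np.array([[5., 0, 0], [6, 0, 0]]))
        np.testing.assert_allclose(tr.rotation, np.eye(3))


def brute_force_correspondences(model, ligand, max_omitted=0):
    """Oracle: all injective kind-consistent assignments covering all mandatory
    features except <= max_omitted, filtered by the pairwise-distance rule."""
    mand = model.mandatory_features
    lk = ligand.kinds()
    lc = ligand.centers()
    out = set()
    n = len(mand)
    for n_omit in range(max_omitted + 1):
        for kept in itertools.combinations(range(n), n - n_omit):
            pools = [[j for j, k in enumerate(lk) if k is mand[i].kind] for i in kept]
            for assign in itertools.product(*pools):
                if len(set(assign)) < len(assign):
                    continue
                ok = True
                for (x, i), (y, j) in itertools.combinations(zip(kept, assign), 2):
                    dm = np.linalg.norm(mand[x].center - mand[y].center)
                    dl = np.linalg.norm(lc[i] - lc[j])
                    if abs(dm - dl) > 2 * max(mand[x].tolerance, mand[y].tolerance):
                        ok = False
                        break
                if ok:
                    out.add(tuple(zip(kept, assign)))
    return out


def random_instance(rng, n_model=4, n_ligand=6, span=8.0):
    mf = [(KINDS[rng.integers(len(KINDS))], rng.uniform(0, span, 3)) for _ in range(n_model)]
    while True:
        try:
            m = model_of(mf)
            break
        except ValueError:
            mf = [(k, c + rng.normal(0, 0.5, 3)) for k, c in mf]
    lf = [(KINDS[rng.integers(len(KINDS))], rng.uniform(0, span, 3)) for _ in range(n_ligand)]
    return m, cloud("lig", lf)


class TestCorrespondences:
    def test_missing_kind_empty(self):
        m = model_of([(FeatureKind.HBA, [0, 0, 0]), (FeatureKind.HBA, [3, 0, 0]),
                      (FeatureKind.HYDROPHOBIC, [0, 3, 0])])
        lig = cloud("l", [(FeatureKind.HYDROPHOBIC, [0, 0, 0]),
                          (FeatureKind.HYDROPHOBIC, [3, 0, 0])])
        assert enumerate_correspondences(m, lig, 0) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, lig = random_instance(rng)
        got = {c.pairs for c in enumerate_correspondences(m, lig, 0)}
        assert got == brute_force_correspondences(m, lig, 0)

    def test_max_omitted_monotone(self, rng):
        m, lig = random_instance(rng, n_model=4, n_ligand=7)
        c0 = {c.pairs for c in enumerate_correspondences(m, lig, 0)}
        c1 = {c.pairs for c in enumerate_correspondences(m, lig, 1)}
        # every full-coverage correspondence survives at the looser setting
        assert c0 <= c1


class TestMatch:
    def test_exact_ligand_matches_reference_model(self):
        from pharmscreen.pharmacophore import reference_model

        m = reference_model("BAMS22")
        lig = LigandFeatureSet("exact", 0, [PharmacophoreFeature(f.kind, f.center)
                                            for f in m.mandatory_features])
        res = match(PharmacophoreModel(m.name, m.features), lig)
        assert res is not None
        assert res.omitted_count == 0
        assert res.feature_rmsd == pytest.approx(0.0, abs=1e-6)

    def test_fit_score_formula(self):
        assert fit_score(4, 0.0) == 40.0
        assert fit_score(7, 1.0) == 67.0

    def test_optional_match_raises_score(self, planted_model):
        from dataclasses import replace

        opt_model = PharmacophoreModel("opt", planted_model.features + [
            PharmacophoreFeature(FeatureKind.HBD, [2.0, -3.0, 2.0], optional=True)])
        base = [PharmacophoreFeature(f.kind, f.center) for f in planted_model.features]
        lig_plain = LigandFeatureSet("p", 0, base)
        lig_opt = LigandFeatureSet("o", 0, base + [
            PharmacophoreFeature(FeatureKind.HBD, [2.0, -3.0, 2.0])])
        s_plain = match(opt_model, lig_plain).fit_score
        s_opt = match(opt_model, lig_opt).fit_score
        assert s_opt > s_plain

    def test_rigid_invariance(self, planted_model, rng):
        from scipy.spatial.transform import Rotation

        base = [PharmacophoreFeature(f.kind, f.center + rng.normal(0, 0.2, 3))
                for f in planted_model.features]
        lig = LigandFeatureSet("l", 0, base)
        res = match(planted_model, lig)
        R = Rotation.random(random_state=np.random.RandomState(9)).as_matrix()
        t = rng.normal(size=3) * 10
        moved = LigandFeatureSet("l2", 0, [PharmacophoreFeature(f.kind, f.center @ R.T + t)
                                           for f in base])
        res2 = match(planted_model, moved)
        assert (res is None) == (res2 is None)
        assert res.fit_score == pytest.approx(res2.fit_score, abs=1e-6)

    def test_shrinking_tolerance_never_creates_hits(self, planted_model, planted_library):
        tight = PharmacophoreModel("tight", [
            PharmacophoreFeature(f.kind, f.center, f.tolerance * 0.4, f.optional)
            for f in planted_model.features])
        subset = planted_library.feature_sets[:60]
        hits_normal = {fs.molecule_id for fs in subset if match(planted_model, fs)}
        hits_tight = {fs.molecule_id for fs in subset if match(tight, fs)}
        assert hits_tight <= hits_normal

    def test_omitted_monotonicity_of_hits(self, planted_model, planted_library):
        subset = planted_library.feature_sets[:40]
        h0 = {fs.molecule_id for fs in subset if match(planted_model, fs, 0)}
        h1 = {fs.molecule_id for fs in subset if match(planted_model, fs, 1)}
        assert h0 <= h1

    @pytest.mark.parametrize("seed", range(40))
    def test_pruned_matcher_equals_exhaustive_oracle(self, seed):
        """Best fit score from the pruned matcher equals exhaustive
        enumeration over every injective kind-consistent correspondence."""
        rng = np.random.default_rng(1000 + seed)
        m, lig = random_instance(rng, n_model=4, n_ligand=6, span=6.0)
        res = match(m, lig)
        best = None
        mand = m.mandatory_features
        pools = [[j for j, k in enumerate(lig.kinds()) if k is f.kind] for f in mand]
        for assign in itertools.product(*pools):
            if len(set(assign)) < len(assign):
                continue
            tr, _ = kabsch_align(np.array([f.center for f in mand]),
                                 lig.centers()[list(assign)])
            moved = tr.apply(lig.centers())
            d = [np.linalg.norm(moved[j] - f.center) for f, j in zip(mand, assign)]
            if any(di > f.tolerance for f, di in zip(mand, d)):
                continue
            rmsd = float(np.sqrt(np.mean(np.square(d))))
            score = fit_score(len(assign), rmsd)
            if best is None or score > best:
                best = score
        if best is None:
            assert res is None
        else:
            assert res is not None
            assert res.fit_score == pytest.approx(best, abs=1e-9)


class TestScreenLibrary:
    def test_empty_library(self, planted_model):
        rep = screen_library([planted_model], [])
        assert rep.hits == [] and rep.results == {}

    def test_parallel_union(self, planted_model, planted_library):
        other = PharmacophoreModel("shifted", [
            PharmacophoreFeature(f.kind, f.center + 100.0) for f in planted_model.features])
        subset = planted_library.feature_sets[:30]
        single_a = screen_library([planted_model], subset)
        single_b = screen_library([other], subset)
        both = screen_library([planted_model, other], subset)
        assert set(both.hits) == set(single_a.hits) | set(single_b.hits)

    def test_planted_separation(self, planted_model, planted_library):
        rep = screen_library([planted_model], planted_library.feature_sets)
        hits = set(rep.hits)
        assert hits == {fs.molecule_id for fs in planted_library.positives}

    def test_deduplication_by_canonical_structure(self, lca):
        """The same structure under two identifiers collapses to one entry in
        the deduplicated hit union."""
        from pharmscreen.chem_core import Molecule
        from pharmscreen.pharmacophore import build_shared_model, perceive_features

        model = build_shared_model([perceive_features(lca, 0)], name="self")
        twin = Molecule(identifier="lca_other_db", rdmol=lca.rdmol,
                        conformers=lca.conformers, source_tag="db2")
        rep = screen_library([model], [lca, twin])
        assert len(rep.hits) == 2
        assert len(rep.deduplicated_hits) == 1


class TestEnrichment:
    def test_bile_acid_model_validation_numbers(self):
        # 20 retrieved actives, 2 decoy false positives in an 18,112-compound library
        m = compute_enrichment(tp=20, fp=2, tn=18090, fn=0)
        assert m.n_database == 18112 and m.n_actives == 20
        assert round(m.enrichment_factor, 1) == 823.3
        assert m.sensitivity == 1.0

    def test_triterpene_model_validation_numbers(self):
        m = compute_enrichment(tp=13, fp=3, tn=18089, fn=3)
        assert m.n_database == 18108 and m.n_actives == 16
        assert round(m.enrichment_factor, 1) == 919.5
        assert round(m.sensitivity, 2) == 0.81

    def test_select_everything_gives_ef_one(self):
        m = compute_enrichment(tp=10, fp=990, tn=0, fn=0)
        assert m.enrichment_factor == pytest.approx(1.0)

    def test_nothing_retrieved_ef_undefined(self):
        m = compute_enrichment(tp=0, fp=0, tn=980, fn=20)
        assert m.enrichment_factor is None

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            compute_enrichment(-1, 0, 0, 5)
        with pytest.raises(ValueError):
            compute_enrichment(0, 3, 7, 0)
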