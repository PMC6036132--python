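"""Post-screening hit triage.

Four independent views rank and group virtual hits:

* pharmacophore RDF clustering — each conformer's feature set is encoded as a
  radial-distribution-function vector (one Gaussian-smoothed distance
  histogram per unordered feature-kind pair); molecules are compared by the
  cosine similarity of these vectors and grouped by complete-linkage
  agglomeration;
* Gaussian shape + chemistry ("color") TanimotoCombo scoring against a query
  pose, each component in [0, 1] so the combined score lies in [0, 2];
* descriptor-space PCA with interpretable sign conventions (PC1 ~ size,
  PC2 ~ aromaticity/conjugation, PC3 ~ lipophilicity) followed by Ward
  minimum-variance grouping of the first three component scores;
* PAINS substructure alerts (published families A/B/C) flagging likely
  promiscuous hitters.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .chem_core import Molecule
from .pharmacophore import FeatureKind, LigandFeatureSet, perceive_features

logger = logging.getLogger(__name__)

# RDF grid: 60 radii 0.25-15.0 Å (step 0.25) per unordered kind pair (21
# blocks), Gaussian smoothing width B = 4 Å^-2 -> 1260 entries.
RDF_RADII = np.arange(1, 61) * 0.25
RDF_B = 4.0
_KINDS = sorted(FeatureKind, key=lambda k: k.value)
RDF_KIND_PAIRS = list(itertools.combinations_with_replacement(_KINDS, 2))
RDF_LENGTH = len(RDF_KIND_PAIRS) * len(RDF_RADII)


def pharmacophore_rdf(featureset: LigandFeatureSet) -> np.ndarray:
    """Radial distribution function vector of a feature set.

    Block (k1, k2) at radius r accumulates ``exp(-B (r - d_ij)^2)`` over all
    feature pairs with kinds {k1, k2}.  Invariant to rigid motion and feature
    ordering; a single-feature set gives a zero vector with a warning.
    """
    if len(featureset.features) == 0:
        raise ValueError("feature set is empty")
    vec = np.zeros(RDF_LENGTH)
    if len(featureset.features) == 1:
        warnings.warn(f"single-feature set {featureset.molecule_id!r}: zero RDF vector",
                      stacklevel=2)
        return vec
    block_index = {pair: i for i, pair in enumerate(RDF_KIND_PAIRS)}
    nbins = len(RDF_RADII)
    for fa, fb in itertools.combinations(featureset.features, 2):
        d = float(np.linalg.norm(fa.center - fb.center))
        pair = tuple(sorted((fa.kind, fb.kind), key=lambda k: k.value))
        b = block_index[pair]
        vec[b * nbins:(b + 1) * nbins] += np.exp(-RDF_B * (RDF_RADII - d) ** 2)
    return vec


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two RDF vectors; in [0, 1] because entries
    are non-negative.  A zero vector gives 0 with a warning."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("cosine similarity with a zero vector defined as 0", stacklevel=2)
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


@dataclass(eq=False)
class ClusterAssignment:
    labels: dict[str, int]
    linkage_method: str
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def cluster_by_pharmacophore(library: list[Molecule] | list[list[LigandFeatureSet]],
                             n_conformers: int = 3, threshold: float = 0.9,
                             linkage_method: str = "complete") -> ClusterAssignment:
    """Group molecules by pharmacophore similarity.

    Molecule-pair similarity is the maximum RDF cosine over their conformer
    feature sets (at most ``n_conformers`` per molecule); distance is
    ``1 − similarity``; complete-linkage agglomeration is cut at ``threshold``.
    """
    if not library:
        raise ValueError("library is empty")
    ids: list[str] = []
    rdfs: list[list[np.ndarray]] = []
    for item in library:
        if isinstance(item, Molecule):
            n = min(n_conformers, max(item.n_conformers, 1))
            sets = [perceive_features(item, i) for i in range(min(n, item.n_conformers))] \
                if item.n_conformers else []
            if not sets:
                raise ValueError(f"molecule {item.identifier!r} has no conformers")
            ids.append(item.identifier)
        else:
            sets = list(item)[:n_conformers]
            ids.append(sets[0].molecule_id)
        rdfs.append([pharmacophore_rdf(s) for s in sets])

    n = len(ids)
    if n == 1:
        return ClusterAssignment({ids[0]: 1}, linkage_method, threshold)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim = max(cosine_similarity(a, b) for a in rdfs[i] for b in rdfs[j])
            dist[i, j] = dist[j, i] = 1.0 - sim
    Z = linkage(squareform(dist, checks=False), method=linkage_method)
    labels = fcluster(Z, t=threshold, criterion="distance")
    return ClusterAssignment(dict(zip(ids, (int(l) for l in labels))), linkage_method, threshold)


# --------------------------------------------------------------------------
# Gaussian shape + color scoring
# --------------------------------------------------------------------------

#: Gaussian amplitude and width chosen so a lone atom's Gaussian volume equals
#: a 1.7 Å hard sphere.
_SHAPE_P = 2.7
_SHAPE_ALPHA = np.pi * (_SHAPE_P / (4.0 / 3.0 * np.pi * 1.7 ** 3)) ** (2.0 / 3.0)
#: Color feature Gaussians: exp(-r² / (2σ²)) with σ = 1.0 Å.
_COLOR_BETA = 0.5


@dataclass(frozen=True)
class ShapeScores:
    shape_tanimoto: float
    color_tanimoto: float

    @property
    def tanimoto_combo(self) -> float:
        return self.shape_tanimoto + self.color_tanimoto


def _gaussian_overlap(xa: np.ndarray, xb: np.ndarray, p: float, alpha: float) -> float:
    """Pairwise-product Gaussian overlap volume between two atom sets."""
    if len(xa) == 0 or len(xb) == 0:
        return 0.0
    d2 = np.sum((xa[:, None, :] - xb[None, :, :]) ** 2, axis=-1)
    pref = p * p * (np.pi / (2.0 * alpha)) ** 1.5
    return float(np.sum(pref * np.exp(-0.5 * alpha * d2)))


def _color_overlap(fa: list, fb: list) -> float:
    tot = 0.0
    for f1 in fa:
        for f2 in fb:
            if f1.kind is f2.kind:
                d2 = float(np.sum((f1.center - f2.center) ** 2))
                tot += (np.pi / (2.0 * _COLOR_BETA)) ** 1.5 * np.exp(-0.5 * _COLOR_BETA * d2)
    return tot


def shape_color_scores(ref_coords: np.ndarray, ref_features: list,
                       fit_coords: np.ndarray, fit_features: list,
                       refine: bool = False) -> ShapeScores:
    """Gaussian shape Tanimoto plus same-kind feature ("color") Tanimoto.

    Conformers are compared in the poses given (the pipeline feeds
    pharmacophore-alignment poses); heavy atoms only, pairwise-overlap
    approximation (triple overlaps ignored).  Both components are symmetric
    and equal 1 on self, so the combined score is bounded by 2 and attains it
    on self-comparison.  With ``refine=True`` a bounded local rigid
    optimization (<= 200 iterations) of the fitted pose maximizes the combo.
    """
    ref_coords = np.asarray(ref_coords, float).reshape(-1, 3)
    fit_coords = np.asarray(fit_coords, float).reshape(-1, 3)

    def combo_for(fitc: np.ndarray, fitf) -> ShapeScores:
        vaa = _gaussian_overlap(ref_coords, ref_coords, _SHAPE_P, _SHAPE_ALPHA)
        vbb = _gaussian_overlap(fitc, fitc, _SHAPE_P, _SHAPE_ALPHA)
        vab = _gaussian_overlap(ref_coords, fitc, _SHAPE_P, _SHAPE_ALPHA)
        shape = vab / (vaa + vbb - vab) if (vaa + vbb - vab) > 0 else 0.0
        caa = _color_overlap(ref_features, ref_features)
        cbb = _color_overlap(fitf, fitf)
        cab = _color_overlap(ref_features, fitf)
        if caa + cbb == 0.0:
            color = 1.0  # identical absence of features
        elif caa + cbb - cab <= 0:
            color = 1.0
        else:
            color = cab / (caa + cbb - cab)
        return ShapeScores(float(shape), float(color))

    if not refine:
        return combo_for(fit_coords, fit_features)

    from dataclasses import replace

    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    fc = fit_coords.mean(axis=0)

    def moved(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        return (fit_coords - fc) @ rot.T + fc + params[3:]

    def objective(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        feats = [replace(f, center=(f.center - fc) @ rot.T + fc + params[3:])
                 for f in fit_features]
        s = combo_for(moved(params), feats)
        return -s.tanimoto_combo

    res = minimize(objective, np.zeros(6), method="Nelder-Mead",
                   options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-6})
    rot = Rotation.from_rotvec(res.x[:3]).as_matrix()
    feats = [type(f)(f.kind, (f.center - fc) @ rot.T + fc + res.x[3:], f.tolerance, f.optional)
             for f in fit_features]
    return combo_for(moved(res.x), feats)


# --------------------------------------------------------------------------
# chemical-space PCA + Ward grouping
# --------------------------------------------------------------------------

@dataclass(eq=False)
class ChemSpaceModel:
    """Standardized-descriptor PCA with interpretable sign conventions."""

    columns: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray            # (n_descriptors, n_components), orthonormal
    explained_variance_ratio: np.ndarray
    scores: "object"                # DataFrame, molecules x PCs

    def transform(self, descriptors) -> np.ndarray:
        X = np.asarray(descriptors[self.columns], float)
        return (X - self.means) / self.scales @ self.loadings


def chemspace_project(descriptors) -> ChemSpaceModel:
    """Project a descriptor table (DataFrame, >= 4 molecules x >= 4 descriptors)
    onto principal components of the z-scored matrix.

    Sign conventions: PC1 is oriented so the molecular-weight loading is
    positive (size axis), PC2 so the aromatic-fraction loading is positive
    (aromaticity/conjugation axis), PC3 so the logP loading is positive
    (lipophilicity axis).  Constant descriptor columns are dropped with a
    warning.
    """
    import pandas as pd

    df = pd.DataFrame(descriptors).astype(float)
    if df.shape[0] < 4 or df.shape[1] < 4:
        raise ValueError("need at least 4 molecules and 4 descriptors")
    std = df.std(ddof=0)
    constant = list(std.index[std == 0.0])
    if constant:
        warnings.warn(f"dropping constant descriptor columns: {constant}", stacklevel=2)
        df = df.drop(columns=constant)
        if df.shape[1] < 4:
            raise ValueError("fewer than 4 varying descriptors remain")

    from sklearn.decomposition import PCA

    means = df.mean().to_numpy()
    scales = df.std(ddof=0).to_numpy()
    Z = (df.to_numpy() - means) / scales
    n_comp = min(Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()

    sign_anchor = {0: "molecular_weight", 1: "aromatic_atom_fraction", 2: "logp_estimate"}
    cols = list(df.columns)
    for pc, col in sign_anchor.items():
        if pc < loadings.shape[1] and col in cols:
            if loadings[cols.index(col), pc] < 0:
                loadings[:, pc] *= -1
                scores[:, pc] *= -1

    score_df = pd.DataFrame(scores[:, :min(3, n_comp)], index=df.index,
                            columns=[f"PC{i+1}" for i in range(min(3, n_comp))])
    return ChemSpaceModel(cols, means, scales, loadings,
                          pca.explained_variance_ratio_, score_df)


def ward_cluster(scores, k: int = 9) -> dict[str, int]:
    """Ward minimum-variance grouping of PC1-PC3 coordinates (Euclidean
    distances) into exactly ``k`` groups."""
    import pandas as pd

    df = pd.DataFrame(scores)
    if k > len(df):
        raise ValueError(f"k={k} exceeds the number of molecules ({len(df)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    Z = linkage(df.to_numpy(), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return {str(idx): int(l) for idx, l in zip(df.index, labels)}


# --------------------------------------------------------------------------
# PAINS
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PAINSResult:
    molecule_id: str
    alerts: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return len(self.alerts) == 0


def pains_screen(mol: Molecule) -> PAINSResult:
    """Match the published PAINS alert families A/B/C against the 2D structure
    (conformer-independent)."""
    from rdkit.Chem import FilterCatalog

    params = FilterCatalog.FilterCatalogParams()
    for fam in (FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS_A,
                FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS_B,
                FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS_C):
        params.AddCatalog(fam)
    catalog = FilterCatalog.FilterCatalog(params)
    matches = catalog.GetMatches(mol.rdmol)
    return PAINSResult(mol.identifier, tuple(m.GetDescription() for m in matches))
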