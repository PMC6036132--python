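"""Pharmacophore matching, library screening and enrichment metrics.

Matching aligns ligand feature sets onto a model by least-squares rigid
superposition over enumerated feature correspondences, accepts an alignment
when every matched pair falls within the model feature's tolerance sphere and
no ligand heavy atom enters an exclusion volume, and keeps the best-scoring
conformer ("best matching conformation" retrieval).  The fit score,
``10·matched − 3·feature_rmsd``, is this package's own documented scoring
function: strictly increasing in matched features, decreasing in geometric
error.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem_core import Molecule
from .pharmacophore import (
    FeatureKind,
    LigandFeatureSet,
    PharmacophoreModel,
    perceive_ensemble,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Transform",
    "Correspondence",
    "MatchResult",
    "ScreenReport",
    "EnrichmentMetrics",
    "kabsch_align",
    "enumerate_correspondences",
    "match",
    "fit_score",
    "screen_library",
    "compute_enrichment",
]


@dataclass(eq=False)
class Transform:
    """Rigid transform x -> R @ x + t (rotation proper, translation in Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class Correspondence:
    """Pairs of (model feature index, ligand feature index), kind-consistent,
    one-to-one on both sides."""

    pairs: tuple[tuple[int, int], ...]


@dataclass(eq=False)
class MatchResult:
    correspondence: Correspondence
    transform: Transform
    matched_count: int
    omitted_count: int
    feature_rmsd: float
    fit_score: float
    exclusion_violations: int
    conformer_index: int
    molecule_id: str = ""
    model_name: str = ""


def kabsch_align(reference: np.ndarray, moving: np.ndarray) -> tuple[Transform, float]:
    """Least-squares rigid superposition of ``moving`` onto ``reference``.

    Returns the optimal proper rotation + translation and the residual RMSD.
    With fewer than 3 point pairs (or degenerate geometry) a translation-only
    alignment is returned with a warning.
    """
    ref = np.asarray(reference, float).reshape(-1, 3)
    mov = np.asarray(moving, float).reshape(-1, 3)
    if ref.shape != mov.shape:
        raise ValueError("point sets must have equal shape")
    if len(ref) < 3:
        warnings.warn("fewer than 3 point pairs: translation-only alignment", stacklevel=2)
        t = ref.mean(axis=0) - mov.mean(axis=0) if len(ref) else np.zeros(3)
        tr = Transform(np.eye(3), t)
        rmsd = float(np.sqrt(np.mean(np.sum((tr.apply(mov) - ref) ** 2, axis=1)))) if len(ref) else 0.0
        return tr, rmsd

    rc, mc = ref.mean(axis=0), mov.mean(axis=0)
    H = (mov - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = rc - R @ mc
    tr = Transform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((tr.apply(mov) - ref) ** 2, axis=1))))
    return tr, rmsd


def enumerate_correspondences(model: PharmacophoreModel, ligand: LigandFeatureSet,
                              max_omitted: int = 0) -> list[Correspondence]:
    """Enumerate kind-consistent correspondences covering all mandatory model
    features except at most ``max_omitted``.

    Candidates are pruned by pairwise internal-distance compatibility:
    a partial assignment survives only while, for every assigned pair of model
    features i, j, ``|d_model(i,j) − d_ligand(i,j)| <= 2·max(tol_i, tol_j)``
    (the triangle-inequality bound on what optimal alignment could repair).
    Enumeration is exhaustive relative to this pruning rule.
    """
    mand = model.mandatory_features
    n = len(mand)
    lig_centers = ligand.centers()
    lig_kinds = ligand.kinds()
    if n == 0:
        return []
    dm = np.linalg.norm(
        np.array([f.center for f in mand])[:, None, :] - np.array([f.center for f in mand])[None, :, :],
        axis=-1)
    dl = np.linalg.norm(lig_centers[:, None, :] - lig_centers[None, :, :], axis=-1) \
        if len(lig_centers) else np.zeros((0, 0))

    results: list[Correspondence] = []

    def backtrack(i: int, assigned: list[tuple[int, int]], omitted: int) -> None:
        if i == n:
            if len(assigned) >= 1 and omitted <= max_omitted:
                results.append(Correspondence(tuple(assigned)))
            return
        feat = mand[i]
        for j, k in enumerate(lig_kinds):
            if k is not feat.kind or any(j == lj for _, lj in assigned):
                continue
            ok = True
            for mi, lj in assigned:
                tol = 2.0 * max(feat.tolerance, mand[mi].tolerance)
                if abs(dm[i, mi] - dl[j, lj]) > tol:
                    ok = False
                    break
            if ok:
                backtrack(i + 1, assigned + [(i, j)], omitted)
        if omitted < max_omitted:
            backtrack(i + 1, assigned, omitted + 1)

    backtrack(0, [], 0)
    # drop empty/degenerate correspondences (all omitted)
    return [c for c in results if len(c.pairs) >= max(1, n - max_omitted)]


def fit_score(matched_count: int, feature_rmsd: float) -> float:
    """Documented stand-in scoring function: 10·matched − 3·rmsd."""
    return 10.0 * matched_count - 3.0 * feature_rmsd


def _match_featureset(model: PharmacophoreModel, ligand: LigandFeatureSet,
                      heavy_coords: np.ndarray | None,
                      max_omitted: int) -> MatchResult | None:
    """Best accepted alignment of one conformer feature set onto the model."""
    best: MatchResult | None = None
    lig_centers = ligand.centers()
    n_mand = len(model.mandatory_features)
    mand = model.mandatory_features
    opt = model.optional_features

    for corr in enumerate_correspondences(model, ligand, max_omitted):
        midx = [m for m, _ in corr.pairs]
        lidx = [l for _, l in corr.pairs]
        tr, _ = kabsch_align(np.array([mand[m].center for m in midx]),
                             lig_centers[lidx])
        moved = tr.apply(lig_centers)
        # acceptance: every matched pair within the model feature's tolerance
        dists = [np.linalg.norm(moved[l] - mand[m].center) for m, l in corr.pairs]
        if any(d > mand[m].tolerance for (m, _), d in zip(corr.pairs, dists)):
            continue
        matched_pairs = list(corr.pairs)
        all_dists = list(dists)
        # extend with optional features (greedy nearest, one-to-one)
        used = set(lidx)
        for oi, f in enumerate(opt):
            cands = [(np.linalg.norm(moved[j] - f.center), j)
                     for j, k in enumerate(ligand.kinds())
                     if j not in used and k is f.kind]
            cands = [(d, j) for d, j in cands if d <= f.tolerance]
            if cands:
                d, j = min(cands)
                matched_pairs.append((n_mand + oi, j))
                all_dists.append(d)
                used.add(j)
        # exclusion volumes: no ligand heavy atom (or bare feature point)
        # inside any sphere
        probe = tr.apply(heavy_coords) if heavy_coords is not None else moved
        violations = 0
        for ex in model.exclusions:
            violations += int(np.sum(np.linalg.norm(probe - ex.center, axis=1) < ex.radius))
        if violations > 0:
            continue
        rmsd = float(np.sqrt(np.mean(np.square(all_dists))))
        res = MatchResult(
            correspondence=Correspondence(tuple(matched_pairs)),
            transform=tr,
            matched_count=len(matched_pairs),
            omitted_count=n_mand - len(corr.pairs),
            feature_rmsd=rmsd,
            fit_score=fit_score(len(matched_pairs), rmsd),
            exclusion_violations=0,
            conformer_index=ligand.conformer_index,
            molecule_id=ligand.molecule_id,
            model_name=model.name,
        )
        if best is None or (res.fit_score, -res.feature_rmsd) > (best.fit_score, -best.feature_rmsd):
            best = res
    return best


def match(model: PharmacophoreModel, ligand, max_omitted: int = 0) -> MatchResult | None:
    """Match a model against a conformer ensemble and return the best accepted
    result ("get best matching conformation"), or ``None``.

    ``ligand`` may be a :class:`Molecule` with conformers, a single
    :class:`LigandFeatureSet`, or a list of feature sets (one per conformer).
    Ties across conformers break toward lower feature RMSD, then lower
    conformer index.
    """
    if not model.is_screenable:
        raise ValueError(f"model {model.name!r} is not screenable (<3 mandatory features)")

    if isinstance(ligand, Molecule):
        if ligand.unscreenable or ligand.n_conformers == 0:
            return None
        featuresets = perceive_ensemble(ligand)
        heavy = [ligand.heavy_atom_coords(i) for i in range(ligand.n_conformers)]
    elif isinstance(ligand, LigandFeatureSet):
        featuresets = [ligand]
        heavy = [None]
    else:
        featuresets = list(ligand)
        heavy = [None] * len(featuresets)

    best: MatchResult | None = None
    for fs, hv in zip(featuresets, heavy):
        res = _match_featureset(model, fs, hv, max_omitted)
        if res is None:
            continue
        if best is None or (res.fit_score, -res.feature_rmsd, -res.conformer_index) > \
                (best.fit_score, -best.feature_rmsd, -best.conformer_index):
            best = res
    return best


@dataclass(eq=False)
class ScreenReport:
    """Library-level screening outcome: per-molecule best match per model,
    hit list (a molecule is a hit iff ANY model accepts it) and the
    deduplicated hit union by canonical structure identifier."""

    results: dict[str, dict[str, MatchResult | None]]
    hits: list[str]
    deduplicated_hits: list[str]
    model_names: list[str] = field(default_factory=list)

    def best_match(self, molecule_id: str) -> MatchResult | None:
        per_model = [r for r in self.results.get(molecule_id, {}).values() if r is not None]
        if not per_model:
            return None
        return max(per_model, key=lambda r: (r.fit_score, -r.feature_rmsd))

    def to_frame(self):
        """Hit table: molecule_id, model, conformer, matched, omitted,
        feature_rmsd, fit_score."""
        import pandas as pd

        rows = []
        for mid, per_model in self.results.items():
            for mname, res in per_model.items():
                if res is not None:
                    rows.append({
                        "molecule_id": mid, "model": mname,
                        "conformer": res.conformer_index,
                        "matched": res.matched_count, "omitted": res.omitted_count,
                        "feature_rmsd": res.feature_rmsd, "fit_score": res.fit_score,
                    })
        return pd.DataFrame(rows, columns=["molecule_id", "model", "conformer",
                                           "matched", "omitted", "feature_rmsd", "fit_score"])


def screen_library(models, library, max_omitted: int = 0) -> ScreenReport:
    """Screen a library against one or more models in parallel.

    The hit list is the union over models; deduplication collapses hits with
    the same canonical structure identifier (cross-database duplicates).
    """
    models = list(models) if not isinstance(models, PharmacophoreModel) else [models]
    if not models:
        raise ValueError("at least one model required")
    results: dict[str, dict[str, MatchResult | None]] = {}
    hits: list[str] = []
    canon_seen: dict[str, str] = {}
    dedup: list[str] = []
    for ligand in library:
        mid = ligand.identifier if isinstance(ligand, Molecule) else (
            ligand.molecule_id if isinstance(ligand, LigandFeatureSet) else ligand[0].molecule_id)
        per_model = {m.name: match(m, ligand, max_omitted) for m in models}
        results[mid] = per_model
        if any(r is not None for r in per_model.values()):
            hits.append(mid)
            canon = ligand.canonical_id() if isinstance(ligand, Molecule) else mid
            if canon not in canon_seen:
                canon_seen[canon] = mid
                dedup.append(mid)
    return ScreenReport(results, hits, dedup, [m.name for m in models])


@dataclass(frozen=True)
class EnrichmentMetrics:
    """Confusion counts and derived validation metrics.

    ``enrichment_factor`` is the active fraction among retrieved hits over the
    active fraction in the whole library; ``None`` when nothing is retrieved.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_actives(self) -> int:
        return self.tp + self.fn

    @property
    def n_database(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_actives

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def yield_of_actives(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def enrichment_factor(self) -> float | None:
        if self.tp + self.fp == 0:
            return None
        return (self.tp / (self.tp + self.fp)) * (self.n_database / self.n_actives)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "n_actives": self.n_actives, "n_database": self.n_database,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "yield_of_actives": self.yield_of_actives,
            "enrichment_factor": self.enrichment_factor,
        }


def compute_enrichment(tp: int, fp: int, tn: int, fn: int) -> EnrichmentMetrics:
    """Validate counts and wrap them as :class:`EnrichmentMetrics`.

    Values are kept at full precision; round only at reporting time.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if tp + fn < 1:
        raise ValueError("at least one active required (tp + fn >= 1)")
    return EnrichmentMetrics(tp, fp, tn, fn)
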