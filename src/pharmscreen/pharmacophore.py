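"""Pharmacophore feature perception and ligand-based model building.

A pharmacophore model is a set of typed feature spheres (hydrogen-bond donor
and acceptor, hydrophobic, aromatic, positively/negatively ionizable), each
mandatory or optional, optionally surrounded by an exclusion-volume coat that
marks sterically forbidden space.  Models are built from training ligands
either as *shared*-feature models (only features common to every training
ligand, all mandatory) or *merged*-feature models (union of aligned features;
non-universal ones marked optional).

Feature perception follows a fixed, documented rule table (see
``_PERCEPTION_RULES`` and the hydrophobic-group algorithm in
:func:`perceive_features`); it is deterministic and covariant with rigid
motion of the conformer.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem_core import Conformer, Molecule

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Default feature tolerance radius (Å) and exclusion sphere radius (Å).
DEFAULT_TOLERANCE = 1.5
EXCLUSION_RADIUS = 1.0
#: Feature pairing distance (Å) used during ensemble alignment.
PAIRING_DISTANCE = 1.5


class FeatureKind(str, Enum):
    HBD = "HBD"
    HBA = "HBA"
    HYDROPHOBIC = "HYDROPHOBIC"
    AROMATIC = "AROMATIC"
    NEG_IONIZABLE = "NEG_IONIZABLE"
    POS_IONIZABLE = "POS_IONIZABLE"


@dataclass(eq=False)
class PharmacophoreFeature:
    kind: FeatureKind
    center: np.ndarray
    tolerance: float = DEFAULT_TOLERANCE
    optional: bool = False

    def __post_init__(self) -> None:
        self.kind = FeatureKind(self.kind)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.tolerance <= 0:
            raise ValueError("feature tolerance must be > 0")


@dataclass(eq=False)
class ExclusionVolume:
    center: np.ndarray
    radius: float = EXCLUSION_RADIUS

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("exclusion radius must be > 0")


@dataclass(eq=False)
class PharmacophoreModel:
    """A named set of pharmacophore features plus exclusion volumes."""

    name: str
    features: list[PharmacophoreFeature]
    exclusions: list[ExclusionVolume] = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        for a, b in itertools.combinations(self.features, 2):
            if np.linalg.norm(a.center - b.center) <= 0.1:
                raise ValueError(f"model {self.name!r}: feature centers closer than 0.1 Å")

    @property
    def mandatory_features(self) -> list[PharmacophoreFeature]:
        return [f for f in self.features if not f.optional]

    @property
    def optional_features(self) -> list[PharmacophoreFeature]:
        return [f for f in self.features if f.optional]

    @property
    def is_screenable(self) -> bool:
        return len(self.mandatory_features) >= 3


@dataclass(eq=False)
class LigandFeatureSet:
    """Features perceived on one conformer of one ligand (all mandatory)."""

    molecule_id: str
    conformer_index: int
    features: list[PharmacophoreFeature]

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features]).reshape(-1, 3)

    def kinds(self) -> list[FeatureKind]:
        return [f.kind for f in self.features]


# --------------------------------------------------------------------------
# feature perception
# --------------------------------------------------------------------------

# SMARTS rule table for point features.  Each entry: (kind, SMARTS, mode)
# where mode 'atom' places one feature per matched first atom and 'centroid'
# one per match at the centroid of all matched atoms.
_PERCEPTION_RULES: list[tuple[FeatureKind, str, str]] = [
    # O-H / N-H donors
    (FeatureKind.HBD, "[#7,#8;!H0]", "atom"),
    # acceptors: any non-cationic O; N that is neither amide, cationic nor
    # an aromatic N-H
    (FeatureKind.HBA, "[#8;!$([#8+])]", "atom"),
    (FeatureKind.HBA, "[#7;!$([#7+]);!$([NX3][CX3]=[OX1]);!$([nH])]", "atom"),
    # negatively ionizable groups (centroid of the group)
    (FeatureKind.NEG_IONIZABLE, "[CX3](=O)[OX1H0-,OX2H1]", "centroid"),
    (FeatureKind.NEG_IONIZABLE, "[SX4](=O)(=O)[OX1H0-,OX2H1]", "centroid"),
    (FeatureKind.NEG_IONIZABLE, "[PX4](=O)([OX1H0-,OX2H1])", "centroid"),
    (FeatureKind.NEG_IONIZABLE, "c1nnn[nH,n-]1", "centroid"),
    # positively ionizable: non-amide, non-anilinic sp3 amine; amidine/guanidine
    (FeatureKind.POS_IONIZABLE, "[NX4+]", "atom"),
    (FeatureKind.POS_IONIZABLE,
     "[NX3;!$(N[CX3]=[OX1]);!$(N[a]);!$(N=*);!$(N[CX3]=[NX2])]", "atom"),
    (FeatureKind.POS_IONIZABLE, "[NX3][CX3]=[NX2]", "centroid"),
]

_COMPILED_RULES = [(kind, Chem.MolFromSmarts(s), mode) for kind, s, mode in _PERCEPTION_RULES]

_HALOGENS = {9, 17, 35, 53}


def _hydrophobic_groups(rd: Chem.Mol) -> list[list[int]]:
    """Atom-index groups that carry hydrophobic features.

    Eligible atoms: non-aromatic carbons, halogens, and divalent sulfur, none
    of which is bonded to a formally charged or HB-capable (N/O) atom.
    Maximal connected groups of >= 3 eligible atoms emit features; compact
    groups (<= 6 atoms) give a single centroid, while larger ones are split
    topologically into one group per non-aromatic ring (>= 3 eligible members)
    plus connected acyclic remainder chunks of >= 3 atoms, so extended
    scaffolds (steroids, triterpenes) carry several local hydrophobic centers.
    """
    def eligible(atom: Chem.Atom) -> bool:
        z = atom.GetAtomicNum()
        if atom.GetIsAromatic():
            return False
        if not (z == 6 or z in _HALOGENS or (z == 16 and atom.GetDegree() == 2)):
            return False
        for nb in atom.GetNeighbors():
            if nb.GetFormalCharge() != 0 or nb.GetAtomicNum() in (7, 8):
                return False
        return atom.GetFormalCharge() == 0

    elig = {a.GetIdx() for a in rd.GetAtoms() if eligible(a)}
    # connected components within the eligible set
    seen: set[int] = set()
    components: list[list[int]] = []
    for start in sorted(elig):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for nb in rd.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in elig and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(comp) >= 3:
            components.append(sorted(comp))

    groups: list[list[int]] = []
    ring_info = rd.GetRingInfo()
    for comp in components:
        if len(comp) <= 6:
            groups.append(comp)
            continue
        comp_set = set(comp)
        in_ring_group: set[int] = set()
        for ring in ring_info.AtomRings():
            if any(rd.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                continue
            members = sorted(set(ring) & comp_set)
            if len(members) >= 3:
                groups.append(members)
                in_ring_group.update(members)
        # acyclic remainder: connected chunks of eligible atoms outside rings
        rest = comp_set - in_ring_group
        seen2: set[int] = set()
        for start in sorted(rest):
            if start in seen2:
                continue
            stack, chunk = [start], []
            seen2.add(start)
            while stack:
                i = stack.pop()
                chunk.append(i)
                for nb in rd.GetAtomWithIdx(i).GetNeighbors():
                    j = nb.GetIdx()
                    if j in rest and j not in seen2:
                        seen2.add(j)
                        stack.append(j)
            if len(chunk) >= 3:
                groups.append(sorted(chunk))
        if not any(set(g) <= comp_set for g in groups):
            groups.append(comp)  # fallback: never lose a large component
    return groups


def perceive_features(mol: Molecule, conformer: Conformer | int = 0,
                      tolerance: float = DEFAULT_TOLERANCE) -> LigandFeatureSet:
    """Perceive pharmacophoric features on one conformer of a molecule.

    Aromatic features sit at aromatic-ring centroids; aromatic atoms are
    claimed by those features and excluded from hydrophobic groups (benzene
    yields exactly one AROMATIC feature).
    """
    if isinstance(conformer, int):
        conf_idx = conformer
        conf = mol.conformers[conformer]
    else:
        conf = conformer
        conf_idx = next((i for i, c in enumerate(mol.conformers) if c is conformer), 0)
    coords = conf.coordinates
    rd = mol.rdmol
    if coords.shape[0] != rd.GetNumAtoms():
        raise ValueError("conformer does not cover every atom of the molecule")

    features: list[PharmacophoreFeature] = []
    claimed_hba: set[int] = set()

    for kind, patt, mode in _COMPILED_RULES:
        for match in rd.GetSubstructMatches(patt):
            if mode == "atom":
                idx = match[0]
                if kind is FeatureKind.HBA:
                    if idx in claimed_hba:
                        continue
                    claimed_hba.add(idx)
                features.append(PharmacophoreFeature(kind, coords[idx], tolerance))
            else:
                center = coords[list(match)].mean(axis=0)
                # skip duplicate centroid matches (symmetric SMARTS)
                if any(f.kind is kind and np.linalg.norm(f.center - center) < 0.1
                       for f in features):
                    continue
                features.append(PharmacophoreFeature(kind, center, tolerance))

    for ring in rd.GetRingInfo().AtomRings():
        if all(rd.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            features.append(PharmacophoreFeature(
                FeatureKind.AROMATIC, coords[list(ring)].mean(axis=0), tolerance))

    for group in _hydrophobic_groups(rd):
        features.append(PharmacophoreFeature(
            FeatureKind.HYDROPHOBIC, coords[group].mean(axis=0), tolerance))

    return LigandFeatureSet(mol.identifier, conf_idx, features)


def perceive_ensemble(mol: Molecule, tolerance: float = DEFAULT_TOLERANCE) -> list[LigandFeatureSet]:
    return [perceive_features(mol, i, tolerance) for i in range(mol.n_conformers)]


# --------------------------------------------------------------------------
# model building
# --------------------------------------------------------------------------

def _as_feature_sets(training) -> list[list[LigandFeatureSet]]:
    """Normalize training input to one list of conformer feature sets per ligand.

    Accepts Molecules with conformers, single LigandFeatureSets, or lists of
    LigandFeatureSets (one per conformer).
    """
    out: list[list[LigandFeatureSet]] = []
    for item in training:
        if isinstance(item, Molecule):
            if item.n_conformers == 0:
                raise ValueError(f"training ligand {item.identifier!r} has no conformers")
            out.append(perceive_ensemble(item))
        elif isinstance(item, LigandFeatureSet):
            out.append([item])
        else:
            sets = list(item)
            if not all(isinstance(s, LigandFeatureSet) for s in sets):
                raise TypeError("training items must be Molecule or LigandFeatureSet(s)")
            out.append(sets)
    return out


def _kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mov`` onto ``ref`` (proper rotation)."""
    rc, mc = ref.mean(axis=0), mov.mean(axis=0)
    H = (mov - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def _greedy_pairing(ref: LigandFeatureSet, other_centers: np.ndarray,
                    other_kinds: list[FeatureKind],
                    pairing_distance: float) -> tuple[dict[int, int], float]:
    """One-to-one nearest-first pairing of same-kind features within the
    pairing distance.  Returns {ref index -> other index} and the pairing RMSD."""
    cand = []
    for i, f in enumerate(ref.features):
        for j, (c, k) in enumerate(zip(other_centers, other_kinds)):
            if k is f.kind:
                d = float(np.linalg.norm(f.center - c))
                if d <= pairing_distance:
                    cand.append((d, i, j))
    cand.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs: dict[int, int] = {}
    dists = []
    for d, i, j in cand:
        if i in used_i or j in used_j:
            continue
        pairs[i] = j
        used_i.add(i)
        used_j.add(j)
        dists.append(d)
    rmsd = float(np.sqrt(np.mean(np.square(dists)))) if dists else np.inf
    return pairs, rmsd


def _best_alignment(ref: LigandFeatureSet, sets: list[LigandFeatureSet],
                    pairing_distance: float,
                    max_triplets: int = 20000):
    """Align one ligand (any of its conformer feature sets) onto the reference.

    Enumerates kind-compatible feature-triplet correspondences, superposes by
    least squares, and keeps the alignment maximizing the matched-feature
    count (ties broken by lower pairing RMSD).  Returns
    (pairs, transformed centers, kinds, conformer index) or None.
    """
    best = None
    ref_centers = ref.centers()
    ref_d = np.linalg.norm(ref_centers[:, None] - ref_centers[None, :], axis=-1)
    prune = 2.0 * pairing_distance
    for si, fs in enumerate(sets):
        centers = fs.centers()
        kinds = fs.kinds()
        lig_d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        n_tried = 0
        for ridx in itertools.combinations(range(len(ref.features)), 3):
            i1, i2, i3 = ridx
            rkinds = [ref.features[i].kind for i in ridx]
            pools = [[j for j, k in enumerate(kinds) if k is rk] for rk in rkinds]
            for a, b, c in itertools.product(*pools):
                if a == b or a == c or b == c:
                    continue
                # internal-distance compatibility prunes most candidates cheaply
                if (abs(ref_d[i1, i2] - lig_d[a, b]) > prune
                        or abs(ref_d[i1, i3] - lig_d[a, c]) > prune
                        or abs(ref_d[i2, i3] - lig_d[b, c]) > prune):
                    continue
                n_tried += 1
                if n_tried > max_triplets:
                    break
                R, t = _kabsch(ref_centers[list(ridx)], centers[[a, b, c]])
                moved = centers @ R.T + t
                pairs, rmsd = _greedy_pairing(ref, moved, kinds, pairing_distance)
                # ICP-style polish: re-superpose on every paired feature and
                # re-pair, which rescues near-miss features outside the
                # initial triplet and corrects swapped assignments
                for _ in range(2):
                    if len(pairs) < 3:
                        break
                    ri = [ref.features[i].center for i in pairs]
                    li = [centers[j] for j in pairs.values()]
                    R2, t2 = _kabsch(np.array(ri), np.array(li))
                    moved2 = centers @ R2.T + t2
                    pairs2, rmsd2 = _greedy_pairing(ref, moved2, kinds, pairing_distance)
                    if (len(pairs2), -rmsd2) <= (len(pairs), -rmsd):
                        break
                    pairs, rmsd, moved = pairs2, rmsd2, moved2
                key = (len(pairs), -rmsd)
                if best is None or key > best[0]:
                    best = (key, pairs, moved, kinds, si)
            if n_tried > max_triplets:
                break
    if best is None or len(best[1]) == 0:
        return None
    return best[1], best[2], best[3], best[4]


def _dedupe_coincident(features: list[PharmacophoreFeature],
                       min_sep: float = 0.1) -> list[PharmacophoreFeature]:
    """Drop features whose centers coincide (within ``min_sep``) with an
    already-kept one; mandatory features take precedence.  A hydroxyl oxygen,
    for example, is perceived as both donor and acceptor at the same
    position, but a model keeps only one feature per site."""
    kept: list[PharmacophoreFeature] = []
    for f in sorted(features, key=lambda f: f.optional):
        if all(np.linalg.norm(f.center - g.center) > min_sep for g in kept):
            kept.append(f)
    return kept


def build_merged_model(training, name: str = "merged",
                       pairing_distance: float = PAIRING_DISTANCE,
                       tolerance: float = DEFAULT_TOLERANCE,
                       info: dict | None = None) -> PharmacophoreModel | None:
    """Build a merged-feature model: union of aligned features, features found
    in every training ligand mandatory, the rest optional.

    Returns ``None`` when no common feature set of size >= 3 exists.  A single
    training ligand degenerates to its own full feature set (all mandatory).
    """
    ensembles = _as_feature_sets(training)
    if len(ensembles) == 1:
        fs = max(ensembles[0], key=lambda s: len(s.features))
        feats = _dedupe_coincident([replace(f, tolerance=tolerance) for f in fs.features])
        return PharmacophoreModel(name, feats)

    # candidate references in order of feature richness; every ligand is
    # tried and the reference yielding the most shared (mandatory) features
    # wins, so a distractor-rich ligand cannot sink the whole model
    order = sorted(range(len(ensembles)),
                   key=lambda i: -max(len(s.features) for s in ensembles[i]))
    best_build = None
    for ref_i in order:
        built = _merged_with_reference(ensembles, ref_i, pairing_distance, tolerance)
        if built is None:
            continue
        features, n_mandatory = built
        key = (n_mandatory, len(features))
        if best_build is None or key > best_build[0]:
            best_build = (key, features, ref_i)
    if best_build is None or best_build[0][0] < 3:
        logger.info("no shared feature set of size >= 3 for model %r", name)
        return None
    _, features, ref_i = best_build
    if info is not None:
        # the model frame is the reference ligand's conformer frame
        info["reference_ligand_index"] = ref_i
        info["reference_conformer_index"] = max(
            ensembles[ref_i], key=lambda s: len(s.features)).conformer_index
    return PharmacophoreModel(name, features)


def _merged_with_reference(ensembles, ref_i: int, pairing_distance: float,
                           tolerance: float):
    """Merged feature list using one ligand as the alignment reference.

    Returns (features, n_mandatory) or ``None`` when some ligand admits no
    alignment at all.
    """
    ref = max(ensembles[ref_i], key=lambda s: len(s.features))
    others = [e for i, e in enumerate(ensembles) if i != ref_i]

    # per reference feature: centers contributed by each matching ligand
    contributions: list[list[np.ndarray]] = [[f.center] for f in ref.features]
    match_counts = [0] * len(ref.features)
    extras: list[PharmacophoreFeature] = []

    for ens in others:
        aligned = _best_alignment(ref, ens, pairing_distance)
        if aligned is None:
            return None
        pairs, moved, kinds, _ = aligned
        for i, j in pairs.items():
            contributions[i].append(moved[j])
            match_counts[i] += 1
        unmatched = [j for j in range(len(kinds)) if j not in pairs.values()]
        for j in unmatched:
            extras.append(PharmacophoreFeature(kinds[j], moved[j], tolerance, optional=True))

    n_others = len(others)
    features: list[PharmacophoreFeature] = []
    for i, f in enumerate(ref.features):
        center = np.mean(contributions[i], axis=0)
        features.append(PharmacophoreFeature(
            f.kind, center, tolerance, optional=match_counts[i] < n_others))

    # merge extra (optional) features that coincide across ligands
    for ex in extras:
        dup = next((f for f in features
                    if f.kind is ex.kind and np.linalg.norm(f.center - ex.center) <= pairing_distance),
                   None)
        if dup is None:
            features.append(ex)
    features = _dedupe_coincident(features)
    return features, sum(1 for f in features if not f.optional)


def build_shared_model(training, name: str = "shared",
                       pairing_distance: float = PAIRING_DISTANCE,
                       tolerance: float = DEFAULT_TOLERANCE,
                       info: dict | None = None) -> PharmacophoreModel | None:
    """Build a shared-feature model: only features matched by every training
    ligand, all mandatory.  Feature centers are centroids of the contributing
    ligand features.  Returns ``None`` if fewer than 3 common features exist.
    """
    merged = build_merged_model(training, name=name,
                                pairing_distance=pairing_distance, tolerance=tolerance,
                                info=info)
    if merged is None:
        return None
    shared = [replace(f) for f in merged.mandatory_features]
    return PharmacophoreModel(name, shared)


def add_exclusion_coat(model: PharmacophoreModel, aligned_training: list[Conformer] | list[np.ndarray],
                       radius: float = EXCLUSION_RADIUS, grid_step: float = 1.0,
                       shell: tuple[float, float] = (2.5, 3.5),
                       max_spheres: int = 100) -> PharmacophoreModel:
    """Surround the aligned training ensemble with an exclusion-volume coat.

    Grid points (``grid_step`` Å) over the ensemble bounding box (+4 Å margin)
    whose minimum distance to any training heavy atom falls inside ``shell``
    are kept and farthest-point downsampled to ``max_spheres`` spheres.  No
    training atom lies inside any emitted sphere by construction.  An empty
    training list leaves the model unchanged.
    """
    coords_list = [c.coordinates if isinstance(c, Conformer) else np.asarray(c, float)
                   for c in aligned_training]
    if not coords_list:
        return model
    atoms = np.vstack(coords_list)
    lo = atoms.min(axis=0) - 4.0
    hi = atoms.max(axis=0) + 4.0
    axes = [np.arange(lo[d], hi[d] + grid_step / 2, grid_step) for d in range(3)]
    grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    from scipy.spatial import cKDTree

    dmin, _ = cKDTree(atoms).query(grid)
    pts = grid[(dmin >= shell[0]) & (dmin <= shell[1])]
    if len(pts) > max_spheres:
        pts = _farthest_point_sample(pts, max_spheres)
    exclusions = [ExclusionVolume(p, radius) for p in pts]
    return PharmacophoreModel(model.name, model.features, exclusions, model.schema_version)


def _farthest_point_sample(points: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point subset (seeded at the point nearest the centroid)."""
    pts = np.asarray(points, float)
    start = int(np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    chosen = [start]
    dist = np.linalg.norm(pts - pts[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(pts - pts[nxt], axis=1))
    return pts[chosen]


# --------------------------------------------------------------------------
# JSON persistence and packaged reference models
# --------------------------------------------------------------------------

def save_model(model: PharmacophoreModel, path: str | Path) -> None:
    doc = {
        "schema_version": model.schema_version,
        "name": model.name,
        "features": [
            {"kind": f.kind.value, "center": [float(x) for x in f.center],
             "tolerance": f.tolerance, "optional": f.optional}
            for f in model.features
        ],
        "exclusions": [
            {"center": [float(x) for x in e.center], "radius": e.radius}
            for e in model.exclusions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> PharmacophoreModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"invalid pharmacophore JSON in {path}: {exc}") from exc
    for key in ("schema_version", "name", "features"):
        if key not in doc:
            raise ValueError(f"pharmacophore JSON {path} missing required key {key!r}")
    try:
        features = [PharmacophoreFeature(FeatureKind(f["kind"]), f["center"],
                                         f["tolerance"], bool(f.get("optional", False)))
                    for f in doc["features"]]
        exclusions = [ExclusionVolume(e["center"], e["radius"])
                      for e in doc.get("exclusions", [])]
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"malformed pharmacophore JSON in {path}: {exc}") from exc
    return PharmacophoreModel(doc["name"], features, exclusions, int(doc["schema_version"]))


def reference_model(name: str) -> PharmacophoreModel:
    """Load a packaged reference model by name (``"BAMS22"`` or ``"TTM8"``).

    BAMS22: 2 mandatory hydrophobic + 2 mandatory HB-acceptor features with an
    optional HB donor, hydrophobic and negatively ionizable feature — the
    bile-acid-type query.  TTM8: 4 mandatory hydrophobic, 2 mandatory
    HB-acceptor and 1 mandatory negatively ionizable feature — the
    triterpene-type query.  Geometry is regenerated from public training
    structures by this package's own perception (see ``scripts`` helper), not
    copied from any proprietary model file.
    """
    from importlib import resources

    fname = {"bams22": "bams22.json", "ttm8": "ttm8.json"}.get(name.lower())
    if fname is None:
        raise KeyError(f"unknown reference model {name!r}")
    with resources.as_file(resources.files("pharmscreen.data") / fname) as p:
        return load_model(p)
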