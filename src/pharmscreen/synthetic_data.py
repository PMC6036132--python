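"""Ground-truth generators that make every pipeline stage testable offline.

Three generators emulate the data the screening campaign consumes:

* :func:`plant_feature_clouds` — libraries of abstract ligand feature sets
  built around a known (planted) pharmacophore: positives reproduce the
  model's mandatory features up to Gaussian positional jitter plus a few
  distractor features; negatives carry the same feature multiset with kinds
  shuffled and pairwise geometry perturbed beyond what feature tolerances can
  absorb, and are verified unmatched by construction.
* :func:`build_molecular_benchmark` — a labeled molecule library grown from
  public bile-acid and triterpene-acid scaffolds: actives are small
  substituent variations that preserve the pharmacophoric groups; inactives
  are variations that destroy one required group (e.g. carboxylic acid ->
  methyl ester), with the destroyed group recorded.
* :func:`generate_decoys` — DUD-E-style property-matched decoy selection:
  candidates must sit inside 1D property windows of a matched active while
  staying topologically dissimilar (circular-fingerprint Tanimoto < 0.35) to
  every active.
* :func:`simulate_assay` — reporter-assay plates following a 4PL
  concentration–response with multiplicative Gaussian noise on the reporter
  signal and an EGFP channel that collapses above a cytotoxicity threshold.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem

from .bioassay import fourpl
from .chem_core import Molecule, compute_descriptors, fingerprint, tanimoto
from .pharmacophore import (
    DEFAULT_TOLERANCE,
    FeatureKind,
    LigandFeatureSet,
    PharmacophoreFeature,
    PharmacophoreModel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedModelSpec",
    "AssaySimSpec",
    "PlantedLibrary",
    "plant_feature_clouds",
    "default_planted_model",
    "ACTIVE_SCAFFOLDS",
    "build_molecular_benchmark",
    "random_druglike_pool",
    "DecoyWindows",
    "generate_decoys",
    "simulate_assay",
]


# --------------------------------------------------------------------------
# planted-pharmacophore feature-cloud libraries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedModelSpec:
    """Recipe for a planted-pharmacophore library."""

    model: PharmacophoreModel
    n_positives: int = 100
    n_negatives: int = 1000
    jitter: float = 0.2         # Å, sd of isotropic positional noise on planted features
    seed: int = 0
    max_distractors: int = 2

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass(eq=False)
class PlantedLibrary:
    feature_sets: list[LigandFeatureSet]
    labels: dict[str, bool]      # id -> is_positive
    spec: PlantedModelSpec

    @property
    def positives(self) -> list[LigandFeatureSet]:
        return [f for f in self.feature_sets if self.labels[f.molecule_id]]

    @property
    def negatives(self) -> list[LigandFeatureSet]:
        return [f for f in self.feature_sets if not self.labels[f.molecule_id]]


def default_planted_model(name: str = "planted", tolerance: float = DEFAULT_TOLERANCE) -> PharmacophoreModel:
    """A compact 4-feature ground-truth pharmacophore (2 hydrophobic, 1 HBA,
    1 negatively ionizable) with bile-acid-like inter-feature distances."""
    feats = [
        PharmacophoreFeature(FeatureKind.HYDROPHOBIC, [0.0, 0.0, 0.0], tolerance),
        PharmacophoreFeature(FeatureKind.HYDROPHOBIC, [4.5, 1.0, 0.5], tolerance),
        PharmacophoreFeature(FeatureKind.HBA, [2.0, 3.5, -1.0], tolerance),
        PharmacophoreFeature(FeatureKind.NEG_IONIZABLE, [7.5, -1.5, 1.5], tolerance),
    ]
    return PharmacophoreModel(name, feats)


def _pairwise_compatible(model: PharmacophoreModel, fs: LigandFeatureSet) -> bool:
    """True if ANY kind-consistent correspondence survives the matcher's
    pairwise-distance pruning (used to reject accidental-match negatives)."""
    from .screening import enumerate_correspondences

    return len(enumerate_correspondences(model, fs, max_omitted=0)) > 0


def plant_feature_clouds(spec: PlantedModelSpec) -> PlantedLibrary:
    """Generate a labeled library of feature sets around a planted model.

    Positives: the model's mandatory features with isotropic Gaussian jitter
    (sd ``spec.jitter``) plus 0–``max_distractors`` random distractor
    features, in a random rigid frame.  Negatives: the same feature multiset
    with kinds shuffled and all pairwise distances perturbed by more than
    2x tolerance (geometry rescaling), rejection-verified to admit no
    correspondence at zero omitted features.
    """
    rng = np.random.default_rng(spec.seed)
    mand = spec.model.mandatory_features
    centers = np.array([f.center for f in mand])
    kinds = [f.kind for f in mand]
    tol = max(f.tolerance for f in mand)
    all_kinds = list(FeatureKind)
    bbox_lo = centers.min(axis=0) - 2.0
    bbox_hi = centers.max(axis=0) + 2.0
    dmat = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    d_min = dmat[dmat > 0].min()

    def random_frame(points: np.ndarray) -> np.ndarray:
        # random proper rotation + translation, so libraries carry no shared frame
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        return points @ Q.T + rng.uniform(-20, 20, size=3)

    sets: list[LigandFeatureSet] = []
    labels: dict[str, bool] = {}

    for i in range(spec.n_positives):
        pts = centers + rng.normal(0.0, spec.jitter, size=centers.shape)
        feats = [PharmacophoreFeature(k, c, tol) for k, c in zip(kinds, pts)]
        for _ in range(rng.integers(0, spec.max_distractors + 1)):
            feats.append(PharmacophoreFeature(
                all_kinds[rng.integers(len(all_kinds))],
                rng.uniform(bbox_lo, bbox_hi), tol))
        pts_all = np.array([f.center for f in feats])
        moved = random_frame(pts_all)
        feats = [replace(f, center=c) for f, c in zip(feats, moved)]
        mid = f"pos_{i:05d}"
        sets.append(LigandFeatureSet(mid, 0, feats))
        labels[mid] = True

    # geometry rescaling that pushes every pairwise distance off by > 2*tol
    scale = 1.0 + 3.0 * tol / d_min
    n_made = 0
    attempt = 0
    while n_made < spec.n_negatives:
        attempt += 1
        perm = rng.permutation(len(kinds))
        shuffled_kinds = [kinds[p] for p in perm]
        pts = centers * scale + rng.normal(0.0, spec.jitter + 0.1, size=centers.shape)
        feats = [PharmacophoreFeature(k, c, tol) for k, c in zip(shuffled_kinds, pts)]
        fs = LigandFeatureSet(f"neg_{n_made:05d}", 0, feats)
        if _pairwise_compatible(spec.model, fs):
            # rare accidental geometry: perturb harder and retry
            if attempt > 20 * spec.n_negatives:
                raise RuntimeError("could not generate guaranteed-negative feature sets")
            continue
        moved = random_frame(np.array([f.center for f in feats]))
        fs = LigandFeatureSet(fs.molecule_id, 0,
                              [replace(f, center=c) for f, c in zip(feats, moved)])
        sets.append(fs)
        labels[fs.molecule_id] = False
        n_made += 1

    return PlantedLibrary(sets, labels, spec)


# --------------------------------------------------------------------------
# molecular benchmark from public scaffolds
# --------------------------------------------------------------------------

#: Public structures of potent bile-acid and triterpene-acid receptor agonists
#: (stereochemistry omitted; inputs are screened as given).
ACTIVE_SCAFFOLDS: dict[str, str] = {
    "lithocholic_acid": "CC(CCC(=O)O)C1CCC2C3CCC4CC(O)CCC4(C)C3CCC12C",
    "chenodeoxycholic_acid": "CC(CCC(=O)O)C1CCC2C3C(O)CC4CC(O)CCC4(C)C3CCC12C",
    "deoxycholic_acid": "CC(CCC(=O)O)C1CCC2C3CCC4CC(O)CCC4(C)C3CC(O)C12C",
    "taurolithocholic_acid":
        "CC(CCC(=O)NCCS(=O)(=O)O)C1CCC2C3CCC4CC(O)CCC4(C)C3CCC12C",
    "oleanolic_acid":
        "CC1(C)CCC2(C(=O)O)CCC3(C)C(=CC4C5(C)CCC(O)C(C)(C)C5CCC34C)C2C1",
    "ursolic_acid":
        "CC1CCC2(C(=O)O)CCC3(C)C(=CC4C5(C)CCC(O)C(C)(C)C5CCC34C)C2C1C",
    "betulinic_acid":
        "CC(=C)C1CCC2(C(=O)O)CCC3(C)C(CCC4C5(C)CCC(O)C(C)(C)C5CCC34C)C12",
    "hederagenin":
        "CC1(C)CCC2(C(=O)O)CCC3(C)C(=CC4C5(C)CCC(O)C(CO)(C)C5CCC34C)C2C1",
}

#: Substituent decorations that leave the pharmacophoric groups intact.
_DECORATIONS = ["C", "F", "CC", "Cl"]


def _eligible_carbons(rd: Chem.Mol) -> list[int]:
    out = []
    for a in rd.GetAtoms():
        if a.GetAtomicNum() != 6 or a.GetIsAromatic():
            continue
        if a.GetTotalNumHs() < 1:
            continue
        if any(nb.GetAtomicNum() in (7, 8) for nb in a.GetNeighbors()):
            continue
        out.append(a.GetIdx())
    return out


def _attach(rd: Chem.Mol, site: int, frag_smiles: str) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = Chem.RWMol(Chem.CombineMols(rd, frag))
    combo.AddBond(site, rd.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


_ACID = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_ESTER_CAP = Chem.MolFromSmiles("C(=O)OC")
_HYDROXYL = Chem.MolFromSmarts("[CX4][OX2H1]")


def _destroy_group(rd: Chem.Mol, rng: np.random.Generator) -> tuple[Chem.Mol, str] | None:
    """Apply one pharmacophore-destroying transform; returns (mol, destroyed)."""
    from rdkit.Chem import AllChem

    choices = []
    if rd.HasSubstructMatch(_ACID):
        choices.append("NEG_IONIZABLE")
    if rd.HasSubstructMatch(_HYDROXYL):
        choices.append("HBD")
    if not choices:
        return None
    target = choices[int(rng.integers(len(choices)))]
    if target == "NEG_IONIZABLE":
        # carboxylic acid -> methyl ester (removes the ionizable head)
        prods = AllChem.ReplaceSubstructs(rd, _ACID, _ESTER_CAP, replaceAll=False)
    else:
        # hydroxyl -> methyl ether (removes the donor)
        prods = AllChem.ReplaceSubstructs(rd, Chem.MolFromSmarts("[OX2H1]"),
                                          Chem.MolFromSmiles("OC"), replaceAll=False)
    for p in prods:
        try:
            Chem.SanitizeMol(p)
            return p, target
        except Exception:
            continue
    return None


def build_molecular_benchmark(n_actives: int = 40, n_inactives: int = 40,
                              seed: int = 0) -> tuple[list[Molecule], dict[str, dict]]:
    """Labeled molecule library grown from the packaged public scaffolds.

    Returns (molecules, labels); ``labels[id]`` carries ``active`` (bool),
    ``scaffold`` and, for inactives, ``destroyed`` (which pharmacophoric group
    the variation removed).  Labels partition the library.
    """
    rng = np.random.default_rng(seed)
    scaffolds = [(name, Chem.MolFromSmiles(smi)) for name, smi in ACTIVE_SCAFFOLDS.items()]
    for name, rd in scaffolds:
        if rd is None:
            raise RuntimeError(f"packaged scaffold {name} failed to parse")

    mols: list[Molecule] = []
    labels: dict[str, dict] = {}
    seen: set[str] = set()

    def add(rd: Chem.Mol, ident: str, info: dict) -> bool:
        smi = Chem.MolToSmiles(rd)
        if smi in seen:
            return False
        seen.add(smi)
        mols.append(Molecule(identifier=ident, rdmol=Chem.MolFromSmiles(smi),
                             source_tag="benchmark"))
        labels[ident] = info
        return True

    # actives: scaffolds themselves, then decorated variants
    count = 0
    for name, rd in scaffolds:
        if count >= n_actives:
            break
        if add(rd, f"act_{count:04d}", {"active": True, "scaffold": name}):
            count += 1
    guard = 0
    while count < n_actives and guard < 50 * n_actives:
        guard += 1
        name, rd = scaffolds[int(rng.integers(len(scaffolds)))]
        sites = _eligible_carbons(rd)
        if not sites:
            continue
        dec = _DECORATIONS[int(rng.integers(len(_DECORATIONS)))]
        out = _attach(rd, sites[int(rng.integers(len(sites)))], dec)
        if out is not None and add(out, f"act_{count:04d}",
                                   {"active": True, "scaffold": name, "decoration": dec}):
            count += 1
    if count < n_actives:
        raise RuntimeError("analog enumeration exhausted before reaching n_actives")

    count = 0
    guard = 0
    while count < n_inactives and guard < 50 * n_inactives:
        guard += 1
        name, rd = scaffolds[int(rng.integers(len(scaffolds)))]
        # optionally decorate first so inactives are as varied as actives
        if rng.random() < 0.5:
            sites = _eligible_carbons(rd)
            if sites:
                dec = _attach(rd, sites[int(rng.integers(len(sites)))],
                              _DECORATIONS[int(rng.integers(len(_DECORATIONS)))])
                if dec is not None:
                    rd = dec
        res = _destroy_group(rd, rng)
        if res is None:
            continue
        out, destroyed = res
        if add(out, f"inact_{count:04d}",
               {"active": False, "scaffold": name, "destroyed": destroyed}):
            count += 1
    if count < n_inactives:
        raise RuntimeError("could not generate the requested number of inactives")
    return mols, labels


# --------------------------------------------------------------------------
# property-matched decoys
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DecoyWindows:
    """1D property windows a decoy must satisfy relative to its matched active
    (published decoy-generation conventions) plus the 2D dissimilarity cap."""

    mw: float = 25.0
    logp: float = 1.0
    hbd: int = 1
    hba: int = 2
    rotatable: int = 2
    max_tanimoto: float = 0.35


def generate_decoys(actives: list[Molecule], pool: list[Molecule], per_active: int = 50,
                    windows: DecoyWindows = DecoyWindows()) -> tuple[list[Molecule], dict[str, str]]:
    """Select property-matched, topology-dissimilar decoys from a candidate pool.

    Each decoy lies within ``windows`` of its matched active (identical net
    charge) AND has fingerprint Tanimoto < ``windows.max_tanimoto`` to EVERY
    active.  At most ``per_active`` per active, deduplicated by canonical
    structure.  A depleted pool yields fewer decoys with a warning.
    """
    act_desc = [compute_descriptors(m) for m in actives]
    act_fps = [fingerprint(m) for m in actives]
    act_canon = {m.canonical_id() for m in actives}

    pool_entries = []
    for m in pool:
        canon = m.canonical_id()
        if canon in act_canon:
            continue
        pool_entries.append((m, canon, compute_descriptors(m), fingerprint(m)))

    chosen: list[Molecule] = []
    assignment: dict[str, str] = {}
    used: set[str] = set()
    for active, d, _ in zip(actives, act_desc, act_fps):
        n_taken = 0
        for m, canon, pd_, fp in pool_entries:
            if n_taken >= per_active:
                break
            if canon in used:
                continue
            if abs(pd_.molecular_weight - d.molecular_weight) > windows.mw:
                continue
            if abs(pd_.logp_estimate - d.logp_estimate) > windows.logp:
                continue
            if abs(pd_.hbd_count - d.hbd_count) > windows.hbd:
                continue
            if abs(pd_.hba_count - d.hba_count) > windows.hba:
                continue
            if abs(pd_.rotatable_bonds - d.rotatable_bonds) > windows.rotatable:
                continue
            if pd_.net_charge != d.net_charge:
                continue
            if any(tanimoto(fp, afp) >= windows.max_tanimoto for afp in act_fps):
                continue
            used.add(canon)
            chosen.append(m)
            assignment[m.identifier] = active.identifier
            n_taken += 1
        if n_taken < per_active:
            warnings.warn(
                f"pool exhausted for active {active.identifier!r}: "
                f"{n_taken}/{per_active} decoys", stacklevel=2)
    return chosen, assignment


_POOL_CORES = [
    "C1CCCCC1", "C1CCCC1", "C1CCC2CCCCC2C1", "C1CC2CCC1CC2",
    "c1ccccc1", "c1ccc2ccccc2c1", "CCCCCCCC", "C1CCCCCC1",
]
_POOL_FRAGS = ["C", "CC", "CCC", "CCCC", "C1CCCCC1", "C(=O)O", "O", "F", "CC(C)C",
               "c1ccccc1", "CCO"]


def random_druglike_pool(n: int, seed: int = 0,
                         mw_range: tuple[float, float] = (220.0, 560.0)) -> list[Molecule]:
    """Assemble a synthetic candidate pool by randomly decorating simple ring
    and chain cores with small fragments.

    Each candidate grows toward a random molecular-weight target inside
    ``mw_range``; most carry one carboxylic acid and up to two hydroxyls so
    the pool's 1D property distribution overlaps that of acidic natural
    products while staying topologically unlike fused polycyclic scaffolds.
    Feeds :func:`generate_decoys`.
    """
    from rdkit.Chem import Descriptors

    rng = np.random.default_rng(seed)
    hydrophobic_frags = ["C", "CC", "CCC", "CCCC", "CC(C)C", "C1CCCCC1",
                         "C1CCCC1", "c1ccccc1", "CCCCCC"]
    mols: list[Molecule] = []
    seen: set[str] = set()
    guard = 0
    while len(mols) < n and guard < 60 * n:
        guard += 1
        rd = Chem.MolFromSmiles(_POOL_CORES[int(rng.integers(len(_POOL_CORES)))])
        target = rng.uniform(*mw_range)
        polar = []
        if rng.random() < 0.85:
            polar.append("C(=O)O")
        polar += ["O"] * int(rng.integers(0, 3))
        for frag in polar:
            sites = _eligible_carbons(rd)
            if not sites:
                break
            out = _attach(rd, sites[int(rng.integers(len(sites)))], frag)
            if out is not None:
                rd = out
        while Descriptors.MolWt(rd) < target:
            sites = _eligible_carbons(rd)
            if not sites:
                break
            frag = hydrophobic_frags[int(rng.integers(len(hydrophobic_frags)))]
            out = _attach(rd, sites[int(rng.integers(len(sites)))], frag)
            if out is None:
                break
            rd = out
        smi = Chem.MolToSmiles(rd)
        if smi in seen:
            continue
        seen.add(smi)
        mols.append(Molecule(identifier=f"pool_{len(mols):05d}",
                             rdmol=Chem.MolFromSmiles(smi), source_tag="pool"))
    return mols


# --------------------------------------------------------------------------
# simulated reporter-assay plates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AssaySimSpec:
    """Ground truth for a simulated concentration–response campaign.

    The reporter signal follows ``RLU = RFU · scale · f(c) · (1 + ε)`` with
    ``f`` the 4PL response in fold units and ε ~ N(0, noise_cv²);
    RFU ~ N(µ, (0.1µ)²), reduced to 30% above ``cytotox_threshold``.
    """

    ec50: float = 13.88          # µM
    hill: float = 2.0
    top: float = 16.0            # fold activation plateau
    bottom: float = 1.0          # vehicle-level fold
    noise_cv: float = 0.10
    concentrations: tuple[float, ...] = tuple(np.geomspace(0.5, 30.0, 8).round(4))
    replicates: int = 4
    experiments: int = 3
    cytotox_threshold: float | None = None   # µM
    compound_id: str = "cpd"
    positive_fold: float = 18.59  # positive-control fold over vehicle
    rfu_mean: float = 20000.0
    rlu_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.experiments < 3:
            raise ValueError("need >= 3 experiments for SEM aggregation")


def simulate_assay(spec: AssaySimSpec) -> pd.DataFrame:
    """Simulate a plate table (schema of :mod:`pharmscreen.bioassay`).

    Each experiment contains vehicle and positive-control wells plus
    ``replicates`` compound wells per concentration; cytotoxicity reduces the
    EGFP channel to 30% of its mean above the threshold.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []

    def rfu_draw(cytotoxic: bool) -> float:
        mu = spec.rfu_mean * (0.3 if cytotoxic else 1.0)
        return float(max(rng.normal(mu, 0.1 * spec.rfu_mean), 1.0))

    def well(exp, cond, cid, conc, rep, response, cytotoxic=False):
        rfu = rfu_draw(cytotoxic)
        eps = rng.normal(0.0, spec.noise_cv) if spec.noise_cv > 0 else 0.0
        rlu = max(rfu * spec.rlu_scale * response * (1.0 + eps), 0.0)
        rows.append({"experiment": exp, "condition": cond, "compound_id": cid,
                     "conc_uM": conc, "replicate": rep, "rlu": rlu, "rfu": rfu})

    for exp in range(1, spec.experiments + 1):
        for rep in range(1, spec.replicates + 1):
            well(exp, "vehicle", "DMSO", 0.0, rep, spec.bottom)
            well(exp, "positive", "positive_control", 10.0, rep, spec.positive_fold)
        for conc in spec.concentrations:
            f = float(fourpl(np.array([conc]), spec.bottom, spec.top,
                             np.log10(spec.ec50), spec.hill)[0])
            toxic = spec.cytotox_threshold is not None and conc > spec.cytotox_threshold
            for rep in range(1, spec.replicates + 1):
                well(exp, "compound", spec.compound_id, conc, rep, f, cytotoxic=toxic)
    return pd.DataFrame(rows)
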