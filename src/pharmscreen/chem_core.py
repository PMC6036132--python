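"""Molecule container, file I/O, descriptors, fingerprints and conformer generation.

Everything downstream (feature perception, screening, decoy generation,
chemical-space projection) consumes the types defined here.  Molecules wrap an
RDKit ``Mol``; conformers live on the wrapped molecule and are mirrored as
plain :class:`Conformer` records (coordinates in Å, strain energy in kcal/mol
relative to the ensemble minimum).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolAlign, rdMolDescriptors

logger = logging.getLogger(__name__)

__all__ = [
    "Molecule",
    "Conformer",
    "ConformerSettings",
    "DescriptorBlock",
    "Fingerprint",
    "read_library",
    "write_smiles",
    "compute_descriptors",
    "descriptor_table",
    "fingerprint",
    "tanimoto",
    "generate_conformers",
]


@dataclass(eq=False)
class Conformer:
    """A single 3D geometry: per-atom Cartesian coordinates (Å) and relative
    strain energy (kcal/mol, >= 0 with respect to the ensemble minimum)."""

    coordinates: np.ndarray
    energy: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if self.energy < -1e-9:
            raise ValueError("conformer energy must be >= 0 relative to the ensemble minimum")


@dataclass(eq=False)
class Molecule:
    """A small molecule with optional 3D conformers.

    ``identifier`` must be unique within a library; ``source_tag`` records the
    library of origin.  ``rdmol`` carries connectivity and any conformers.
    """

    identifier: str
    rdmol: Chem.Mol
    source_tag: str = ""
    conformers: list[Conformer] = field(default_factory=list)
    unscreenable: bool = False

    def __post_init__(self) -> None:
        if self.heavy_atom_count < 1:
            raise ValueError(f"molecule {self.identifier!r} has no heavy atoms")

    @classmethod
    def from_smiles(cls, smiles: str, identifier: str, source_tag: str = "") -> "Molecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES for {identifier!r}: {smiles}")
        return cls(identifier=identifier, rdmol=mol, source_tag=source_tag)

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.rdmol.GetAtoms() if a.GetAtomicNum() > 1)

    @property
    def atoms(self) -> list[tuple[str, int]]:
        return [(a.GetSymbol(), a.GetFormalCharge()) for a in self.rdmol.GetAtoms()]

    @property
    def bonds(self) -> list[tuple[tuple[int, int], float, bool]]:
        return [
            ((b.GetBeginAtomIdx(), b.GetEndAtomIdx()), b.GetBondTypeAsDouble(), b.GetIsAromatic())
            for b in self.rdmol.GetBonds()
        ]

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    def smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)

    def canonical_id(self) -> str:
        """Canonical structure identifier for cross-library deduplication:
        canonical SMILES of the largest fragment (salts stripped, charges kept)."""
        frags = Chem.GetMolFrags(self.rdmol, asMols=True, sanitizeFrags=False)
        largest = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        return Chem.MolToSmiles(largest)

    def heavy_atom_coords(self, conformer_index: int = 0) -> np.ndarray:
        conf = self.conformers[conformer_index]
        idx = [a.GetIdx() for a in self.rdmol.GetAtoms() if a.GetAtomicNum() > 1]
        return conf.coordinates[idx]


@dataclass(frozen=True)
class ConformerSettings:
    """Conformer-ensemble generation budget.

    ``rms_threshold`` (Å) is the minimum pairwise heavy-atom best-fit RMSD
    between retained conformers; ``energy_window`` (kcal/mol) bounds strain
    relative to the ensemble minimum; ``max_pool`` caps the raw embedding
    pool and ``max_conformers`` the retained ensemble.
    """

    timeout_s: float = 600.0
    rms_threshold: float = 0.8
    energy_window: float = 20.0
    max_pool: int = 4000
    max_conformers: int = 200

    def __post_init__(self) -> None:
        for name in ("timeout_s", "rms_threshold", "energy_window", "max_pool", "max_conformers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_conformers > self.max_pool:
            raise ValueError("max_conformers must be <= max_pool")


#: High-quality profile used for small libraries.
BEST = ConformerSettings()
#: Reduced-cost profile for large libraries (same filters, smaller ensemble).
FAST = ConformerSettings(max_conformers=25)


@dataclass(frozen=True)
class DescriptorBlock:
    """1D physicochemical profile used for decoy matching and chemical-space
    projection."""

    molecular_weight: float
    logp_estimate: float
    tpsa: float
    hbd_count: int
    hba_count: int
    rotatable_bonds: int
    ring_count: int
    heavy_atom_count: int
    aromatic_atom_fraction: float
    conjugated_bond_fraction: float
    net_charge: int

    FIELDS = (
        "molecular_weight", "logp_estimate", "tpsa", "hbd_count", "hba_count",
        "rotatable_bonds", "ring_count", "heavy_atom_count",
        "aromatic_atom_fraction", "conjugated_bond_fraction", "net_charge",
    )

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.FIELDS}


@dataclass(frozen=True)
class Fingerprint:
    """2048-bit circular (radius-2) topology fingerprint."""

    bits: np.ndarray

    N_BITS = 2048
    RADIUS = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))
        if self.bits.shape != (self.N_BITS,):
            raise ValueError(f"fingerprint must have {self.N_BITS} bits")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def read_library(path: str | Path, fmt: str | None = None, source_tag: str = "") -> list[Molecule]:
    """Read a molecule library from a ``.smi`` (one record per line, whitespace
    separated identifier) or SDF V2000 file.

    Multi-conformer SDF input is supported via consecutive records sharing an
    identifier: their geometries are collected on a single molecule.  Invalid
    records are skipped and counted; an unreadable file or a file with zero
    valid records raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {"smi": "smiles", "smiles": "smiles", "sdf": "sdf", "mol": "sdf"}.get(
            path.suffix.lstrip(".").lower(), "smiles")
    source_tag = source_tag or path.stem

    mols: list[Molecule] = []
    skipped = 0
    if fmt == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            ident = parts[1].strip() if len(parts) > 1 else f"{source_tag}_{lineno}"
            rd = Chem.MolFromSmiles(smiles)
            if rd is None:
                skipped += 1
                logger.warning("skipping unparsable SMILES record at line %d of %s", lineno, path)
                continue
            mols.append(Molecule(identifier=ident, rdmol=rd, source_tag=source_tag))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        by_id: dict[str, Molecule] = {}
        for i, rd in enumerate(supplier):
            if rd is None:
                skipped += 1
                logger.warning("skipping unparsable SDF record %d of %s", i, path)
                continue
            ident = rd.GetProp("_Name") if rd.HasProp("_Name") and rd.GetProp("_Name") else f"{source_tag}_{i}"
            confs = []
            if rd.GetNumConformers() > 0:
                confs = [Conformer(rd.GetConformer().GetPositions(), 0.0)]
            if ident in by_id:
                by_id[ident].conformers.extend(confs)
            else:
                mol = Molecule(identifier=ident, rdmol=rd, source_tag=source_tag, conformers=confs)
                by_id[ident] = mol
                mols.append(mol)
    else:
        raise ValueError(f"unknown library format: {fmt!r}")

    if not mols:
        raise ValueError(f"no valid records in {path}")
    ids = [m.identifier for m in mols]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate identifiers in {path}")
    logger.info("read %d molecules (%d skipped) from %s", len(mols), skipped, path)
    return mols


def write_smiles(mols: list[Molecule], path: str | Path) -> None:
    lines = [f"{m.smiles()} {m.identifier}" for m in mols]
    Path(path).write_text("\n".join(lines) + "\n")


def compute_descriptors(mol: Molecule) -> DescriptorBlock:
    """Compute the 1D physicochemical descriptor block.

    The logP estimate is an atomic-contribution (Crippen-type) value; the
    descriptors are deterministic for a given molecule.  Degenerate single-atom
    molecules return zeros for bond/ring-derived fields.
    """
    rd = mol.rdmol
    n_heavy = mol.heavy_atom_count
    n_bonds = rd.GetNumBonds()
    n_aromatic = sum(1 for a in rd.GetAtoms() if a.GetIsAromatic())
    n_conj = sum(1 for b in rd.GetBonds() if b.GetIsConjugated())
    return DescriptorBlock(
        molecular_weight=Descriptors.MolWt(rd),
        logp_estimate=Crippen.MolLogP(rd),
        tpsa=rdMolDescriptors.CalcTPSA(rd),
        hbd_count=rdMolDescriptors.CalcNumHBD(rd),
        hba_count=rdMolDescriptors.CalcNumHBA(rd),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(rd),
        ring_count=rdMolDescriptors.CalcNumRings(rd),
        heavy_atom_count=n_heavy,
        aromatic_atom_fraction=n_aromatic / n_heavy if n_heavy else 0.0,
        conjugated_bond_fraction=n_conj / n_bonds if n_bonds else 0.0,
        net_charge=Chem.GetFormalCharge(rd),
    )


def descriptor_table(mols: list[Molecule]):
    """Descriptor blocks for a library as a pandas DataFrame (one row per
    molecule, indexed by identifier)."""
    import pandas as pd

    rows = {m.identifier: compute_descriptors(m).as_dict() for m in mols}
    return pd.DataFrame.from_dict(rows, orient="index")


def fingerprint(mol: Molecule) -> Fingerprint:
    """Radius-2 circular fingerprint folded to 2048 bits."""
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=Fingerprint.RADIUS,
                                                    fpSize=Fingerprint.N_BITS)
    bv = gen.GetFingerprint(mol.rdmol)
    arr = np.zeros(Fingerprint.N_BITS, dtype=bool)
    arr[list(bv.GetOnBits())] = True
    return Fingerprint(arr)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a∩b| / |a∪b| in [0, 1].

    Two all-zero fingerprints have undefined similarity; defined here as 0
    with a warning.
    """
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        warnings.warn("tanimoto of two empty fingerprints defined as 0", stacklevel=2)
        return 0.0
    return inter / union


def generate_conformers(mol: Molecule, settings: ConformerSettings = BEST,
                        seed: int = 42) -> list[Conformer]:
    """Generate a strain-filtered, diversity-pruned conformer ensemble.

    Distance-geometry embedding with a fixed random seed, force-field
    relaxation, then: energies re-expressed relative to the ensemble minimum,
    conformers outside ``energy_window`` dropped, and greedy RMSD pruning so
    every retained pair differs by >= ``rms_threshold`` heavy-atom best-fit
    RMSD.  At most ``max_conformers`` are kept (lowest energy first).

    On embedding failure the molecule is flagged un-screenable and an empty
    list is returned (not fatal).
    """
    rd = Chem.AddHs(Chem.Mol(mol.rdmol))
    n_embed = int(min(settings.max_pool, max(2 * settings.max_conformers, 4)))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = -1.0
    params.useRandomCoords = False
    cids = AllChem.EmbedMultipleConfs(rd, numConfs=n_embed, params=params)
    if len(cids) == 0:
        mol.unscreenable = True
        logger.warning("3D embedding failed for %s; flagged un-screenable", mol.identifier)
        return []

    energies: list[tuple[int, float]] = []
    if AllChem.MMFFHasAllMoleculeParams(rd):
        results = AllChem.MMFFOptimizeMoleculeConfs(rd, maxIters=200)
    else:
        results = AllChem.UFFOptimizeMoleculeConfs(rd, maxIters=200)
    for cid, (converged, energy) in zip(cids, results):
        energies.append((cid, float(energy)))

    e_min = min(e for _, e in energies)
    pool = [(cid, e - e_min) for cid, e in energies if e - e_min <= settings.energy_window]
    pool.sort(key=lambda t: t[1])

    rd_noH = Chem.RemoveHs(rd)
    kept: list[tuple[int, float]] = []
    for cid, rel_e in pool:
        if len(kept) >= settings.max_conformers:
            break
        if all(rdMolAlign.GetBestRMS(rd_noH, rd_noH, prbId=cid, refId=kcid) >= settings.rms_threshold
               for kcid, _ in kept):
            kept.append((cid, rel_e))

    heavy_idx = [a.GetIdx() for a in rd.GetAtoms() if a.GetAtomicNum() > 1]
    # heavy-atom order in the H-stripped embedding matches the input molecule
    conformers = []
    for cid, rel_e in kept:
        pos = rd.GetConformer(cid).GetPositions()[heavy_idx]
        conformers.append(Conformer(pos, rel_e))

    mol.conformers = conformers
    mol.unscreenable = False
    return conformers
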