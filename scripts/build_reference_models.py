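"""Regenerate the packaged reference pharmacophore models (BAMS22 / TTM8).

The feature compositions are the published ones; the geometry is produced
deterministically by this package's own perception on public training
structures (taurolithocholic acid for the bile-acid model, oleanolic acid for
the triterpene model), so no proprietary model file is reproduced.  Run from
the repository root:

    python scripts/build_reference_models.py
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np

from pharmscreen.chem_core import ConformerSettings, Molecule, generate_conformers
from pharmscreen.pharmacophore import (
    FeatureKind,
    PharmacophoreFeature,
    PharmacophoreModel,
    add_exclusion_coat,
    perceive_features,
    save_model,
)
from pharmscreen.synthetic_data import ACTIVE_SCAFFOLDS

SEED = 2024
OUT = Path(__file__).resolve().parents[1] / "src" / "pharmscreen" / "data"


def _pick_pair_max_sep(feats):
    return max(itertools.combinations(feats, 2),
               key=lambda p: np.linalg.norm(p[0].center - p[1].center))


def _farthest_point_pick(feats, k):
    chosen = [max(feats, key=lambda f: np.linalg.norm(f.center))]
    rest = [f for f in feats if f is not chosen[0]]
    while len(chosen) < k and rest:
        nxt = max(rest, key=lambda f: min(np.linalg.norm(f.center - c.center) for c in chosen))
        chosen.append(nxt)
        rest.remove(nxt)
    return chosen


def build_bams22() -> PharmacophoreModel:
    mol = Molecule.from_smiles(ACTIVE_SCAFFOLDS["taurolithocholic_acid"], "TLC")
    generate_conformers(mol, ConformerSettings(max_pool=30, max_conformers=1), seed=SEED)
    fs = perceive_features(mol, 0)
    by_kind = {k: [f for f in fs.features if f.kind is k] for k in FeatureKind}

    hba_pair = _pick_pair_max_sep(by_kind[FeatureKind.HBA])
    hyd = _farthest_point_pick(by_kind[FeatureKind.HYDROPHOBIC], 3)
    # optional donor: closest to a mandatory acceptor without coinciding with
    # one (a hydroxyl O is both donor and acceptor; centers must stay distinct)
    hbd_cands = [f for f in by_kind[FeatureKind.HBD]
                 if all(np.linalg.norm(f.center - a.center) > 0.1 for a in hba_pair)]
    hbd = min(hbd_cands,
              key=lambda f: min(np.linalg.norm(f.center - a.center) for a in hba_pair))
    neg = by_kind[FeatureKind.NEG_IONIZABLE][0]

    feats = [
        PharmacophoreFeature(FeatureKind.HYDROPHOBIC, hyd[0].center),
        PharmacophoreFeature(FeatureKind.HYDROPHOBIC, hyd[1].center),
        PharmacophoreFeature(FeatureKind.HBA, hba_pair[0].center),
        PharmacophoreFeature(FeatureKind.HBA, hba_pair[1].center),
        PharmacophoreFeature(FeatureKind.HBD, hbd.center, optional=True),
        PharmacophoreFeature(FeatureKind.HYDROPHOBIC, hyd[2].center, optional=True),
        PharmacophoreFeature(FeatureKind.NEG_IONIZABLE, neg.center, optional=True),
    ]
    model = PharmacophoreModel("BAMS22", feats)
    return add_exclusion_coat(model, [mol.conformers[0]])


def build_ttm8() -> PharmacophoreModel:
    mol = Molecule.from_smiles(ACTIVE_SCAFFOLDS["oleanolic_acid"], "oleanolic_acid")
    generate_conformers(mol, ConformerSettings(max_pool=30, max_conformers=1), seed=SEED)
    fs = perceive_features(mol, 0)
    by_kind = {k: [f for f in fs.features if f.kind is k] for k in FeatureKind}

    hyd = _farthest_point_pick(by_kind[FeatureKind.HYDROPHOBIC], 4)
    hba_pair = _pick_pair_max_sep(by_kind[FeatureKind.HBA])
    neg = by_kind[FeatureKind.NEG_IONIZABLE][0]

    feats = [PharmacophoreFeature(FeatureKind.HYDROPHOBIC, f.center) for f in hyd]
    feats += [PharmacophoreFeature(FeatureKind.HBA, f.center) for f in hba_pair]
    feats.append(PharmacophoreFeature(FeatureKind.NEG_IONIZABLE, neg.center))
    model = PharmacophoreModel("TTM8", feats)
    return add_exclusion_coat(model, [mol.conformers[0]])


if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    for builder, fname in [(build_bams22, "bams22.json"), (build_ttm8, "ttm8.json")]:
        model = builder()
        save_model(model, OUT / fname)
        print(f"{model.name}: {len(model.mandatory_features)} mandatory + "
              f"{len(model.optional_features)} optional features, "
              f"{len(model.exclusions)} exclusion spheres -> {OUT / fname}")
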