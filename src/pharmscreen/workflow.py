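"""Campaign orchestration: cluster -> build models -> validate -> screen ->
prioritize -> rank, with config, logging and provenance.

The pipeline mirrors a three-level screening campaign: (1) training-set
clustering and pharmacophore model generation with theoretical validation
against decoys, (2) virtual screening of the library with the validated
models, (3) hit triage (RDF pharmacophore clustering, shape TanimotoCombo
against the best-fitting query pose, descriptor-PCA chemical space with Ward
grouping, PAINS alerts) and ranking.  Every random draw flows from the config
seed; each run writes a resolved-config copy next to its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioassay, chem_core, pharmacophore, prioritization, screening, synthetic_data

logger = logging.getLogger(__name__)


@dataclass
class CampaignConfig:
    """Resolved configuration of a screening campaign.

    ``conformer_profile`` selects BEST (full ensembles) or FAST (reduced
    ensembles); the synthetic benchmark sizes control the offline ground-truth
    library when no external files are given.
    """

    seed: int = 7
    conformer_profile: str = "FAST"
    max_conformers: int | None = 3        # override for desk-scale runs
    n_training: int = 6
    n_actives: int = 24
    n_inactives: int = 16
    pool_size: int = 1500
    decoys_per_active: int = 8
    max_omitted: int = 0
    cluster_threshold: float = 0.9
    chemspace_groups: int = 9
    active_threshold: float = 50.0
    weak_threshold: float = 15.0
    library_path: str | None = None
    model_paths: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CampaignConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def conformer_settings(self) -> chem_core.ConformerSettings:
        base = chem_core.BEST if self.conformer_profile.upper() == "BEST" else chem_core.FAST
        if self.max_conformers is not None:
            base = chem_core.ConformerSettings(
                timeout_s=base.timeout_s, rms_threshold=base.rms_threshold,
                energy_window=base.energy_window, max_pool=base.max_pool,
                max_conformers=self.max_conformers)
        return base


def run_pipeline(config: CampaignConfig, outdir: str | Path) -> dict:
    """Execute the full campaign on the synthetic benchmark (or configured
    library) and write stage outputs + a resolved-config audit copy.

    Returns the campaign report dictionary.  Any stage failure raises with a
    stage-specific message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(asdict(config)))
    rng = np.random.default_rng(config.seed)
    report: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # ---- library -------------------------------------------------------
    stage("library")
    if config.library_path:
        mols = chem_core.read_library(config.library_path)
        labels = {m.identifier: {"active": None} for m in mols}
    else:
        mols, labels = synthetic_data.build_molecular_benchmark(
            config.n_actives, config.n_inactives, seed=config.seed)
    settings = config.conformer_settings()
    screenable = []
    for m in mols:
        chem_core.generate_conformers(m, settings, seed=int(rng.integers(2**31 - 1)))
        if m.n_conformers:
            screenable.append(m)
    report["stages"]["library"] = {"n_molecules": len(mols), "n_screenable": len(screenable)}

    actives = [m for m in screenable if labels[m.identifier].get("active")]
    inactives = [m for m in screenable if labels[m.identifier].get("active") is False]
    if len(actives) < config.n_training:
        raise RuntimeError("library stage: not enough screenable actives for training")

    # ---- training-set clustering & model building ----------------------
    stage("cluster")
    assignment = prioritization.cluster_by_pharmacophore(
        actives, threshold=config.cluster_threshold)
    report["stages"]["cluster"] = {"n_clusters": assignment.n_clusters}

    stage("build-model")
    by_cluster: dict[int, list] = {}
    for m in actives:
        by_cluster.setdefault(assignment.labels[m.identifier], []).append(m)
    top = max(by_cluster.values(), key=len)
    training = top[:config.n_training]
    info: dict = {}
    model = pharmacophore.build_shared_model(training, name="campaign_model", info=info)
    if model is None:
        raise RuntimeError("build-model stage: no shared feature set among training ligands")
    # the coat must live in the model frame = the reference ligand's conformer
    ref = training[info["reference_ligand_index"]]
    model = pharmacophore.add_exclusion_coat(
        model, [ref.conformers[info["reference_conformer_index"]]])
    pharmacophore.save_model(model, outdir / "model.json")
    report["stages"]["build_model"] = {
        "n_features": len(model.features),
        "n_mandatory": len(model.mandatory_features),
        "n_exclusions": len(model.exclusions),
    }

    # ---- theoretical validation (decoys + metrics) ---------------------
    stage("make-decoys")
    pool = synthetic_data.random_druglike_pool(config.pool_size, seed=config.seed + 1)
    decoys, _ = synthetic_data.generate_decoys(actives, pool,
                                               per_active=config.decoys_per_active)
    for d in decoys:
        chem_core.generate_conformers(d, settings, seed=int(rng.integers(2**31 - 1)))
    decoys = [d for d in decoys if d.n_conformers]
    report["stages"]["decoys"] = {"n_decoys": len(decoys)}

    stage("validate")
    validation = actives + inactives + decoys
    val_report = screening.screen_library([model], validation, config.max_omitted)
    hitset = set(val_report.hits)
    tp = sum(1 for m in actives if m.identifier in hitset)
    fp = sum(1 for m in inactives + decoys if m.identifier in hitset)
    fn = len(actives) - tp
    tn = len(inactives) + len(decoys) - fp
    metrics = screening.compute_enrichment(tp, fp, tn, fn)
    report["stages"]["validate"] = metrics.as_dict()
    pd.DataFrame([metrics.as_dict()]).to_csv(outdir / "validation_metrics.csv", index=False)

    # ---- virtual screening --------------------------------------------
    stage("screen")
    screen_report = screening.screen_library([model], screenable, config.max_omitted)
    hits = [m for m in screenable if m.identifier in set(screen_report.hits)]
    screen_report.to_frame().to_csv(outdir / "hits.csv", index=False)
    report["stages"]["screen"] = {"n_hits": len(hits)}
    if not hits:
        raise RuntimeError("screen stage: no virtual hits retrieved")

    # ---- prioritization ------------------------------------------------
    stage("prioritize")
    if config.chemspace_groups > len(hits):
        raise RuntimeError(
            f"prioritize stage: chemspace_groups={config.chemspace_groups} exceeds "
            f"the {len(hits)} virtual hits")
    desc = chem_core.descriptor_table(hits)
    space = prioritization.chemspace_project(desc)
    groups = prioritization.ward_cluster(space.scores, k=config.chemspace_groups)

    # query pose: best-fitting conformation of the top-scoring hit
    best_hit = max(hits, key=lambda m: screen_report.best_match(m.identifier).fit_score)
    q_match = screen_report.best_match(best_hit.identifier)
    q_coords = q_match.transform.apply(best_hit.heavy_atom_coords(q_match.conformer_index))
    q_feats = pharmacophore.perceive_features(best_hit, q_match.conformer_index).features
    q_feats = [pharmacophore.PharmacophoreFeature(f.kind, q_match.transform.apply(f.center[None])[0],
                                                  f.tolerance) for f in q_feats]

    rows = []
    for m in hits:
        res = screen_report.best_match(m.identifier)
        coords = res.transform.apply(m.heavy_atom_coords(res.conformer_index))
        feats = pharmacophore.perceive_features(m, res.conformer_index).features
        feats = [pharmacophore.PharmacophoreFeature(f.kind, res.transform.apply(f.center[None])[0],
                                                    f.tolerance) for f in feats]
        sc = prioritization.shape_color_scores(q_coords, q_feats, coords, feats)
        pains = prioritization.pains_screen(m)
        rows.append({
            "molecule_id": m.identifier, "fit_score": res.fit_score,
            "tanimoto_combo": sc.tanimoto_combo, "shape_tanimoto": sc.shape_tanimoto,
            "color_tanimoto": sc.color_tanimoto, "group": groups[m.identifier],
            "pains_alerts": ";".join(pains.alerts),
            "active_label": labels[m.identifier].get("active"),
        })
    hit_table = pd.DataFrame(rows).sort_values(
        ["tanimoto_combo", "fit_score"], ascending=False).reset_index(drop=True)
    hit_table.to_csv(outdir / "prioritized_hits.csv", index=False)
    report["stages"]["prioritize"] = {
        "n_groups": len(set(groups.values())),
        "n_pains_flagged": int((hit_table["pains_alerts"] != "").sum()),
    }

    # ---- ranked selection ---------------------------------------------
    stage("rank")
    selection = (hit_table[hit_table["pains_alerts"] == ""]
                 .groupby("group", group_keys=False).head(2))
    selection.to_csv(outdir / "selection.csv", index=False)
    report["stages"]["rank"] = {"n_selected": int(len(selection))}

    (outdir / "campaign_report.json").write_text(json.dumps(report, indent=1))
    return report


def assay_report(plate: pd.DataFrame, low_uM: float = 5.0, high_uM: float = 20.0) -> pd.DataFrame:
    """Analyze a screening plate: normalization, cytotoxicity, activity calls.

    Output columns mirror the campaign reporting shape: per-compound percent
    activation (mean ± SEM) at the two screening concentrations, cytotoxicity
    flags and the activity class.
    """
    norm = bioassay.normalize_plate(plate)
    agg = bioassay.aggregate_activity(norm)
    tox = bioassay.flag_cytotoxicity(plate)
    tox_map = {(r.compound_id, r.conc_uM): bool(r.cytotoxic) for r in tox.itertuples()}
    rows = []
    for cid, grp in agg.groupby("compound_id"):
        def level(c):
            sub = grp[np.isclose(grp["conc_uM"], c)]
            return (float(sub["pct_mean"].iloc[0]), float(sub["pct_sem"].iloc[0])) \
                if len(sub) else (None, None)
        (p_lo, s_lo), (p_hi, s_hi) = level(low_uM), level(high_uM)
        t_lo = tox_map.get((cid, low_uM), False)
        t_hi = tox_map.get((cid, high_uM), False)
        call = bioassay.classify_activity(cid, p_lo, p_hi, t_lo, t_hi)
        rows.append({"compound_id": cid, "pct_low": p_lo, "sem_low": s_lo,
                     "cytotoxic_low": t_lo, "pct_high": p_hi, "sem_high": s_hi,
                     "cytotoxic_high": t_hi, "class": call.call})
    return pd.DataFrame(rows)
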