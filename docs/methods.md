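# Methods

This note records the models, rules and numerical choices behind
`pharmscreen`, and what the synthetic benchmarks do and do not establish.

## Feature perception

Pharmacophoric features are perceived from 2D structure plus one conformer's
coordinates, by a fixed rule table:

* **HBD** — any O–H or N–H (feature at the heteroatom).
* **HBA** — any non-cationic oxygen; nitrogens that are neither amide N,
  cationic, nor aromatic N–H.
* **NEG_IONIZABLE** — carboxylic acid/carboxylate, sulfonic acid/sulfonate,
  phosphate, tetrazole; feature at the group centroid.
* **POS_IONIZABLE** — quaternary N; non-amide, non-anilinic sp3 amines;
  amidine/guanidine (group centroid).
* **AROMATIC** — each fully aromatic ring's centroid.  Aromatic atoms are
  claimed by these features and excluded from hydrophobic grouping, so
  benzene carries exactly one feature.
* **HYDROPHOBIC** — maximal connected groups of ≥3 eligible atoms
  (non-aromatic carbon, halogen, divalent sulfur, none bonded to a charged or
  N/O atom).  Compact groups (≤6 atoms) give one centroid feature.  Larger
  components are split topologically: one feature per non-aromatic ring with
  ≥3 eligible members plus acyclic remainder chunks of ≥3 atoms.  The split
  is the deliberate design choice here: without it an entire steroid or
  triterpene skeleton collapses into a single hydrophobic point, which makes
  multi-point hydrophobic models (and the published bile-acid/triterpene
  model compositions, with 2–4 hydrophobic features each) unreachable.
  Because the partition is purely topological, perception stays deterministic
  and covariant with rigid motion.

A hydroxyl oxygen is perceived as both donor and acceptor at the same
position; during model assembly coincident centers are collapsed to one
feature (mandatory wins) because a model's feature centers must be distinct.

Hydrogen-bond direction vectors are not modeled; all features are
center + tolerance spheres.  Default tolerance 1.5 Å, exclusion-sphere radius
1.0 Å — conventional ligand-based defaults.

## Model building

Training ligands contribute one feature set per conformer.  Every ligand is
tried as the alignment reference: for each other ligand, kind-compatible
feature triplets are enumerated (pruned by internal-distance compatibility,
|Δd| ≤ 2 × pairing distance), superposed by least squares, greedily paired
one-to-one within the 1.5 Å pairing distance, and polished by up to two
rounds of re-superposition on all paired features (an ICP step that rescues
near-misses outside the seed triplet).  The reference yielding the most
universally matched features wins; this makes building robust to a
distractor-rich reference, which a fixed most-features-first choice is not.

*Shared* models keep only features matched by **every** training ligand (all
mandatory, centers = contributor centroids); *merged* models add the
remaining aligned features as optional.  Fewer than three shared features is
an explicit "no model" outcome.  A single training ligand degenerates to its
own feature set.

The exclusion coat samples a 1 Å grid over the aligned training conformers'
bounding box (+4 Å margin), keeps points whose distance to the nearest
training heavy atom lies in [2.5, 3.5] Å, and farthest-point downsamples to
≤100 spheres — a shell that hugs the common surface without touching the
training ligands.

Packaged reference models reproduce the published feature *compositions* of
the two production models (bile-acid type: 2 hydrophobic + 2 acceptor
mandatory, donor/hydrophobic/negatively-ionizable optional; triterpene type:
4 hydrophobic + 2 acceptor + 1 negatively ionizable, all mandatory).  Their
geometry is regenerated deterministically from public training structures
(taurolithocholic acid, oleanolic acid) by this package's own perception —
the original models' coordinates are unpublished and numeric parity is a
non-goal.

## Matching and screening

Correspondence enumeration covers all mandatory features except at most
`max_omitted`, pruned by pairwise distance compatibility with threshold
2 × tolerance (the triangle-inequality bound on what a rigid alignment could
repair, so the pruning is lossless).  Each correspondence is aligned by the
Kabsch solution (proper rotation enforced; under 3 pairs a translation-only
fallback is used with a warning); a match is accepted iff every paired
feature lands inside the model feature's tolerance sphere and no ligand heavy
atom enters an exclusion sphere.  Optional features extend an accepted match
greedily.  Across conformers the best accepted result wins (score, then lower
RMSD, then lower conformer index).

The fit score `10·matched − 3·feature_rmsd` is this package's own documented
scoring function (commercial fit scores are proprietary); it is strictly
increasing in matched features and decreasing in geometric error, which is
all the pipeline relies on.

Enrichment metrics follow the standard confusion-count definitions; EF is
undefined (reported as such) when nothing is retrieved.  Values are kept at
full precision and rounded only for reporting.

## Conformer ensembles

Distance-geometry embedding (seeded, deterministic) followed by force-field
relaxation; energies are re-expressed relative to the ensemble minimum,
conformers above the 20 kcal/mol window are dropped, and greedy pruning
enforces ≥0.8 Å pairwise heavy-atom best-fit RMSD, capped at the profile's
maximum (BEST 200 / FAST 25 conformers, pool ≤4,000).  The embedding pool is
sized at twice the requested ensemble — a cost/coverage compromise for
desk-scale runs; ensembles carry all the flexibility used during matching
(no on-the-fly torsion fitting).

## Prioritization

* **RDF vectors**: 21 unordered feature-kind pairs × 60 radii (0.25–15 Å,
  step 0.25), Gaussian smoothing `exp(−B(r−d)²)` with B = 4 Å⁻²; invariant to
  rigid motion and feature order.  Molecule similarity is the max cosine over
  up to 3 conformers each; clustering is complete-linkage on 1 − cosine with
  a 0.9 cut (the cut semantics are parameterized since the original tool's
  internal meaning is undocumented).
* **Shape/color scores**: heavy-atom Gaussians with amplitude 2.7 and width
  chosen so a lone atom integrates to a 1.7 Å hard-sphere volume;
  pairwise-overlap approximation (triple overlaps ignored, hydrogens
  ignored).  Color uses σ = 1.0 Å Gaussians over same-kind features.  Both
  Tanimoto components are exactly 1 on self, so the combo attains its upper
  bound 2 on self-comparison.  Poses come from pharmacophore alignment;
  optional local rigid refinement (Nelder–Mead, ≤200 iterations) is off by
  default to mirror that use.
* **Chemical space**: PCA of the z-scored descriptor block with sign
  conventions making PC1 a size axis (positive molecular-weight loading),
  PC2 aromaticity/conjugation and PC3 lipophilicity; constant columns are
  dropped with a warning.  Grouping is Ward minimum-variance on PC1–PC3
  (Euclidean), exact group count k (default 9).  This is a locally trained
  projection used for diversity triage, not a reproduction of any external
  reference map's coordinates.
* **PAINS**: the published substructure alert families A/B/C, via RDKit's
  filter catalog; purely 2D, conformer-independent.

## Assay analysis

Per experiment: nRLU = RLU/RFU, fold = nRLU / mean(vehicle), percent =
100·(nRLU − vehicle)/(positive − vehicle); aggregation is replicate means
within experiments, then mean ± SEM across ≥3 experiments.  Percent is
invariant to rescaling all RLU; fold to jointly rescaling RLU and RFU.
Cytotoxicity: one-way ANOVA on RFU across conditions, then Bonferroni-
corrected Welch comparisons against vehicle at α = 0.05; a group is flagged
iff its mean is lower and significant; <3 replicates is reported as
insufficient data rather than a call.  Activity classes: ≥50% of the positive
control at either screening concentration → active, ≥15% → weak, cytotoxic at
both → not evaluable.

The 4PL fit runs Levenberg–Marquardt least squares in
(bottom, top, log10 EC50, h) with tolerance 1e-8 and a bounded evaluation
budget; initialization bottom = min, top = max, h = 1, EC50 from linear
interpolation of the mean response profile at half-span.  Constant responses
short-circuit to a flagged degenerate result; non-convergence is reported
honestly with the parameters.  An EC50 outside the tested concentration range
is reported but flagged as extrapolated, since potency beyond a cytotoxicity
limit is inherently uncertain.

## Synthetic ground truth

* **Planted feature clouds**: positives are the model's mandatory features
  with isotropic Gaussian jitter plus 0–2 random distractor features, in a
  random rigid frame; negatives carry the same feature multiset with kinds
  shuffled and the geometry rescaled so every pairwise distance moves by
  >2 × tolerance, then are rejection-verified to admit no correspondence —
  the rescaling alone cannot rule out accidental matches through permuted
  correspondences, so the verification makes the negative label true by
  construction.
* **Molecular benchmark**: public bile-acid and triterpene-acid structures
  (stereochemistry omitted; inputs are screened as given) expanded by small
  substituent decorations; inactives destroy one pharmacophoric group
  (acid → methyl ester removes the ionizable head; hydroxyl → methyl ether
  removes a donor) and record which.
* **Decoys**: candidates must sit inside the published decoy-generation
  property windows of a matched active (MW ±25 Da, logP ±1, HBD ±1, HBA ±2,
  rotatable bonds ±2, identical net charge) and keep circular-fingerprint
  Tanimoto <0.35 to *every* active.  The candidate pool is assembled from
  simple ring/chain cores grown toward random molecular-weight targets with
  mostly acidic, partly hydroxylated decoration — property-overlapping but
  topologically unlike fused polycyclics.
* **Plates**: RLU = RFU·scale·f(c)·(1+ε), ε ~ N(0, cv²), RFU ~ N(µ, (0.1µ)²)
  collapsing to 30% of µ above the cytotoxicity threshold; every experiment
  carries vehicle and positive-control wells (positive fold 18.59, a typical
  strong-agonist response at its reference concentration).

Simulation sizes used by the default test and acceptance runs (balance of
statistical resolution against a single-CPU run): planted benchmarks of
100 actives/1,000 decoys; EC50 recovery over 200 seeded campaigns of
8 concentrations (0.5–30 µM) × 4 replicates × 3 experiments at 10% noise,
Hill slope 2, plateaus 14.9- and 23.5-fold back-calculated from the reference
compounds' reported fold activation at 20 µM; 1,000-permutation EF null;
1,000-replicate cytotoxicity type-I simulation.

What passing these benchmarks shows — and does not.  The generators share the
matcher's *vocabulary* (feature kinds, tolerances) but not its code path for
positives; recovery therefore validates alignment, enumeration and scoring
end to end.  They do not emulate conformer-model error on real molecules,
tautomer/protonation ambiguity, assay-plate edge effects, or the property
distributions of commercial screening databases, so quantitative enrichment
on real campaigns will be lower than on planted libraries.

## Known limitations

* No directional H-bond features, feature weights, stereochemistry or
  tautomer handling; molecules are screened as given.
* The fit score and the locally trained chemical-space projection are
  internally consistent stand-ins, not reproductions of proprietary scores;
  published per-compound fit/TC values are out of numeric scope.
* Exclusion checks use heavy-atom centers without van der Waals radii.
* The cytotoxicity test pools replicates across experiments (no
  experiment-level random effect).
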