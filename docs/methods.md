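# Methods

`clusterrank` implements a machine-learning protocol for ranking clusters of
docked protein–protein complexes. This note records the model, its
assumptions, the parameters that matter, and the design choices taken where
the protocol left room.

## The ranking problem

Protein–protein docking produces thousands of candidate poses ("decoys") per
target, of which at most a handful resemble the bound complex. Scoring
single poses with one energy function is notoriously brittle: incorrect
binding sites frequently produce spuriously low energies. The protocol here
ranks *clusters* of poses instead, and replaces the single energy by the
distributions of many molecular descriptors within each cluster.

## Pipeline

1. **Normalisation and filtering.** All models of a target are truncated to
   the residues shared by every model (keyed by chain ID, author residue
   number and insertion code). Poses with a steric clash — any
   receptor–ligand atom pair strictly closer than the sum of the two van der
   Waals radii — are removed. Touching spheres are legal: "overlap" is read
   strictly, so the boundary case `d == r_i + r_j` passes. Hydrogens are
   excluded from clash checks by default (configurable); the radii table
   (H 1.2, C 1.7, N 1.55, O 1.52, S 1.8 Å, unknown elements 1.7 Å with a
   warning) ships as a packaged TSV and can be overridden.

2. **Quality measures.** LRMSD superposes receptor Cα atoms (Kabsch) and
   reports the ligand-Cα RMSD — deliberately Cα-only for both steps, with a
   backbone option. FNAT counts reference interface residue–residue
   contacts (any heavy-atom pair ≤ 5 Å) preserved by the model. IRMSD
   superposes on backbone (N, Cα, C, O) atoms of reference interface
   residues (heavy atom within 10 Å of the partner chain) and reports that
   fit RMSD. Quality classes (high/medium/acceptable/incorrect) come from a
   configurable threshold table on (fnat, lrmsd, irmsd) with the standard
   community defaults; externally supplied class labels are also accepted.

3. **Clustering.** GROMOS-style neighbour counting at a 10 Å LRMSD cutoff:
   the unassigned model with the most unassigned neighbours (distance ≤
   cutoff, inclusive) seeds each cluster; ties are broken by the
   lexicographically smallest model ID so the partition is independent of
   input order. Clusters must hold strictly more than 5 decoys to be
   ranked; an `always_include` list can rescue small near-native clusters.

4. **Enrichment.** Locally re-sampled pose sets (externally produced, or
   synthetic stand-ins) are sub-clustered at 3 Å; the ten largest
   sub-clusters each contribute the member closest to their centroid. These
   representatives join the cluster **only** for descriptor aggregation:
   the size feature and the min-LRMSD label count original decoys alone,
   since enrichment poses are not candidate answers (both behaviours are
   configurable).

5. **Descriptors and features.** Any per-model numeric table keyed by model
   ID can be ingested; two built-in exemplars (an inter-chain residue
   contact potential and an atomic contact count) allow runs from PDB files
   alone. Each target's columns are standardised to zero mean and unit
   variance over all of that target's models — decoys plus enrichment,
   population SD (the n vs n−1 choice is immaterial to tree classifiers
   but fixed for reproducibility). Each cluster–descriptor distribution is
   reduced to MIN / Q1 / AVG / Q3 / MAX (AVG denotes the median; quartiles
   use linear interpolation of order statistics, the common default in
   scientific software) and the raw cluster size is appended: `5·D + 1`
   features per cluster, 546 at D = 109. Feature order is descriptor-major,
   stat-minor, SIZE last, so importance indices are reproducible.

6. **Pairwise learning.** For every unordered within-target cluster pair a
   training example concatenates the two feature vectors (1092 features at
   D = 109; slots named `C1_…`/`C2_…`, canonical orientation = lower
   cluster ID first) with label 1 iff the C1 cluster's minimum LRMSD is
   strictly smaller. Exact ties are excluded (label undefined; rare). An
   extremely randomized trees classifier (3000 bootstrapped trees, gini,
   `floor(√p)` features per split — 33 at p = 1092 — depth ≤ 100, 1-sample
   leaves, OOB estimate) is trained on the pooled examples. Evaluation is
   leave-complex-out CV: each fold holds out every example of one target.
   Ranking is a round-robin tournament: each pair is evaluated once in
   canonical orientation (both-order averaging available), a win goes to
   the predicted lower-LRMSD cluster at the 0.5 probability threshold, and
   clusters are ranked by descending wins, ties broken by summed
   probability margin, then cluster ID.

7. **Descriptor screening and feature reduction.**
   - Mann-Whitney U (two-sided; exact null for small tie-free groups,
     tie-corrected normal approximation otherwise) compares near-native
     clusters (≥ 1 acceptable-or-better member) to incorrect ones per
     descriptor, with tiers ***/**/* at p < 1e-4/1e-3/1e-2. The screening
     observation is the per-cluster median of member values (a robust
     centre; per-model pooling available via `unit="model"`).
   - Pearson correlation over all descriptor pairs; |r| > 0.6 counts as a
     strong collinearity partner; zero-variance descriptors are reported
     as 0 and flagged.
   - RFE removes the 10 lowest-importance features per round, where
     importances are averaged over the LCO-CV folds; metrics are recorded
     at every size and the size with the best mean F1 wins (ties prefer
     the smaller set).
   - The transform sweep (factor analysis, PCA, RBF-kernel PCA with the
     scikit-learn default γ = 1/p) walks dimensions from the full feature
     count down to 2 in steps of 10 (a bottom-up grid anchoring is
     available); within each fold the transformer is fitted on training
     records only.

## Synthetic benchmark

The generator produces the conditions the protocol is designed for, with
full ground truth:

- **Structures** are compact ~30-residue Cα pseudo-chains — enough geometry
  for meaningful superposition while keeping tests second-scale. They carry
  no side chains, no physically meaningful energetics and no backbone
  flexibility; passing tests demonstrate the statistical machinery, not
  docking realism.
- **Poses** are rigid ligand placements at well-separated centres around
  the receptor (pairwise centre separation ≈ 35–40 Å at the defaults,
  comfortably above 3× the 10 Å clustering cutoff), perturbed by ~5°
  rotations and 1.2 Å translations so intra-cluster LRMSD stays well inside
  the cutoff. Cluster sizes follow Zipf weights over a floor of 6 models,
  keeping the heavy tail while letting every cluster survive the "> 5"
  size cutoff so planted ground truth stays rankable. One cluster
  (probability `p_near_native`) sits exactly at the reference pose.
- **Descriptors** are linear in the per-model LRMSD plus Gaussian noise
  plus a two-component heavy-tailed outlier mixture (Laplace, fraction 5%,
  scale 1.5 by default) that makes group ranges overlap — the failure mode
  that defeats single-descriptor ranking in practice. The configured ρ is
  the *realized* descriptor–LRMSD Pearson correlation including outliers:
  the clean-noise variance is solved from ρ and the outlier variance
  (infeasible combinations clamp the clean noise to zero with a warning).
  Geometry and descriptors use separate seed streams.
- **Default conditions**: 11 targets (a typical training-set size for this
  problem), 160 decoys per target in 10 clusters, D = 16 descriptors
  cycling through the eight descriptor categories, ρ = 0.9, 5% outliers.
  Problem sizes in the test suite are scaled to these desk-scale values;
  the recovery contract (planted cluster at mean LCO-CV rank ≤ 2, pairwise
  accuracy > 0.8 with 300 trees) is exercised at 8 targets × 10 clusters
  over five seeds.

## Numerical and degenerate-input choices

- Kabsch superposition is SVD-based with a proper-rotation correction;
  collinear inputs warn (the rotation about the line is ill-defined).
  Fewer than 3 matched atoms is an error.
- Zero-variance descriptor columns standardise to all zeros and never
  contribute importance; undefined correlations are reported as 0 with a
  flag; metric ratios with zero denominators are 0 by convention.
- An all-clashed target, an empty residue intersection, a single-class
  training set, a reference without interface contacts, and a
  single-model standardisation each raise informative errors rather than
  degrading silently.
- Duplicate model IDs (descriptor rows or enrichment attachment) are
  errors; missing descriptor rows follow a drop-model policy by default,
  with per-column median imputation as the alternative.

## Known limitations

- The 109-descriptor panel of the original protocol is not re-implemented;
  the pipeline is descriptor-agnostic and reproduces the feature arithmetic
  at any D (546/1092 at D = 109). Real descriptor servers enter via CSV.
- Enrichment pose *generation* (localized docking) is out of scope; the
  pipeline consumes externally produced or synthetic pose sets.
- Win-count ranking ignores intransitivity beyond the tie-break margin;
  probability calibration is out of scope.
- The synthetic benchmark's clusters are far better separated than real
  decoy clusters; real data adds flexible backbones, partial residue
  coverage and descriptor failure modes the generator does not emulate.
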