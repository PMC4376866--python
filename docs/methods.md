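# Methods

## The prediction model

pocketpath predicts compound–target interactions by graph proximity in a
bipartite similarity network rather than by physical docking. The
assumptions are the classic comparative ones:

1. compounds similar to a ligand with a known complex tend to bind
   pockets similar to that complex's binding site;
2. similarity is transitive enough that short, high-similarity paths are
   evidence of interaction, while long or weak paths are not;
3. pocket similarity can be summarized by a scalar comparison Z-score and
   compound similarity by a pair-classifier probability in (0, 1].

Edges carry distances `d = 1/similarity` with similarity clamped to
(1e-6, 1], so a perfect hop costs 1 and anything weaker costs more. A hit
score is the inverse of the summed path distances; since each hop costs at
least 1, scores live in (0, 1] and a three-hop, high-similarity path
scores near 1/3.

### Network construction

* **Drug-likeness filter**: only compounds with wQED ≥ 0.35 (inclusive)
  enter the ligand sub-network. wQED is consumed as an input column; a
  pluggable scorer hook (default: RDKit's weighted QED) covers compounds
  that arrive without it.
* **Edge thresholds** are strict (`>`): site pairs need Z > 2.0, modeled
  target links Z > 1.0, following the "higher than" wording of the
  protocol this package implements.
* **Z normalization**: the protocol calls for a "normalized Z-score" edge
  weight without giving a formula. We use `z / (z + z_ref)` with `z_ref`
  equal to the acceptance threshold of the context (2.0 for site pairs,
  1.0 for model links): bounded in (0, 1], strictly increasing, equal to
  0.5 exactly at the threshold. It is a documented stand-in, exposed in
  config.
* **Condensation**: the redundancy unit is described both as a k-core and
  as a set where "every two members are similar" — a clique. The two
  definitions conflict; both are implemented. The default is a greedy
  maximal-clique cover (largest clique first, ties to the
  lexicographically smallest member tuple), because only it guarantees
  the stated pairwise-similarity property; `kcore` mode (default k = 2,
  connected components of the k-core) is available for fidelity to the
  letter. Clusters are disjoint and singletons are kept, so that path
  semantics stay unambiguous. Cluster–cluster edges take the maximum
  member-pair weight.
* **Model-site integration** applies, in order: quality ≥ 1.1; acceptance
  only if some comparison row has *both* site sequence and structure
  identity > 40%; size ≥ 6 residues; then a greedy redundancy scan
  dropping sites with > 80% residue identity to an already-kept site of
  the same protein. The scan order (descending residue count, then
  ascending id, first-seen wins) is fixed because the protocol names no
  order and determinism is required. Residue identity between two sites
  of one protein is the shared-residue fraction of the smaller site;
  cross-protein redundancy is not assessed because residue coordinates
  are only comparable within a protein.
* **Query integration** keeps, per ligand cluster, the single strongest
  classifier link (probability ≥ 0.5); canonical-structure identity
  short-circuits to similarity exactly 1.0, which is what the benchmark's
  identity-exclusion rule later removes.

### Search and scoring

The bounded Dijkstra is hand-written (a binary-heap search keyed by
(distance, hops, path)) because the contract includes deterministic
tie-breaking: among equal-distance paths, fewer hops win, then the
lexicographically smallest node sequence. The frontier is pruned at
`d_max` (default 10.0 ≈ four to five moderate-similarity hops; the value
is a config knob since the original protocol states a bound exists but
not its size).

Scores are normalized per run before Z-scoring (`minmax` by default,
`none` available). Both Z-scores are invariant under any affine
normalization, so this choice affects only the reported normalized
column — it can never change Gz, Lz, rankings or classifier inputs.
Z-scores use population (ddof = 0) statistics; groups with zero variance
get Z = 0 with a warning. Local statistics are grouped per binding site
by default (`local_scope="protein"` pools a protein's sites). Per-protein
aggregation of site scores uses the maximum (best-pocket convention).

### Classifiers

Both classifiers are scikit-learn random forests (500 trees, sqrt
features per split, class-balanced weights — the protocol names the
family but no hyperparameters; all exposed in config). The pair
classifier consumes a symmetric feature vector: fingerprint Tanimoto
(2048-bit Morgan, radius 2), absolute descriptor deltas (MW, logP,
rotatable bonds, aromatic rings, H-bond donors/acceptors) and min/max
descriptor ratios (MW, TPSA); missing descriptors become a −1 sentinel
with a warning. The meta-classifier consumes (s, Gz, Lz) and, in the
id-aware variant, the compound identity as a CRC32 hash mod 1024
(stable across processes, unlike Python's salted `hash`). Calls use an
inclusive 0.5 threshold. Evaluation is stratified 10-fold CV; headline
precision/recall come from out-of-fold probabilities so no row is scored
by a forest that saw it. Single scores are compared on the same folds
(fold-mean AUC of ranking by that score), which makes the
classifier-versus-single-score comparison apples-to-apples.

## What the synthetic universe emulates

`synthgen` plants exactly the structure the method assumes: compounds in
scaffold families (within-scaffold pair similarity ~Beta(8,2), i.e.
around 0.8; across ~Beta(2,8), around 0.2; Gaussian jitter, sd 0.05),
binding sites in pocket classes (within-class comparison Z ~ N(4,1),
across ~ N(0,1)), and interactions between scaffolds and the classes they
bind. Queries are held-out members of the scaffold families; the planted
truth is scaffold/class co-membership. Compounds are emitted both as
featurized records and as simple decorated-scaffold SMILES so the
chemistry code path is exercised alongside the precomputed-similarity
bypass. Low-drug-likeness decoys (wQED < 0.35) exercise the filter
without touching the truth.

Three heterogeneities make the benchmark behave like real data rather
than a toy:

* **confusable pairs** (`cross_class_noise`, default 0.05): a fraction of
  cross-group pairs drawn from boundary distributions (similarity
  ~Beta(5,5); Z ~ N(2.5,1)) — false similarity calls are borderline, not
  confidently high. Cross-class model-site comparisons draw
  Z ~ N(−1, 1) so the spurious-link rate above the Z > 1 cut matches the
  ~2% rate of the site table at its own Z > 2 cut.
* **per-target model quality**: each modeled site has its own comparison-Z
  level (uniform in [3.0, 6.5], jitter 0.3). Raw scores are then not
  comparable across targets; the local Z exists precisely to fix this.
* **promiscuity**: most pocket classes are bound by 1–2 scaffolds, a
  minority by 4 (`scaffolds_per_class_choices`), and each query carries a
  promiscuity factor (uniform [0.9, 1.12]) scaling its link strengths.
  Promiscuous pockets are where per-target standardization misleads and
  the raw score helps; per-query promiscuity is what the id-aware
  classifier can calibrate away.

Defaults: 8 scaffolds × 6 ligands, 10 classes × 5 sites, 2 modeled
proteins per class (one site each), 48 queries, seed 7. Sample sizes
were chosen so that 10-fold CV estimates are statistically meaningful
(~960 labeled pairs) while the whole pipeline runs in ~30 s on one CPU.
Model-site quality is drawn in [1.2, 2.0] and sizes in 7–12 residues —
the generator emulates post-quality-filter model data; the quality /
identity / size / redundancy stages are exercised by dedicated fixtures
in the test suite.

What passing tests do **not** show: the generator has no real chemistry
beyond valid SMILES (similarities are planted, not computed from
structure), no 3D pocket geometry, no database-scale sparsity, and its
noise is homogeneous. Recovery numbers on it say the machinery is
correct and well-calibrated, not that the method achieves any particular
accuracy on real structural data.

## Numerical and degenerate-input choices

* similarity clamp ε = 1e-6 (finite distances; near-zero similarity is
  effectively unreachable under any practical `d_max`);
* symmetric duplicate similarity rows resolve to the maximum value, the
  same convention as cluster edges; self-loop rows are dropped with a
  warning; non-numeric values are fatal;
* zero-variance Z groups → Z = 0 plus warning; empty prediction sets are
  fatal; unreachable queries are a status, not an error;
* ROC sweeps all distinct score values (parameter-free); AUC is
  trapezoidal; single-class truth yields AUC = NA;
* truth matching is protein-level (predicted site counts toward its
  parent protein), since annotations are drug–protein pairs; higher
  scores are treated as better for s, Gz and Lz alike (orientation is a
  config flag per score);
* all randomness flows from explicit seeds: one `numpy` generator per
  synthetic universe, `random.Random(seed)` for negative sampling,
  `random_state=seed` for forests and folds. Reruns are byte-identical.

## Known limitations

* The greedy clique cover is O(cliques) per round; fine at the scale the
  package targets (thousands of nodes), not tuned for millions.
* The pair classifier's training features are a reconstruction — the
  original's exact training set and feature list are not public.
* The redundancy filter cannot compare sites across proteins without an
  external identity table (hook available via the comparisons input).
* `d_max` and the score normalization of the original protocol are
  unpublished; both are documented config knobs, and conclusions that
  depend on them should be checked under `normalize="none"` and a range
  of bounds.
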