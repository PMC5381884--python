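# Methods

This note documents the models, conventions and numerical choices behind
`pocketscreen`, what the synthetic generators do and do not emulate, and
the known limitations.

## Screening evaluation

### Score tables and repeats

The unit of input is a long-format table of docking scores:
`(ligand_id, pocket_id, repeat, score, class_label, pharmacology,
chemotype)`.  Scores are energy-like — lower is better by default; every
function takes a `lower_is_better` switch for engines with the opposite
convention.  Docking engines that rely on stochastic conformational
sampling are conventionally run several times per ligand (three repeats
here); `best_of_repeats` keeps the best score per (ligand, pocket),
breaking exact ties by the lowest repeat index so results never depend
on row order.  Ligands with an incomplete repeat set are dropped from
per-repeat statistics (so the S.E.M. is computed over screens of the
same library) but retained in best-of-repeats pooling if at least one
repeat exists.

### ROC construction and tie handling

The ROC step curve is built by sweeping the score threshold from best to
worst.  All ligands sharing a score enter together, advancing TP and FP
jointly — a diagonal segment — which makes the curve independent of
input order.  AUC is the trapezoidal area of the (FPR, TPR) polyline and
equals the probability that a random active outranks a random decoy with
ties counted one half (verified against a pairwise-counting oracle and
scikit-learn's `roc_auc_score` in the test suite).

### NSQ_AUC

Early recovery is what matters in prospective screening: only the top
few percent of a ranked library is ever purchased or assayed.  The
square-root AUC re-weights the false-positive axis accordingly:

    SQ_AUC  = ∫ TPR d(√FPR),
    NSQ_AUC = 100 · (SQ_AUC − 1/3) / (1 − 1/3) = 150·SQ_AUC − 50.

The reference terms are analytic: a perfect screen (all actives first)
has unit area under the transformed curve for any class counts, and the
diagonal TPR = FPR integrates to ∫₀¹ u² du = 1/3.  NSQ_AUC therefore
lives in [−50, 100]; negative values mean the pocket discriminates *for*
false positives.

A numerical subtlety: each ROC segment is linear in FPR, and its image
under the square-root substitution is integrated in closed form,

    ∫ y du = (y₀ − s·F₀)(√F₁ − √F₀) + s(F₁^{3/2} − F₀^{3/2})/3,
    s = Δy/ΔF,

rather than by a vertex trapezoid.  For purely horizontal/vertical
segments (untied data) the two coincide, but for diagonal tied-score
segments the trapezoid would replace the curved image by its chord — an
all-tied screen would score NSQ_AUC = 25 instead of the exact 0.  The
closed form keeps the anchors (100 / 0 / −50) exact for any class
counts, which the acceptance suite asserts.

Because NSQ_AUC depends on scores only through the ranking, it is
invariant under any strictly monotone transform of the scores (property
tested).

### Enrichment factors

EF_x = (TP_x/N_x)/(TP/N) with N_x = round(x·N/100), minimum 1.  The
discretization of N_x is not standardized; rounding (rather than
flooring) was chosen and is applied consistently.  Ties at the cut are
broken by ligand id.  Chemotype-resolved EF uses only the true positives
of the requested chemotype in TP and TP_x while N and N_x count the
whole screened database; a chemotype with no true positives yields a
missing value with a warning rather than a zero, since "no enrichment"
and "nothing to enrich" are different findings.

### Pocket comparison statistics

Per-repeat NSQ_AUC values (no best-of pooling — each repeat is its own
screen) give mean ± S.E.M. with S.E.M. = s/√R, s the sample standard
deviation.  For more than two pockets, a one-way ANOVA is followed by
Tukey's HSD (scipy implementations); for exactly two, an unpaired
t-test with Welch's correction.  Significance stars follow the
conventional ladder: * P ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001, **** ≤ 0.0001.
With all-zero variance and equal means the F statistic is reported as
undefined (NaN) instead of raising.  Each pairwise row also records
which pocket had the higher mean, since a significant difference is only
useful with its direction.

## Library preparation

Public bioactivity databases report many measurements on racemic
samples; libraries derived from them store one (possibly wrong)
enantiomer.  The preparation pipeline mirrors the racemic-screening
convention:

- **Constitution key**: canonical SMILES after removing all stereo
  descriptors (RDKit).  This is the identity used for deduplication.
- **Racemic flag**: set iff the molecule has ≥ 1 (potential, i.e.
  assigned or unassigned) tetrahedral stereocenter.
- **Enantiomer multiplicity**: 2^n labels, capped at 2¹⁰ with a warning;
  enumeration is label-only — no 3D enantiomer structures are generated,
  since docking them is the engine's job, not this package's.
- **Deduplication**: records sharing a constitution merge into one (the
  lexicographically smallest id survives), with an old→new id mapping
  returned for joining score tables.  Conflicting active/decoy labels on
  merged records are an error naming the ids, not a silent choice.

### Chemotype clustering

Pairwise dissimilarity is 1 − Tanimoto over Morgan fingerprints
(radius 2, 2048 bits) — a standard chemotype-practice choice; the
fingerprint is a config knob, not a claim.  Complete linkage builds the
tree.  The cut: the number of clusters of size ≥ 2 rises and falls as
the cut height grows, so the tree is scanned from the top and the first
(lowest) height in the top-most band with exactly `max_clusters` such
clusters is used; fully formed families are thereby preferred over
transient pairings lower in the tree.  If no height qualifies, a flat
`max_clusters` cut is used.  The `max_clusters` largest clusters are
named A–D in decreasing size (ties by smallest member id); everything
else — singletons at the chosen cut — is "other".  Cluster centers are
medoids (minimum summed dissimilarity, ties by id).  Cut heights are
per-library quantities and are not comparable across libraries.  With
fewer ligands than `max_clusters` every ligand is its own named cluster;
an all-identical library is a single cluster A.

## Structure comparison

- **Loading** (Biopython): heavy atoms of amino-acid residues in the
  selected chains plus the named ligand; waters and all other
  heteroatoms stripped; author residue numbering and insertion codes
  preserved; alternate locations resolve to the highest-occupancy
  conformer.  Ligand connectivity comes from a supplied bond list or
  from a covalent-radius distance rule (sum of radii + 0.45 Å) —
  adequate for the miniature complexes this package generates; supply
  explicit bonds for exotic chemistry.
- **Pocket**: residues with any heavy atom within 5 Å of any ligand
  heavy atom, matched across complexes by residue number + insertion
  code, and unioned over the group so a contact in any one member counts.
  The docking-box selection uses the same rule at 4 Å.
- **Superposition**: least-squares rigid fit (SVD Kabsch with reflection
  guard) on backbone N/CA/C/O of shared pocket-union residues, applied
  to all atoms including the ligand.  Backbone-only fitting keeps
  side-chain variation out of the reference frame, preserving the
  meaning of the subsequent ligand RMSD as "where the ligand sits in the
  pocket".
- **Ligand RMSD**: computed in the group frame with *no further
  fitting*.  The atom correspondence minimizes RMSD over all
  element-labeled graph isomorphisms (networkx), so topologically
  equivalent atoms — a flipped carboxylate, a rotated phenyl — cannot
  inflate the value; exhaustive up to 10⁴ mappings, then a name-matching
  fallback with a warning.  Verified against a brute-force automorphism
  oracle for small ligands.
- **Pocket RMSD**: heavy atoms matched by residue number + atom name;
  atoms present in only one complex (unmodeled side-chains) are skipped
  so truncated residues still contribute their shared atoms.

### Interaction fingerprints

Seven boolean classes per pocket residue, from the residue's
perspective: hydrophobic, H-bond donor, H-bond acceptor, weak (C–H)
donor, weak acceptor, ionic, aromatic.  Default geometric rules (all
configurable via `IfpCutoffs`):

| class        | rule                                                        |
|--------------|-------------------------------------------------------------|
| hydrophobic  | apolar C/S pair ≤ 4.5 Å                                     |
| H-bond       | donor–acceptor heavy atoms ≤ 3.5 Å, antecedent angle ≥ 90°  |
| weak H-bond  | C–H donor to acceptor ≤ 3.8 Å                               |
| ionic        | opposite formal charges ≤ 4.0 Å                             |
| aromatic     | ring-centroid distance ≤ 5.0 Å                              |

Structures carry no hydrogens, so protonation follows pH-7 rules:
Asp/Glu anionic, Lys/Arg cationic, His neutral; ligand amine nitrogens
(carbon-only neighbors, ≤ 3 heavy neighbors, non-ring) cationic;
carboxylate oxygens anionic; ligand aromatic rings detected as planar
5/6-rings of C/N/O/S (0.15 Å tolerance).  These are likelihood flags for
comparing complexes, not assertions of physical presence — which is also
why every cutoff is exposed.  Residues with no atom inside the largest
cutoff get an all-false row, keeping group heatmaps aligned.

### Model quality

Per-residue RSCC and B-factor tables (computed upstream by
crystallographic software) are joined to the pocket: RSCC < 0.8 flags a
poor density fit; a poor fit is corroborated when the B-factor also
exceeds the pocket median.  Asp, Glu, Met, Tyr and disulfide cysteines
(S–S ≤ 2.5 Å when a structure is supplied) are radiation-damage-prone,
so low RSCC there is annotated as inconclusive rather than evidence
against the model; free cysteines are not flagged.

## Synthetic data

The generators define the study conditions for all tests and examples.

- **Scores**: decoys ~ N(μ₀, σ²) with μ₀ = −20, σ = 1 (arbitrary
  energy-like units); actives shifted by `effect_size` toward better
  scores plus an optional per-chemotype shift; each repeat adds
  N(0, 0.3²).  Defaults follow the screening-library conventions the
  analysis assumes: 50 actives, 39 property-matched decoys per active
  (1950 decoys), 3 repeats.  The Gaussian family is the simplest model
  that reproduces the phenomena of interest (graded overall enrichment,
  chemotype-selective early recovery); it does not emulate score–ligand
  correlations, heavy tails or engine failure modes, so passing tests
  demonstrate the correctness of the *analysis*, not the behavior of any
  docking engine on real libraries.
- **Libraries**: molecules from four well-separated scaffold families
  (naphthalene carboxamides, pyridine sulfonamides, cyclohexanecarboxylate
  esters, 3-substituted indoles; default sizes 4/3/3/2) with homologous
  substituents, a configurable fraction bearing one unassigned
  stereocenter, and injected enantiomer-double pairs.  Family separation
  (max within-family dissimilarity < min between-family) is itself
  asserted in the tests, so cluster-recovery results are interpretable.
  Decoy molecules are not generated — physical-property matching is a
  non-goal; the decoy *convention* lives in the score tables.
- **Toy complexes**: 1–15 residues placed around a small probe ligand
  (benzene ring, benzylic aminium arm, phenolic hydroxyl) with each
  intended interaction realized at an exact target distance (verified to
  0.01 Å); ideal residue geometries, not rotamer libraries — fixtures
  need exact distances, not realism.  Unintended inter-entity contacts
  under 1.5 Å abort construction.  Complexes serialize to valid PDB and
  survive a load round-trip to 10⁻³ Å (PDB coordinate precision).

All generators are deterministic given their seed (byte-for-byte,
asserted in tests).

## Problem sizes used in the test and acceptance runs

Screens use the default 2000-ligand library (50 actives × 40).  The
parameter-recovery study simulates three pockets at effect sizes 0.5σ,
1.0σ and 2.0σ, three repeats each, over 20 seeds, and requires the mean
NSQ_AUC ordering to match the effect-size ordering in ≥ 19/20 seeds with
the extreme pair Tukey-flagged at P ≤ 0.05.  Oracle-equivalence checks
run 200 random instances each.  These sizes make the whole suite run in
well under a minute while leaving the statistical assertions sharp.

## Known limitations

- Docking, rescoring and pose generation are out of scope by design;
  score tables are consumed, never produced, and the interactive-scoring
  and RSCC computations of upstream engines are likewise inputs only.
- Ligand chemistry perception from bare PDB coordinates (bond inference,
  protonation, aromaticity) is rule-based and intentionally simple;
  supply explicit bonds or adjust `IfpCutoffs` for unusual ligands.
- Chemotype clusters depend on the fingerprint and linkage choices;
  cross-library comparisons of cut heights are meaningless and
  deliberately unsupported.
- The enantiomer multiplicity ignores meso compounds and double-bond
  stereochemistry; it counts tetrahedral-center labels only.
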