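# Methods

## The problem

`kinopcm` models kinase-inhibitor interaction panels proteochemometrically:
the measured interaction strength pK_d(k, l) = −log10 K_d of kinase *k* and
inhibitor *l* is regressed jointly on numeric descriptors of both partners.
Unlike single-target QSAR, one model covers the whole panel and can
extrapolate to new compounds, new kinases, and new pairs. The package
emulates the structure of a kinome-scale primary screen: a few hundred
kinase catalytic domains from seven groups (AGC, CAMK, CK1, CMGC, STE, TK,
TKL), a few dozen inhibitors, roughly a quarter of all pairs active, pK_d
measured in [5, 10.62], and all pairs below the screen's detection limit
(pK_d = 5) recorded at the floor value pK_d = 4.

## Protein description schemes

Six schemes map an amino-acid sequence to a fixed-width numeric vector.

* **aligned_z** — columns of a multiple sequence alignment encoded by the
  five Sandberg z-scales. Columns with gaps in more than 50% of sequences
  are removed first (strictly "more than": exactly 50% is kept). Gaps encode
  as the zero vector; since z-scales are centered over the alphabet, zero
  reads as "average residue". Width = positions x 5.
* **acc** — auto-/cross-covariances of z-scales: term (z_a, z_b, lag) =
  Σ_i V_{a,i} V_{b,i+lag} / (N − lag) over lags 1..L, computed on
  per-sequence mean-centered z-values. Centering makes homopolymers encode
  exactly zero and removes composition offsets, so ACC captures sequence
  *patterns*. Width = L x 25; L defaults to 50 (larger lags add noise from
  indel misregistration faster than they add signal; short lags lose
  longer-range structure).
* **macc** — MACC1: for each (z_a, z_b, lag) the four sign-resolved extreme
  products: largest positive product among (+,+) and among (−,−) position
  pairs, most negative among (+,−) and (−,+). "Maximum" is read as maximum
  magnitude within each sign quadrant, reported with its natural sign; a
  quadrant with no qualifying pair contributes exactly 0, and each term is
  traceable to the residue pair that attained it. Width = 4 x L x 25.
* **ctd** — composition/transition/distribution over 7 attribute partitions
  of the alphabet into 3 classes (hydrophobicity, van der Waals volume,
  polarity, polarizability, charge, secondary structure, solvent
  accessibility; the standard groupings are embedded in
  `kinopcm.tables`). 21 compositions + 21 transitions (unordered class
  pairs, normalized by N−1) + 105 distribution values (first / 25% / 50% /
  75% / last occurrence positions divided by N; the quantile index is
  ⌈q·n_c⌉ and an absent class contributes five zeros). Width 147.
* **so_paa** — sequence-order coupling numbers τ_d = Σ_i d(s_i, s_{i+d})²
  for d = 1..30 with two residue-distance matrices (60 values),
  quasi-sequence-order descriptors X_a = f_a/(1 + w Στ) and
  X_{20+d} = w τ_d/(1 + w Στ) with w = 0.1 (100 values), and type-1
  pseudo-amino-acid descriptors built the same way from correlation factors
  averaging squared differences of standardized hydrophobicity,
  hydrophilicity and side-chain mass, with weight w = 0.05 (50 values).
  Width 210.
* **aac_dc** — amino-acid (20) and dipeptide (400) composition, each group
  summing to 1. Width 420.

Distance matrices: the Grantham matrix is computed from Grantham's published
composition/polarity/volume values and constants (α = 1.833, β = 0.1018,
γ = 0.000399, scale 50.723); tests pin it to canonical pair values (S-R 110,
L-I 5, C-W 215). The matrix used in the Schneider-Wrede role is a synthetic
reconstruction — Euclidean distance over the three standardized PAA property
scales, max-normalized — because the original table is not bundled; it is
symmetric with zero diagonal and clearly labelled synthetic in the code.
Swapping in the original values changes only the so_paa block.

Non-standard residues (B, J, O, U, X, Z) are rejected with an error naming
the sequence and position; descriptor orderings are frozen so blocks are
byte-stable across runs.

## Preprocessing and cross-terms

All descriptors are mean-centered and scaled to unit variance
(zero-variance columns are dropped); each block is then weighted by
1/√(width) so every block's descriptor variances sum to 1 and wide protein
blocks cannot drown the ligand block. The response is mean-centered.

A purely linear model in the concatenated blocks is additive in ligand and
kinase and cannot express selectivity. Cross-terms restore it: ligand
descriptors are compressed to all n−1 principal components and kinase
descriptors to the components explaining 95% of variance; every ligand-PC x
kinase-PC product becomes one cross column, Pareto-scaled (divided by √sd —
the usual chemometric compromise between no scaling and autoscaling, which
would blow up near-constant products) and multiplied by a block weight. The
weight is swept over 0..2 in steps of 0.1 inside the inner CV, starting at 0
(plain linear PLS).

PCA is exposed as a NIPALS iteration (tolerance 1e-9 on the score change,
at most 500 iterations, sign fixed by making the largest-magnitude loading
positive); an exact SVD solver with the identical output convention is used
on wide blocks and is tested equal to the iteration.

All states — scaling, PCA, Pareto sds, response mean — are fitted on the
training entities of a fold and applied unchanged to held-out rows. PCs are
recomputed inside every training set (per-fold, the leakage-safe reading;
computing them once globally would let held-out kinases shape the basis).

## Correlation methods

* **PLS** — NIPALS PLS1. The single-response path uses the
  covariance-deflating form of the recursion (only X'y is deflated), which
  is algebraically identical to classic NIPALS but avoids rewriting X per
  component; predictions through the coefficient vector
  B = W(P'W)⁻¹Q' and through the score path agree to 1e-8, and the model is
  tested against an independent PLS implementation to 1e-6. Component count
  (1..15) is chosen by inner CV; with cross-terms the block weight is chosen
  jointly.
* **PLS-DA** — multi-response NIPALS PLS on 0/1 class indicators; reports
  cross-validated Q² per class and overall.
* **SVR** — epsilon-SVR with RBF kernel; the quadratic program is delegated
  to libsvm (via scikit-learn), with kernels precomputed from pairwise
  squared distances so the (γ, C) grid reuses them. Default grids are
  log2-spaced, γ ∈ 2^{−6..0}, C ∈ 2^{−1..9}; ε = 0.1 x sd(y).
* **k-NN** — 1/distance-weighted mean of the k nearest training pairs in
  the scaled descriptor space; k ∈ {1,3,5,7,9} and a kinase-block weight
  ∈ {0.25, 0.5, 1, 2, 4} (applied as weight² on the kinase part of the
  squared distance) are chosen by inner CV. Exact matches return the mean
  response of all zero-distance neighbours.
* **Model tree** — an M5-style tree: splits maximize SD reduction, each
  node carries a ridge-stabilized linear model over the attributes tested in
  its subtree, pruning compares the node model's complexity-penalized error
  (factor (n+ν)/(n−ν)) with its subtree, and predictions are smoothed along
  the path to the root with constant 15. The tree runs on a PCA-compressed
  design (95% variance) to keep split search tractable on wide blocks. A
  constant response yields a single leaf, not an error.

Ties in any grid go to the simplest model: grids are ordered simple to
complex and the first maximum wins.

## Validation protocol

Q² = 1 − PRESS/SS_tot with the mean taken over the evaluated set (a
mean-predicting model scores 0; worse models go negative).

Double CV splits the panel into 25 parts — over pairs (→ P²) or over whole
kinases balanced to ±1 (→ P²_kin). Five parts at a time form the outer
verification set; the other 20 parts feed a 5-fold inner loop (train 16/25,
validate 4/25) that selects hyperparameters per outer fold; the model is
refit on the 20/25 and scored on the untouched 5/25. Every row is predicted
exactly once; outer purity (no row, and in kinase-wise mode no kinase, on
both sides of a fold) is asserted by id audit on every run.

ROC analysis thresholds the observed pK_d at 5 (active vs floored), scores
by predicted pK_d, and reports the trapezoid AUC (tested equal to the
Mann-Whitney rank statistic to 1e-10) plus specificity at fixed
sensitivities. The error histogram reports cumulative fractions of
|error| ≤ {0.25, 0.5, 1, 2} pK_d units. The dataset-size sweep trains on a
fraction of pairs or kinases (hyperparameters from 5-fold CV inside the
training subset), evaluates on the remainder and averages over repeated
random splits.

## The synthetic generator

Real panel data of this kind is proprietary/external, so the generator is a
first-class module producing everything downstream of the wet lab:

* **Sequences.** Groups are assigned round-robin and shuffled (balanced to
  ±1; with as many kinases as groups, exactly one each). Each group has a
  5-residue conserved motif of the basic-hydrophobic-P-hydrophobic-basic
  flavour seen in activation loops, at a group-specific relative position
  (±2 jitter), and a group consensus sequence anchored at the motif;
  members copy consensus positions with probability 1 − mutation_rate
  (default 0.4) and otherwise draw from a mildly group-tilted background
  composition. Divergence therefore pervades the whole domain, as between
  real kinase families — this is what makes both aligned and
  alignment-free z-scale descriptions group-separable, while CTD (which
  sees mostly composition) separates poorly, reproducing the qualitative
  ordering of the real comparison. Domain lengths are mostly 240-300 with
  tails to 194 and 606. The emitted MSA anchors every sequence at its motif
  start; it is a construction, not an inferred alignment.
* **Ligand table.** A 3-dimensional nonnegative latent vector per compound
  (gamma-distributed: pharmacophore features are present to a varying,
  never negative degree), embedded with noise in ~20% of the 150 columns;
  the rest are noise, and three trailing columns are near-duplicates so
  correlation pruning has work to do.
* **Activity.** pK_d(k,l) = μ + a_k + b_l + u_k' M v_l + ε with ε ~
  N(0, 0.3). Kinase latents u_k are group latents times ~10-25%
  multiplicative individual variation; M is nonnegative and sparse. The
  bilinear term is scaled to sd = interaction_weight (default 2.0), so
  selectivity dominates the additive effects (a: sd ≈ 0.54, b: sd = 0.5) —
  the regime the method is designed for. Because u, v and M are
  nonnegative and right-skewed, the latent surface has a long right tail
  and a narrow sub-threshold body, like real affinity data where potent
  binders are rare; a symmetric Gaussian surface would put so much latent
  spread below the detection limit that no linear model could score well on
  the censored matrix, which would misrepresent the problem. μ is set from
  the empirical quantile of the surface so the active fraction hits the
  24.8% target exactly up to matrix discreteness. Censoring is applied
  after noise (a detection-limited assay); floored cells carry exactly 4.0
  and the inactive mask; actives are clipped to [5, 10.62].

What the generator does **not** emulate: realistic phylogeny within and
between groups (a flat consensus-plus-mutations model, no indel history in
the MSA beyond length padding), assay heteroscedasticity, correlated
measurement error, compound series structure, or mutated kinase variants.
Passing the recovery tests therefore shows the pipeline recovers planted
bilinear structure from censored data under realistic size/censoring
conditions — not that it would achieve the same numbers on a real panel.

## Problem sizes and defaults used in tests and scripts

The full-scale panel (317 x 38) is generated and checked for its marginal
properties in seconds. Model-comparison protocols (double CV, size sweep,
ROC) run at 80 kinases x 20 inhibitors — 1,600 pairs — where one double-CV
run takes seconds (PLS, k-NN) to half a minute (SVR, model tree) and the
whole acceptance computation a few minutes; the analysis scripts expose
`--n-kinases/--n-inhibitors` to scale up. At this scale cross-term PLS and
SVR typically reach P² ≈ 0.85-0.93, P²_kin ≈ 0.78-0.90, AUC ≥ 0.96, and
plain PLS without cross-terms trails by 0.2-0.3 in P² — the qualitative
pattern the method predicts (new pairs easier than new kinases; selectivity
not expressible additively).

## Known limitations and open choices

* The MACC1 quadrant convention follows one reading of "positive and
  negative values considered separately"; alternatives (e.g. max by signed
  value rather than magnitude) would change the (+,−)/(−,+) terms.
* Correlation pruning drops, from the worst-correlated pair, the member
  with the larger maximum r² against the *other* remaining descriptors
  (partner excluded — including it would tie every comparison); iterated to
  convergence. Single-pass variants can keep slightly different sets.
* Q²/P² use the evaluated-set mean; a training-mean convention would shift
  values slightly on skewed splits.
* Hyperparameters are re-selected per outer fold (the stricter protocol);
  selecting once globally would be cheaper and slightly optimistic.
* The SVR precomputed-kernel path holds an n x n distance matrix; beyond
  ~5,000 pairs per fold, memory forces the direct feature-space path or
  sub-sampling.
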