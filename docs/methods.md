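# Methods

## The prediction problem

Catalytic residues — the handful of amino acids that perform an
enzyme's chemistry — are rare (on the order of 1% of residues) and sit
in a characteristic context: they are strongly conserved, and they lie
toward the interior of the folded chain, near the bottom of the active
site. The predictor exploits exactly these two signals. All other
per-residue features the package computes (contact-graph centralities,
relative solvent accessibility) are retained for analysis because they
are standard in this literature, but they are strongly mutually
correlated with burial and add little on top of the distance to the
center of mass; the deployed classifier deliberately uses only
conservation (as a hard prefilter) plus GCM distance and residue type.

## Chain model

`structure.parse_pdb_chain` reads fixed-column ATOM records of one
chain, first model only. Only heavy atoms are kept (deuterium counts as
hydrogen); waters and ligands are dropped; non-standard residues with
an unambiguous parent (MSE→MET, SEP→SER, …) are mapped, others skipped
with a warning. Of several alternate locations for one atom the highest
occupancy wins, ties going to the first seen. Atoms carry standard
atomic weights by element; an unrecognized element falls back to the
carbon mass with a warning. Residues lacking a Cα stay in the chain —
they contribute to the center of mass, the contact graph and the SASA
environment — but are excluded from the feature table and from
classification, because the geometric feature is defined on the Cα.

## Features

**Conservation.** Per-column relative entropy
RE = Σₐ pₐ·log₂(pₐ/qₐ), base 2, no pseudocounts and no sequence
weighting; gaps and non-standard letters are excluded from the counts.
The default background q is uniform (1/20 per type), so RE ranges over
[0, log₂ 20 ≈ 4.32] and the protocol thresholds (3.5, 3.8) sit in the
top of that range; the Robinson–Robinson composition is selectable, and
the choice is recorded in the config serialization. Alignment hits are
filtered before scoring: each hit must cover ≥ 75% of the query's
non-gap positions, and a greedy scan in input order (search tools
return hits in relevance order) drops any hit more than 95% identical
to an already-retained hit, identity being matches over the shorter
ungapped length on mutually aligned columns. The query is always
retained; if every hit is filtered away the profile is computed from
the query alone with a warning.

**Geometry.** GCM = Σ Mᵢ·Rᵢ / Σ Mᵢ over all heavy atoms of the chain;
the feature is |Cα − GCM| in Å. Both are exactly equivariant/invariant
under rigid motions, which the tests check to 1e-9.

**Contact graph.** Edge (i, j) iff the minimum heavy-atom distance
between residues i and j is ≤ 4.5 Å (configurable); edges have unit
length. This is the standard distance-cutoff surrogate for
contact-analysis programs, whose exact contact logic is not reproduced;
an adapter ingests an externally produced two-column residue-pair
table instead. Closeness is computed per connected component
((n_reachable − 1)/Σd; an isolated node scores 0 — the convention is a
package choice, the common one for disconnected graphs). Betweenness is
left unnormalized and PageRank uses damping 0.85, iterated to an L1
change below 1e-12; scale does not matter because each centrality is
converted to an ascending rank percentile in (0, 1] (mean rank for
ties, maximum exactly 1) before use. networkx provides the centrality
implementations; the test suite verifies them against independent
brute-force BFS, path-enumeration and power-iteration oracles on random
graphs.

**Solvent accessibility.** An internal Shrake–Rupley implementation:
each atom's sphere (van der Waals radius + 1.4 Å probe) is sampled at
960 golden-spiral quadrature points (deterministic; quadrature error
≈ 0.1% on an isolated sphere, well under the 1–2% the analyses need),
points inside any neighbor's expanded sphere are occluded, and per-atom
areas are summed per residue. RSA% divides by the theoretical
extended-state Gly-X-Gly reference areas of Tien et al. (2013), shipped
in code and named in the config output. An adapter reads externally
produced naccess-format `.rsa` tables. RSA is an analysis feature only;
it does not enter the final predictor.

## Classifier and training protocol

Architecture: 21 inputs (20-way residue-type indicator + z-scored GCM
distance) → 10 sigmoid hidden units → 1 sigmoid output. The distance is
z-scored with the balanced training sample's mean and standard
deviation, stored in the model, because raw ångström values would dwarf
the 0/1 indicators.

Training is classic online back propagation with squared-error loss:
weights initialized uniform(−0.5, 0.5) from the seeded generator,
learning rate 0.05, patterns shuffled every epoch under the same seed,
500 epochs by default. Training rows are first prefiltered at
conservation 3.5, then balanced to 1:1 by sampling negatives once,
without replacement (if the pool is short all negatives are used, with
a warning). After each epoch the network is applied to the verification
set — held-out structures, never rows of training structures — and the
weights finally returned are those of the epoch with the highest
verification MCC (ties: earliest epoch). The verification MCC is the
deployed metric: the conservation prefilter is applied to the calls and
prefiltered residues count as negative calls, while the MCC denominator
remains the full verification set. (Selecting on the unfiltered MCC
instead rewards epochs that call almost nothing positive, since every
positive call on a non-conserved residue is a false positive there;
with prefiltered selection the pooled synthetic-recovery sensitivity is
stable across seeds.) Prediction applies the final prefilter (default
3.8) and calls a survivor catalytic when the network output is ≥ 0.5.

Defaults in `TrainingConfig`: learning rate 0.05 (dimensionless),
500 epochs, hidden width 10, sampling ratio 1, training prefilter 3.5
bits, decision threshold 0.5. Only the hidden width, the back
propagation family, the 1:1 ratio and the two conservation thresholds
are protocol-fixed; the rest are ordinary neural-network defaults
chosen once for stable convergence on balanced samples of tens to
hundreds of patterns.

## Metrics and cross-validation

MCC uses the zero-marginal convention (any zero marginal → 0), so the
threshold scan is total. Sensitivity, precision and F1 are reported on
the percent scale. In every metric, residues removed by the prefilter
are negative calls over the full input universe — necessary for
whole-input sensitivities to be meaningful. `cross_validate` assigns
sequence-identity *clusters* (not structures) to k folds differing by
at most one cluster, so homologous structures never straddle a
train/test boundary; within each training split a fraction of clusters
(default 20%) is reserved as the verification set for epoch selection.
The ECDF separation analysis normalizes its relative-difference curve
by the maximum absolute gap between the two class ECDFs; this
convention is recorded in the returned metadata because other
normalizations exist.

## Threshold recalibration

`scan_entropy_threshold` evaluates each threshold t in {lo, lo+step, …,
hi} (default 2.5–4.0 in 0.1 steps, 16 values): prefilter at t, predict
on survivors, count removed functional residues as false negatives,
compute MCC over all residues, and return the argmax (ties to the
larger threshold, preferring the stronger filter). This is the
operation one reruns whenever the reference sequence database behind
the alignments changes, since database growth inflates the number of
residues reaching a given conservation level.

## Synthetic fixtures: what they emulate and what they don't

`fixtures` generates toy chains as self-avoiding-ish random walks with
exact 3.8 Å Cα steps confined to a sphere of radius 3.2·n^⅓ Å
(protein-like packing density), 4–8 heavy pseudo-atoms of realistic
masses per residue, and 10% planted catalytic residues — placed in the
inner quartile of GCM distances and given catalytic-propensity types
(H, D, E, K, R, C, S, T, N, Y). The remaining core positions are
hydrophobic, and 80% of them are conservation decoys. Alignments are
gapless, depth 30: planted-conserved columns are invariant (scoring
exactly log₂ 20), all other columns mutate per row with probability 0.5
to uniform letters (scoring ≈ 1.3 bits, far below the prefilter). The
fixtures therefore reproduce the joint signal the method assumes —
conservation × centrality × residue type — and the qualitative
correlation sign pattern (function positive with conservation and
closeness, negative with GCM distance), at a base rate of 10% rather
than the ~1% of real annotation universes.

They do **not** emulate: real backbone geometry or side-chain
chemistry, gapped alignments and phylogenetic correlation between
sequences, annotation noise, partially conserved catalytic sites, or
surface catalytic residues. Passing the recovery tests shows the
pipeline is implemented correctly and recovers a planted signal of the
assumed form; it does not certify real-data accuracy, which depends on
curated annotations and a designated reference database.

The recovery experiment (10 structures × 50 residues per seed, 6/2/2
train/verification/test split by structure, 5 seeds, pooled counts)
is sized to run in about half a minute on one CPU while leaving ≥ 50
functional residues in the pooled held-out evaluation.

## Numerical choices and degenerate inputs

- PageRank tolerance 1e-12 (L1), oracle agreement required to 1e-8.
- Percentile ties: mean competition rank (deterministic, symmetric).
- SASA: 960 points default; the refined-quadrature cross-check uses 10×
  points and 2% tolerance on overlapping atoms.
- Relative entropy: 0·log 0 = 0; the background is floored at 1e-12
  only to guard pathological custom backgrounds; all-gap columns score
  NaN with a warning.
- Prefilter boundary: scores exactly equal to the threshold are kept
  ("less than" is discarded).
- Balanced sampling with too few negatives keeps all negatives and
  warns rather than failing.
- A verification set with a single class raises (MCC undefined).
- Model files are versioned plain text with 17-significant-digit
  weights, so save/load round-trips bit-exactly.

## Known limitations

- The contact criterion is a plain distance cutoff; programs that
  classify contacts by interface chemistry will produce somewhat
  different graphs (the adapter accepts their tables).
- The conservation scale is tied to the background choice; thresholds
  of 3.5/3.8 bits assume the near-uniform base-2 convention and must be
  re-scanned for other backgrounds or databases.
- Chains shorter than ~2 residues cannot support centralities; a
  single-residue graph raises rather than inventing a value.
- The predictor is trained per corpus: the shipped code contains no
  pre-trained weights, and models should be retrained when the
  annotation source or alignment pipeline changes.
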