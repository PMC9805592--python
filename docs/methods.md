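# Methods

## Interface graphs

A two-chain complex is reduced to a residue-level graph of its interface.
Contact residues — those with at least one heavy atom within the
*interface cutoff* (default 8.5 Å) of any heavy atom of the other chain —
form the node set, ordered deterministically by (chain id, residue
number, insertion code). Two edge sets live on this one node set:

- **external edges** between cross-chain node pairs whose minimal
  heavy-atom distance is within the interface cutoff;
- **internal edges** between same-chain node pairs within the *internal
  cutoff* (default 3.0 Å), i.e. residues in close intra-chain packing
  contact.

All cutoff comparisons are inclusive (`≤`). Hydrogens, waters and HETATM
records are removed at parse time, so every distance in the package is a
heavy-atom distance by construction. Alternate locations are resolved to
the highest-occupancy conformer (ties: file order). Because nodes and
edges depend only on inter-atomic distances, the graph is exactly
invariant under rigid transforms of the input coordinates; this is the
property that lets a graph network skip the rotational data augmentation
a grid CNN would need.

An empty interface is reported as a distinct error, never as an empty
graph. A graph with no internal edges is legal; at least one external
edge always exists when construction succeeds.

## Features

Node feature blocks, in fixed column order (widths in parentheses):
residue type one-hot over the 20 canonical amino acids in alphabetical
3-letter order (20); formal side-chain charge at pH 7 — ARG/LYS +1,
ASP/GLU −1, HIS +0.1 as a partial-protonation approximation, others 0
(1); polarity class one-hot over {apolar, polar, positive, negative}
(4); buried surface area (1). With sequence profiles enabled, the 20
PSSM substitution scores (20), the positional information content (1)
and a conservation score (1) follow, for 48 columns in total; a
PSSM-only configuration has 20. Noncanonical residues get all-zero
one-hot blocks and a warning. The conservation score is defined here as
the PSSM score of the residue's own amino-acid column (the diagonal
read-out), a documented convention.

**BSA.** Buried surface area is the residue's solvent-accessible surface
in its isolated chain minus its SASA in the complex, clamped at 0.
SASA is Shrake–Rupley-style point sampling (biotite), probe 1.4 Å, 100
points per atom, element-based (Bondi) radii. Point sampling against a
space-fixed grid is slightly orientation-dependent, so coordinates are
first rotated into a molecule-fixed principal-axis frame whose axis
signs are fixed by odd moments of the coordinate distribution; these
functionals are rotation-invariant, which makes the computed BSA
invariant under rigid transforms to float precision rather than only to
sampling tolerance.

**Edge feature.** The minimal inter-residue heavy-atom distance x (Å)
is mapped to an interaction strength

    e(x) = tanh(−x/2 + 2) + 1,

a strictly decreasing, bounded transform with e(0) = tanh(2)+1 ≈ 1.96,
e(4) = 1 and e → 0 at long range. The same transform is applied to
internal and external edges.

**Scaling.** Features are stored raw. Min–max scaling of node-feature
columns on the training set is a training-config flag, on by default:
the BSA and PSSM columns span tens of units while the one-hot blocks are
binary, and a shared scale keeps Adam at learning rate 0.001 effective
across blocks.

## Docking-quality targets

Against a reference (bound) structure the package computes, per model:

- **fnat** — the fraction of the reference's cross-chain residue
  contacts (minimal heavy-atom distance ≤ 5 Å) reproduced by the model;
  bounded in [0, 1], insensitive to how badly a wrong model is wrong,
  which makes it a better regression target than an RMSD.
- **iRMSD** — backbone (N, CA, C, O) RMSD over reference-defined
  interface residues (cross-chain heavy-atom distance ≤ 10 Å) after
  least-squares superposition of those atoms (Kabsch via SVD).
- **lRMSD** — backbone RMSD of the ligand chain after superposing on the
  receptor backbone only; the receptor is the longer chain (ties: first
  chain id).
- **CAPRI class** — high / medium / acceptable / incorrect from the
  standard fnat + RMSD threshold table; improving any metric never
  demotes the class.
- **binary label** — fnat ≥ 0.3 (inclusive), the acceptable-quality
  binarization used for ranking metrics.

The 5 and 10 Å cutoffs and the class thresholds follow the CAPRI
assessment convention; they are conventions of the field, not values
re-derived here. Residue correspondence between model and reference is
by (chain, number, insertion code); residues missing from the model are
dropped from RMSD atom sets with a warning.

## GINet

The network splits the graph into its internal and external sub-graphs
and processes them in two parallel branches with separate parameters.
Each branch applies two rounds of edge-weighted message passing

    h'_i = ReLU( W_self h_i + b + Σ_{j∈N(i)} e_ij W_nbr h_j ),

with the fixed interaction strengths e_ij as edge weights (not
re-derived per layer), then pools node embeddings by a per-feature mean.
The two pooled vectors are concatenated and passed through two fully
connected layers (ReLU between). Default widths: 16 per convolution
layer, 128 for the first dense layer; both configurable. Nodes without
edges in a branch pass through the self term only, so a graph with zero
internal edges degenerates gracefully. The rationale for two branches is
to learn both the interaction itself (external) and each side's
propensity to interact (internal).

The output is permutation-invariant (mean pooling) and — because every
upstream feature is rotation-invariant — identical for rigidly
transformed inputs. Hierarchical pooling inside the blocks is not
implemented; the mean flatten is the only pooling. The two branches are
independent; an interleaved variant that alternates internal/external
convolutions on shared embeddings is a possible extension, not built.

Forward pass, analytic gradients and the Adam optimizer are implemented
directly on NumPy arrays; the gradients are checked against central
finite differences in the test suite. Loss is mean squared error for
regression and softmax cross-entropy for classification, with optional
per-class weights; an automated mode sets weights inversely proportional
to class counts (normalized to sum 1), equivalent to duplicating
minority examples. Training shuffles per epoch from a single seed that
also fixes parameter initialization; the returned parameters are those
minimizing the evaluation-set loss across epochs (the defensible variant
of train-set versus eval-set selection). A non-finite loss aborts with
the offending epoch and graph named. Checkpoints are JSON (parameters,
config, scaler, feature-column names); scoring refuses graphs whose
feature columns differ from the checkpoint's.

## Metrics

ROC AUC (rank-averaged ties, equivalent to Mann–Whitney U, via
scikit-learn), hit rate (percentage of all positives in the top N),
success rate (percentage of complexes with ≥ 1 positive in the top N),
Spearman ρ (average ranks for ties, via scipy), and a binary confusion
report (accuracy, sensitivity, specificity, precision; undefined ratios
are NaN, never 0). Ranking ties are broken by a stable sort on model id,
so top-N metrics are deterministic. A per-complex averaged ROC helper
interpolates TPR onto a fixed FPR grid and averages across complexes.

## Synthetic data

The fixtures module generates everything the pipeline consumes. A
reference complex is two idealized extended chains (N, CA, C, O and CB
except glycine; CA spacing 3.8 Å) facing each other CB-to-CB across a
4 Å gap, with seeded random amino-acid types and 0.15 Å coordinate
jitter; at the default 9 residues per chain this guarantees ≥ 5
cross-chain contacts at 5 Å and a connected interface at the default
cutoffs. Decoys rigidly perturb the ligand chain at graded levels —
default (translation Å, rotation °) pairs (0,0), (1,4), (2,8), (4,16),
(8,30) — about a random axis through its centroid, recording the true
transform; median fnat decreases and median lRMSD increases with level,
spanning both sides of the 0.3 label threshold. Synthetic PSSMs draw
integer scores in [−4, 4] and bias the own-residue column by +6, so the
own-residue score dominates its row as in profiles of conserved
positions.

The desk-scale scoring benchmark is 16 independent reference complexes
× 5 levels × 7 decoys (≈ 560 graphs; a few far-perturbed decoys have no
interface and are dropped, as unconvertible models would be), default
26-column features, fnat regression for 20 epochs, batch 128, Adam at
0.001 — the standard scoring configuration at a size a laptop handles in
seconds. What passing shows: the full pipeline (structures → graphs →
features → targets → training → ranking) is wired correctly and the
network can learn a geometric quality signal. What it does not show:
performance on real docking decoys, whose conformational diversity,
side-chain packing and energetics the rigid-perturbation generator does
not emulate.

## Numerical choices and limitations

- Cutoff boundaries are inclusive everywhere; boundary fixtures pin this.
- Graphs are undirected, stored once with i < j, expanded to symmetric
  dense adjacencies at network load (interfaces have tens of nodes, so
  dense is cheap).
- The brute-force all-pairs distance enumeration is the correctness
  reference for node/edge/contact construction in tests; production code
  may use a k-d tree for the atom-level search.
- Superposition requires ≥ 3 non-collinear atom pairs; improper
  (reflection) fits are rejected.
- Only two-chain complexes, first PDB model, protein residues; no
  atom-level graphs, no mmCIF, no residue depth / half-sphere exposure
  features (deliberately omitted: slow to compute and largely implied by
  BSA plus the node neighbourhood).
- Training is CPU-bound pure NumPy; it is sized for desk-scale datasets
  (hundreds to thousands of graphs), not for hundred-thousand-model
  docking benchmarks.
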