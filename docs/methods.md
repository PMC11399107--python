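# Methods

This note records the modeling choices behind `helixspec`: what is computed,
which parameters matter, what the synthetic data does and does not emulate,
and where the design was genuinely open.

## Structure model

Parsing keeps heavy atoms only. Waters, ions, ligands and hydrogens are
dropped; alternate locations keep the highest-occupancy conformer (ties
resolve toward altloc "A"); only the first model of multi-model files is
read. DNA is restricted to standard DA/DC/DG/DT — chemically modified bases
(e.g. 5-methylcytosine) and RNA are rejected with a clear error, because the
sym-helix template and pairing rules assume unmodified B-form duplex DNA.

Watson–Crick pairs are detected geometrically: complementary bases on
different strands, C1′–C1′ distance in [9.0, 11.5] Å, glycosidic-nitrogen
distance ≤ 4.0 Å, each nucleotide in at most one pair (greedy by N–N
distance). Both gates are parameters of `detect_base_pairs`. The default
glycosidic-N gate is calibrated to the package's idealized duplex geometry,
in which the glycosidic nitrogens straddle the helix axis; survey-derived
crystal structures place these nitrogens farther apart (~9 Å in canonical
B-DNA), so parsing such structures requires widening `max_n_distance`. The
Watson strand is the longer strand (tie → lexicographically smaller chain
id), making flank coordinates reproducible; pair indices are 0-based and run
5′→3′ along it. A 5′-terminal nucleotide without a phosphate yields a
sym-helix phosphate point marked absent rather than an imputed position.

## Sym-helix

The base-pair frame has its origin at the midpoint of the two glycosidic
nitrogens, y along Crick-C1′ → Watson-C1′, z along the local helix direction
(from neighboring pair origins, orthogonalized against y; terminal pairs use
their single neighbor; an isolated pair is a geometry error), and
x = y × z oriented toward the major groove (checked against the
C1′-midpoint → origin sense, flipping z to preserve right-handedness).
Anchoring frames on C1′/glycosidic-N only — never on base-ring atoms —
makes the sym-helix *exactly* independent of base identity at fixed
coordinates, which the tests assert bytewise.

Base-edge points are template offsets in frame coordinates (Å), treated as
data and config-overridable:

* major: (2.2, −2.4, 0), (2.9, −0.8, 0), (2.9, 0.8, 0), (2.2, 2.4, 0)
* minor: (−2.6, −1.6, 0), (−3.0, 0, 0), (−2.6, 1.6, 0)

These are package defaults chosen to mimic averaged Watson–Crick
functional-group sites; they are not fitted to any particular structure
survey. Backbone points use actual coordinates: the two phosphate P atoms
and the two sugar-ring centroids (C1′, C2′, C3′, C4′, O4′). Every point
carries an outward normal (unit vector from the frame origin) and the local
helix axis; together with distances these are the only geometric inputs to
the network, which makes the whole pipeline rigid-motion invariant by
construction.

Shape features per pair: twist, rise and roll from the relative transform
between consecutive frames (assigned to the earlier pair; the last pair
copies its neighbor), and minor groove width as the minimum cross-strand
P–P distance between the Watson phosphate of pair i and Crick phosphates of
pairs i−4…i−2, minus 5.8 Å of phosphate radii, floored at 0 — the usual
refined-width convention. Missing-phosphate widths are imputed with the
helix mean. Shape features are z-scored per helix before entering the
network so the model sees relative, scale-robust variation.

## Protein graph

Vertex features are pure lookups on (residue, atom name, element):
element one-hot (C/N/O/S/P/other), donor and acceptor flags from a fixed
per-residue table (backbone N donates, backbone O accepts; Arg NH1/NH2/NE
donate; Asp/Glu carboxylates accept; Cys SG both donates and accepts via the
thiol sulfur, a specificity-relevant contact in some major-groove
interfaces), aromatic-ring membership for His/Phe/Tyr/Trp, a backbone flag,
a residue-class one-hot (Arg/Lys/His positive; Asp/Glu negative;
Ser/Thr/Asn/Gln/Cys/Tyr polar; the rest hydrophobic; nonstandard residues
"other" with element-default flags) and a formal charge sign. No
solvent-accessibility or secondary-structure descriptors in this version —
they would add heavy dependencies; the feature block is width-parameterized
so alternatives can be slotted in.

Edges connect atoms within `r_graph` = 4.0 Å (covalent bonds plus close
contacts). A vertex above `max_degree` = 16 keeps its nearest neighbors and
the edge set is re-symmetrized by union, so memory stays predictable while
the graph remains symmetric.

## Network

Implemented on a small reverse-mode autodiff core (`helixspec.nn`) written
on numpy; gradients are verified against finite differences in the test
suite. Defaults (all in `ModelConfig`): embed_dim 32, 3 protein layers,
bipartite cutoff 5.0 Å, 16 Gaussian radial basis functions, two 1D
convolution layers of width 48 with kernel 5 (odd, same-length padding).

* Protein message passing: residual updates with mean-aggregated messages
  `MLP([h_neighbor, rbf(d)])`. A vertex with no edges keeps its input
  projection — the learnable map of its own features.
* Bipartite readout: per point group (major, minor, phosphate, sugar) an
  independently parameterized `MLP([h_atom, rbf(d), cos∠(edge, normal),
  cos∠(edge, axis)])` over edges within 5 Å, aggregated per point as
  mean ⊕ max. Mean is density-robust; max preserves sharp single contacts.
  Points with no (unmasked) edges contribute zero vectors.
* Flattening: per pair, the 11 point vectors in fixed group/slot order
  (22·embed_dim values), plus 4 shape features and a 4-wide sequence slot.
  Inactive blocks under a given readout mode are zero-filled so the feature
  width is mode-independent.
* Head: 1D convolutions over the pair axis, a 4-way linear map and a
  per-position softmax — the simplex constraint is enforced exactly rather
  than approximately (softmax, not independent sigmoids). The head is
  zero-initialized, so an untrained model predicts exactly uniform columns;
  training moves it away from that maximally uninformative prior.

Flanks are predicted, never trimmed: the loss only covers target-aligned
columns, and well-calibrated predictions on unbound flanks approach uniform
columns (asserted on held-out synthetic data, mean information content
≤ 0.2 bits; measured ≈ 10⁻⁵ bits).

Edge masks remove bipartite edges of selected atoms only — the protein
graph is untouched — and masking an atom with no bipartite edges leaves the
prediction bitwise identical. Determinism: for a fixed seed and input, all
operations are deterministic numpy; two fresh models with the same config
produce bitwise-equal predictions.

## Training

The loss is L1 on probabilities over covered columns (the MAE metric family;
cross-entropy available by flag). The target→structure correspondence is
computed once per datapoint and frozen. Two correspondence paths exist:

* experimentally derived PWMs are placed by ungapped local alignment against
  the structure's DNA sequence (score = mean matched probability; both
  strands; ties → larger overlap, forward strand, smaller offset);
* synthetic ground truths use the identity placement, because a mostly
  uniform truth PWM gives the aligner almost no positional signal and free
  alignment would scramble the register between planted probes and their
  columns.

Folds are cluster-aware (all datapoints sharing a `group_label` stay
together; groups shuffled by seed and dealt round-robin). The optimizer is
Adam (lr 5·10⁻³, batch 16) with early stopping on validation loss
(patience 8) and best-state restoration; defaults are sized so the full
5-fold run on the 300-complex synthetic corpus takes ~3 minutes on one CPU.
The ensemble is the column-wise arithmetic mean of the fold models (size 5
by default), which stays on the probability simplex.

## Interpretation

Relative importance is exact per-forward-pass edge masking, not gradient
saliency: `RI_a = MAE(Y, Y_~a) / max_b MAE(Y, Y_~b)`, computed over all
protein heavy atoms within the bipartite cutoff of any sym-helix point
(configurable scope). If no atom has any effect — e.g. an untrained
zero-head model — all RI are set to 0 and a degenerate-model warning is
emitted. Residue aggregates: mean, max, sum and `log2(1 + Σ RI)`. Outputs
include delimited atom/residue tables and a PDB copy with RI stamped into
B-factors for sphere visualization. Comparing residue aggregates against
external mutagenesis ΔΔG datasets is supported as a workflow but requires
data this package does not ship.

## Synthetic data: what it emulates, what it does not

The generator emits an idealized straight-axis B-form duplex: per
nucleotide a phosphate (backbone radius 9.4 Å, strands 154° apart across
the minor groove), five sugar-ring atoms and the glycosidic nitrogen at
fixed frame offsets, with twist 36°/step and rise 3.4 Å/step and Gaussian
coordinate noise of 0.05 Å (small enough that geometric assertions stay
tight; a larger value stresses robustness). Probes are three-atom
pseudo-residues docked 2.8–3.2 Å outside a target sym-helix point along its
outward normal, named ARG/ASP/ALA by class so the standard featurization
applies unmodified. Planted rules impose ground-truth columns: donor@major
→ G-favoring (12/15 ≈ 0.8, mimicking the bidentate Arg–guanine H-bond),
acceptor@major → A-favoring, hydrophobic@major → T-favoring, any
class@minor → a mild A/T column (0.35/0.15/0.15/0.35, reflecting
narrow-minor-groove A-tract preference), backbone targets → uniform columns
with a local groove-narrowing of the flanking phosphates. The default
corpus mixes these rules at 30/25/25/10/5/5%, lengths 10–16 bp, 1–3 rules
per complex kept ≥ 2 pairs from the ends, with `group_label` = sorted rule
signature for cluster-aware folds.

Not emulated: real protein folds and rotamers, base-ring atoms, sequence-
dependent DNA shape, solvation, crystallographic noise and disorder, and
the label noise of real PWM databases. Passing tests therefore demonstrate
that the architecture can read geometry-plus-chemistry out of an interface
and localize it to the right columns — not that the shipped defaults reach
any particular accuracy on experimental corpora, which would require the
curated structure/PWM dataset this package deliberately does not bundle.

## Numerical choices and degenerate inputs

* Pairing is greedy on glycosidic-N distance; ties in the alignment search
  resolve by larger overlap, then forward strand, then smaller offset.
* Softmax uses max-shifted exponentials; segment-max gradients split ties
  equally (a deterministic subgradient).
* Zero-length edge directions (atom exactly on a point) fall back to a zero
  unit vector; absent sym-helix points get zero feature vectors and are
  excluded from edge building.
* Degenerate geometry (collinear frame anchors, isolated pairs) raises a
  geometry error rather than producing silent nonsense.
* Checkpoints embed a format version and config; loading refuses on
  mismatch.

## Problem sizes used by the shipped experiments

The recovery experiment (tests and acceptance script) trains a 5-fold
ensemble on 300 generated complexes (~240 train / 60 held-out per fold,
epochs ≤ 40 with early stopping); the ablation comparison uses 60-complex
major-groove-only corpora over 3 seeds; the toy ensemble behind the
interpretation tests uses 30 complexes at 10 epochs. These sizes are the
package's reference study conditions for the synthetic generator.

## Known limitations

* Double-stranded, unmodified B-form DNA only; no RNA, single strands,
  mismatches or modified bases.
* One duplex per complex; multiple disconnected duplexes are rejected
  (biological-assembly reconstruction from symmetry operators is out of
  scope).
* The base-edge template and shape-feature set are package conventions, not
  fitted quantities; both are configurable.
* The default pairing gate assumes the package's idealized duplex geometry
  (see Structure model above) and must be widened for survey-derived
  crystal structures.
* CPU-only by design; the numpy autodiff core is sized for desk-scale
  corpora, not large-scale training.
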