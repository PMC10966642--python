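# Methods

## The problem

Coarse-graining a polymer melt replaces each monomer by one bead at the
monomer's center of mass.  Backmapping is the inverse, one-to-many
problem: given bead positions **Q** and bead types **c**, produce one
representative all-atom configuration **q** — i.e. a sample from
P(**q** | **Q**, **c**).  This package implements a deterministic deep
surrogate for that conditional for linear poly(lactic acid) (PLA), whose
monomers are chiral (L and D lactic acid units), so the reconstruction
must also respect a requested stereo-sequence.

## Chemical model

A monomer is the repeat unit –O1–C2(H5)(C4H3)–C3(=O2)– with the alpha
carbon C2 as the chiral center (substituents O1, C3, C4, H5).  Chains
are linked C3(i)→O1(i+1) and terminated by hydroxyls: the first
monomer's O1 carries H1, the last monomer's C3 carries O3–H3.  An
n-monomer chain therefore has 9n + 3 atoms (903 for a 100-mer) and, the
bond graph being a tree, 9n + 2 bonds.  The cap constitution is an
inference: it is the unique assignment consistent with the printed
per-chain atom counts and a hydroxyl group at each chain extreme.
Standard atomic masses are used (C 12.011, O 15.999, H 1.008 amu).

One detail is deliberately asymmetric with the reference bookkeeping:
published tables list 2700 CG particles for 70 chains of 30 monomers,
but the mapping itself (one bead per monomer) gives 70 × 30 = 2100.
The package follows the mapping definition.

## Representation: bond vectors and anchors

Every atom of a chain maps to one row of a (S, ·) tensor in a fixed
traversal order (O1 → [H1] → C2 → H5 → C4 → H6,H7,H8 → C3 → O2 →
[O3 → H3] per monomer).  The monomer root O1 carries the anchor vector
v0 = r(O1) − Q(monomer); every other atom carries the bond vector from
its traversal parent.  This yields 100 anchor + 803 bond rows = 903
informative rows for a 100-mer, padded with zeros to S = 1024 (the
smallest power of two that accommodates the chain; S = 256 for the
20-mer desk systems).  Targets are divided by a fixed vector scale of
0.3 nm — a generous bound on any PLA bond or anchor vector — so they
lie strictly inside the tanh output range [−1, 1].

Input rows have k + 3 columns: a 3-column CG feature plus the one-hot
bead type.  The CG feature of every atom of monomer i is the scaled
neighbor displacement (Q_i − Q_{i−1})/1.5 nm (zero for the first
monomer) — translation-invariant and local.  An alternative feature
(bead minus chain COM) is retained behind a switch.  The exact content
of these three columns is an implementation decision; only their
dimensionality is externally fixed.

Bead types: chain-end monomers are always distinct types.  A
homopolymer training set uses k = 3 (interior/first/last); a copolymer
set k = 4 (L-interior/D-interior/first/last); combining homopolymer and
copolymer data keeps the four interior labels distinct (homo-L, homo-D,
copo-L, copo-D) for k = 6.

Reconstruction anchors each monomer's center of mass exactly on its
bead: provisional positions follow the traversal tree, then a rigid
per-monomer translation enforces the CG mapping.  Consequences, both
verified by tests: encode→decode is lossless to float32 precision, and
re-mapping any decoded structure returns the input beads to < 1e−9 nm
regardless of the predicted v0 rows (which are auxiliary).  The
inter-monomer linkage C3(i)→O1(i+1) is never used for placement; its
implied length is a quality-control metric.  After stereochemistry
correction (below) the reflected monomers' centers of mass move
slightly, so the pipeline reports the bead-consistency residual both
before and after correction.

## Network

A 1-D U-net maps (S, k+3) to (S, 3): five down-sample blocks (stride-2
convolution → leaky ReLU (slope 0.2) → batch normalization) with filter
counts 64, 128, 256, 512, 512; five up-sample blocks (stride-2
transposed convolution → ReLU, dropout 0.5 on the first); skip
connections concatenate each encoder level onto the decoder level of
matching length; the head is a stride-1 convolution to 3 channels with
tanh.  Kernel width (4), the leaky-ReLU slope, and concatenation as the
skip merge are implementation choices recorded in every checkpoint.
The layer library (convolutions, batch norm, dropout, Adam) is
implemented in NumPy with manual backpropagation; every analytic
gradient is validated against finite differences in the test suite.

## Loss

The training objective is a weighted sum of five geometric penalties on
unscaled (nm) quantities: mean squared bond-vector deviation (L_bv),
mean squared bond-length deviation (L_bl), mean squared bending-angle
deviation (L_ba), a periodic dihedral penalty mean(1 − cos Δφ) (L_da),
and mean squared anchor deviation (L_v0).  The reference configuration
uses λ_bv = λ_bl = 1 and zero for the rest — the combination found to
give the best reconstructions — so the angle/dihedral/anchor terms are
reported diagnostics by default but remain fully trainable.  Angle and
dihedral values require Cartesian geometry; positions are an affine
function of the predicted vectors (traversal cumulative sums plus
COM anchoring onto beads reconstructed from the input's CG
displacement columns), so the chain rule is exact.  Inverse-cosine
arguments are clamped to ±(1 − 1e−7) and degenerate norms floored at
1e−8, keeping gradients finite for arbitrary predictions.

## Training

One sample is one chain of one frame.  Mini-batch gradient descent with
batch size 64 and Adam at an initial learning rate of 1e−3; when the
validation loss fails to improve (relatively) by 1e−5 for a patience
window, the rate is multiplied by 1/8 down to a floor of 1e−6.  Frames
are split 80/10/10 into train/validation/test before encoding, so no
chain of a validation frame is seen in training.  The best-validation
parameter set is retained.  The patience window and improvement
threshold are implementation defaults (20 epochs at production scale,
10 for the desk-scale runs below).

## Stereochemistry

The handedness of monomer i is the sign of the scalar triple product
det[r_O1 − r_H5, r_C3 − r_H5, r_C4 − r_H5]; positive is L by the
convention fixed from the canonical L monomer of the synthetic
generator.  |det| < 1e−6 nm³ marks a degenerate (planar) center as
undefined; undefined counts as a mismatch but cannot be corrected by
reflection.  A CIP-style cross-check for the fixed priority
O1 > C3 > C4 > H5 is provided: L corresponds to the (S) descriptor, as
for lactic acid.  A wrong monomer is corrected by reflecting H5 and the
methyl group (C4, H6–H8) through the plane containing C2, O1 and C3 —
the unique plane that keeps the backbone fixed while swapping the two
off-backbone substituents.  The reflection is an isometry and an
involution (tested); overlaps it may create are reported by a
minimum-distance audit and left to downstream relaxation, which is
outside this package (no force field, no MD).

## Synthetic ensembles

Because no reference trajectories ship with the package, a generator
produces ensembles with fully known statistics.  Chains are grown
atom-by-atom: bond lengths exact (C–O ester 0.143, C–C 0.152–0.153,
C=O 0.122, C–H 0.109, O–H 0.097 nm — loosely PLA-like configuration
values, not force-field parameters); backbone bending angles Gaussian
(means 109.5–116°, σ 3°); the three backbone torsion classes per
junction (psi: O1–C2–C3–O1′, omega: C2–C3–O1′–C2′, phi:
C3–O1′–C2′–C3′) drawn from stereo-label-dependent von Mises mixtures.
Defaults: psi for L is bimodal at (−65°, 160°) with weights (0.6, 0.4)
and κ = 12; omega is the near-planar ester mode at 180° with κ = 40;
phi is bimodal at (−70°, 75°), weights (0.7, 0.3), κ = 12; D mixtures
are the parity images.  H5 and C4 complete an exactly tetrahedral
wedge at C2 whose side is chosen by the sequence letter, so chirality
holds by construction; the methyl and hydroxyl rotors are free
(uniform).  Chains are independently rotated and placed uniformly in a
periodic box; frames are i.i.d. (the model trains frame-wise, so time
correlation is irrelevant here).  No excluded volume is imposed by
default (an optional hard-core placement distance exists), and the
default schedule mirrors the reference melt bookkeeping: 70 chains of
100 monomers, frames every 200 ps over 1 μs (5000 snapshots).

What the generator does *not* emulate: inter-chain packing correlations
(so intermolecular RDF tests can only assert the ideal-gas limit),
excluded volume, hydrogen-bond geometry, and temporal correlation.
Tests passing on this data demonstrate that the machinery — codec,
network, loss, training loop, stereo logic, analyses — is correct and
that the network can learn CG→atom correlations of realistic geometric
structure; they do not certify accuracy on any particular force field's
melts.

## Analyses

Dihedral distributions are pooled, normalized histograms (default 100
bins over (−180°, 180°]) selectable by dihedral class and stereo
context (e.g. the L–D junction classes).  RDFs use minimum-image
distances in orthorhombic boxes, same-chain (intramolecular) or
different-chain (intermolecular) pair filters, and ideal-gas shell
normalization (bin width 0.01 nm by default; r_max must stay below half
the box).  Internal distances ⟨R_n²⟩/n average over all backbone pairs
at separation n (backbone = O1, C2, C3 repeated), computed on unwrapped
coordinates.  Radius of gyration is mass-weighted; density converts
amu/nm³ to kg/m³.  Uncertainties come from block averaging with four
contiguous blocks (trailing remainder dropped; the spread of block
means is the half-width).

## Desk-scale configuration

The reference architecture (64→512 filters, S = 1024) and schedule
(1000 epochs) target GPU-scale training.  The package's CPU-scale
validation condition — used by the end-to-end test — is: 10 chains of
20 monomers, 500 frames, λ_bv = λ_bl = 1, a reduced-width U-net
(base 32 filters, capped at 128), S = 256, and up to 85 epochs with
plateau patience 10.  At this size the training and validation curves
decrease to a close plateau, and the backmapped test frames place the
backbone bond-length peaks on the generator's values; the end-to-end
test asserts the torsion-mixture histogram and all heavy-atom
bond-length peaks as well, at tolerances recorded in the test itself.

A structural caveat applies to distribution-level checks: the network
is a deterministic regressor trained under squared error, so it
approximates the conditional mean E[**b** | **Q**, **c**].  Decoded
torsion marginals are therefore the generator's mixtures convolved with
the conditional spread of the torsion given the local bead path (of
order 10° here, estimated with a nearest-neighbour oracle on bead-path
invariants) plus the remaining fit error.  Sharp multimodal torsion
statistics can consequently come out broadened at desk scale; in the
full-scale workflow this residual blur is removed by the short MD
relaxation that follows backmapping, which is outside this package's
scope.

## Known limitations

* The predictor is deterministic: it returns one representative
  structure per CG input, not samples from the full conditional.
* No post-reconstruction relaxation is provided; outputs are intended
  as starting points for external MD.
* Orthorhombic boxes only; chains must be unwrapped before encoding.
* The stereo corrector cannot fix degenerate (planar) centers.
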