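# Methods

This note documents the models and procedures implemented in `mhcdyn`, the
assumptions behind them, the parameters that matter, the design choices made
where the design was genuinely open, and what the synthetic test fixtures do
and do not establish about real data.

## Structures, trajectories and conventions

Coordinates are in Ångström, residue indices are 1-based within each chain
(so peptide positions P1..P9 map to residue indices 1..9 of the peptide
chain), and frame times are in nanoseconds. A complex has exactly one peptide
chain of exactly nine residues; chain roles (MHC α chain, β2-microglobulin,
peptide) are either supplied or inferred (longest chain → MHC α, 9-residue
chain → peptide). Hydrogens are parsed but excluded from every distance,
graph, SASA, RMSD and RMSF computation. Van der Waals radii are the Bondi
values, fixed in a bundled data file so that surface areas and contact graphs
are bit-for-bit reproducible. Trajectories are multi-model PDB (always
accepted) or an `.npz` frame-stack container behind the same reader contract;
the trajectory carries an equilibration cutoff, 30 ns by default, matching
the exclusion window applied before any training or windowed statistic.

## Solvent-accessible surface area

Per-residue SASA is computed over full residues with a probe radius of
1.4 Å. The integrator is a sharpened variant of Shrake–Rupley sphere
sampling: each atom's extended sphere (r_vdw + probe) is split into
`n_points` equal-area latitude bands (default 960), and within each band the
azimuthal arcs occluded by neighbouring spheres are resolved *exactly* as a
union of intervals, leaving only the polar discretization as a quadrature
error. Plain point-counting at comparable point counts fluctuates by a few
percent when the point count is doubled, because the error is concentrated on
the occlusion boundaries; the band integrator's per-residue values change by
well under 0.1 % on doubling, so the convergence contract (< 0.5 % per
doubling) holds with a wide margin, and the isolated-sphere closed form
4π(r + probe)² is reproduced essentially exactly. An atom engulfed by a
neighbour reports zero area. The hydrophobic/hydrophilic split sums residues
in a configurable hydrophobic set (default {A, V, L, I, M, F, W, P, G});
hydrophobic + hydrophilic equals the total identically because it is a
partition of the same per-residue values.

## Superposition, RMSD, RMSF, anchor distances

All fluctuation measures first superpose frames by a least-squares (Kabsch)
fit of the MHC binding-domain heavy atoms — the MHC α atoms within 8 Å of the
peptide in the reference frame — so that peptide motion is measured relative
to the groove, not to the lab frame. Peptide RMSD is over peptide heavy
atoms against a reference frame; RMSF is the root-mean-square fluctuation
about the time-average structure over production frames, reported per peptide
position or per MHC residue for a backbone or side-chain selection (glycine
side chains report NaN). Anchor distances are the per-frame minimum over all
(anchor heavy atom, MHC α heavy atom) pairs for P2 or P9. Class comparisons
compute per-peptide window means and standard deviations and test the class
difference in each with Welch's two-sample t-test (two-sided). The choice of
Welch's test — for the fluctuations as well, applied to the per-peptide
window SDs — is a documented convention; only "computed p-values" is fixed by
the analysis design.

## Markov state models

The pipeline is: backbone φ/ψ dihedrals → sin/cos features (a 9-mer
contributes 8 φ + 8 ψ = 32 dimensions; chain-terminal undefined angles are
omitted consistently) → tICA → k-means → reversible maximum-likelihood
estimation.

*tICA.* Covariances are estimated mean-free with the symmetrized
(reversible) estimator; C(τ) is symmetrized as (C + Cᵀ)/2 and C(0) receives a
shrinkage term ε·I (ε = 10⁻¹⁰) before the dense symmetric generalized
eigenproblem is solved. Components are reported in descending eigenvalue
order; tICA timescales are −τ/ln|λ|. The five-component default reflects the
five-timescale parameterization used at production scale; a plain (unscaled)
projection is the default.

*Discretization.* k-means with k-means++ seeding, fixed seed, tolerance
10⁻⁶, up to 500 iterations. The production default k = 3000 shrinks
automatically (with a warning) when fewer samples are available, because
desk-scale tests run on toy systems.

*Estimation.* Counts are sliding-window at the chosen lag and never cross
trajectory boundaries. The count matrix is trimmed to its largest strongly
connected component (the active set, with the index mapping recorded), then
the detailed-balance-constrained likelihood is maximized by the standard
self-consistent fixed-point iteration on the symmetric flux matrix
x_ij = (c_ij + c_ji) / (c_i/x_i + c_j/x_j), converged when the relative
change drops below 10⁻¹⁰. T = x/x_row is row-stochastic to 10⁻¹⁰ and
satisfies detailed balance to better than 10⁻⁸ by construction. Eigenpairs
are computed in the π-symmetrized form, so they are real and π-orthogonal;
implied timescales skip λ₁ = 1 and report NaN with a warning for
non-positive eigenvalues. The production lag is 25 ns; lags shrink with a
warning when a trajectory is too short.

## Molecular contact graphs

Two graphs per frame, both under a global 8 Å heavy-atom cutoff. The LL
(intramolecular peptide) graph excludes atom pairs within two covalent bonds
(1-2 and 1-3 pairs); the covalent graph comes from residue templates plus
inter-residue peptide bonds — never from distance heuristics. The LP graph
contains only cross-molecule MHC–peptide contacts. Edges carry the distance,
a bin index under the default scheme (2.5, 4, 6, 8 Å — four bins, the last
edge being the cutoff), and an exponential weight
w = min(1, exp(−(d − d₀)/σ)) with d₀ = 1.5 Å and σ = 2 Å. The weighting
form, bin edges, and node features (element one-hot over {C, N, O, S},
backbone flag, peptide-position scalar) are this package's documented
defaults, all configurable and recorded with any saved model; no external
constants fix them. Peptide covalent bonds are deliberately not encoded as a
graph channel, since that information lives in the sequence representation.

## Classifiers

*MD-graph network.* Each of LL and LP has its own encoder of three
convolutional modules. A module holds one linear submodule per distance bin;
the update is h ← relu(h W_self + Σ_b A_b h W_b + bias), where A_b is the
edge-weighted adjacency restricted to bin b — messages are aggregated over
neighbours with their distance weights (an empty LP edge set contributes zero
messages, not an error). After three modules the node states pass a fully
connected layer, are gathered over peptide atoms, and max- and average-pooled
into a per-graph embedding; the LL and LP embeddings are concatenated and fed
through a dense layer into a two-way softmax. Because every aggregation is a
sum, max or mean over nodes, the output is exactly invariant under node
relabeling.

*Sequence CNN.* Sequences are one-hot encoded with residue columns ordered by
six similarity classes — aliphatic {A,V,L,I,M,C}, aromatic {F,W,Y,H}, polar
{S,T,N,Q}, positive {K,R}, negative {D,E}, special {G,P} (shipped as a table,
overridable). A 2-D convolution spans both the physical (position) and
chemical (ordered-residue) axes; the default kernel covers 3 positions and
the full 20-column chemical axis. Pooling runs over the chemical axis only —
a position-specific motif must stay localized on the position axis for the
model to generalize rather than memorize — followed by two dense layers and
a softmax.

*SASA reference model.* A small dense network over per-position window means
and SDs of total and hydrophobic SASA (9 positions × 4 statistics).

*Training.* Cross-entropy loss; batches of 100; the graph and SASA models use
Adam, the sequence model plain SGD (the more stable choice for that
architecture). "Until the training loss converged" is operationalized as a
plateau rule: stop when the 5-epoch moving average changes by less than a
relative 10⁻³, with a 30-epoch minimum so the flat early phase of SGD cannot
trigger it; the epoch caps default to 140. Per-frame training examples
inherit their peptide's label, frames inside the 30 ns equilibration window
are excluded at graph-construction time, and peptide-level P(immunogenic) is
the mean of per-frame softmax outputs (one value per peptide for the
single-input models). The aggregation rule is a package convention — mean was
chosen as the natural estimator of the conformational-ensemble average.

The networks run on a small reverse-mode automatic-differentiation engine
written on numpy (`mhcdyn.nn`), gradient-checked against central finite
differences in the test suite. AUROC uses the standard tie convention
(ties count ½) and is verified against a brute-force O(n²) pairwise count.
Model comparison reports Pearson r, R², and its two-sided p-value; the test
of H₀: r = 1 (the "symmetric complement") is available only behind an
explicit flag on the caller's side since it is nonstandard.

## Metropolis split debiasing

The split energy is E = mean(S_p over P1, P3..P8) + w_pos · max(S_p over
P1, P3..P9), with w_pos = 0.5 and S_p the mean over test sequences of the
fraction of training sequences with the identical residue at position p. The
max-term position list excludes only the P2 anchor (the literal reading of
the energy definition's ellipsis); both lists are configurable, as is an
alternative similarity that matches residues by the six-class table. Moves
exchange one uniformly chosen same-class (train, test) pair — class matching
preserves label balance, without which AUC comparisons across splits would be
confounded — and are accepted with min(1, exp(−β ΔE)). Defaults: β = 50,
10 000 steps. The production loop tracks per-position residue counts
incrementally; because counts are integers the tracked energy is identical to
a from-scratch recomputation (asserted to 10⁻¹² in the tests). An ensemble
helper generates independently seeded split pairs.

*Scale of the selection pressure.* With this normalized similarity, a single
swap changes E by roughly (family contrast)/n for split size n, so the
dimensionless selection strength is β·ΔE ≈ β/n per move. At β = 50 the
Metropolis sampler operates in its intended regime — moderate uphill
acceptance, diverse final splits rather than steepest descent — when splits
hold on the order of ten peptides per side; for much larger splits the same β
is weakly selecting and the equilibrium split energy stays near the
random-split distribution. The synthetic confound experiments therefore use
10 + 10 splits drawn from a 20-peptide family-structured dataset, where one
run segregates the peptide families completely (final E at or near the
cross-family baseline, far below the 1st percentile of 200 random splits).

## Synthetic fixtures: what they emulate

*Toy complexes* are two idealized parallel helical strands flanking a binding
channel that holds an extended 9-mer whose P2/P9 side chains dip toward the
receptor (< 5 Å initial anchor distances). They are geometric stand-ins:
hard-sphere sanity checks replace physical energetics, because graph,
observable and Markov-model code paths care only about geometry and
annotations. The groove helices omit carbonyl oxygens to keep a clean
cylindrical channel surface.

*Kinetic trajectories* sample a hidden state path from a known reversible
matrix and render each state as a rigid displacement of the P9 residue plus a
lateral offset of P5, with isotropic Gaussian coordinate noise (σ = 0.05 Å
default). Isotropic noise makes the RMSF ground truth analytic (RMSF → σ√3),
and the analytic slowest timescale −1/ln λ₂ of the generating matrix is the
recovery target. State offsets are chosen as orthogonal combinations of the
two motions because dihedral features are periodic: states placed along a
single motion axis can alias onto one another in feature space.

*Labeled sequence sets* plant a positional rule (default: hydrophobic residue
class at P4 ⇒ immunogenic), optionally with a label-correlated confound
residue at another position. *Family-confounded sets* instead build each
class from noisy copies of family motifs (fidelity 0.98, unique sequences
enforced), mimicking homologous peptide clusters — the realistic source of
trivial train/test similarity; within-class motifs are drawn positionally
disjoint so family membership, not any single shared residue, carries the
confound, and with `signal=None` labels correlate with nothing but family,
the pure-confound limit in which a properly debiased split leaves no
learnable signal.

*Anchor-dynamics ensembles* plant a class gap in P9 excursions. They use an
ensemble-specific wide-groove geometry with the peptide hugging one wall so
the excursion direction (radially away from the near wall) maps 1:1 onto the
measured minimum heavy-atom distance over the planted range; immunogenic
peptides excurse by gap + N(0, 0.35²) Å past the equilibration window,
non-immunogenic ones fluctuate by N(0, 0.10²) Å.

What passing these fixtures shows: the estimators recover planted ground
truth under their own model assumptions at desk scale. What it does not show:
performance on real MD ensembles — real force-field dynamics, water, and the
true conformational heterogeneity of 2883 HLA-A2 peptides are outside the
generators' scope, and the reference-scale sequence dataset bundled for
bookkeeping is synthetic (its class sizes, not its sequences, mirror the
reference corpus).

## Numerical choices and degenerate inputs

- tICA regularization ε = 10⁻¹⁰; a singular instantaneous covariance is
  regularized and logged, not an error.
- Reversible MLE convergence 10⁻¹⁰ relative; empty connected components are
  a connectivity error.
- k-means ties and seeding are delegated to a fixed-seed k-means++; duplicate
  points always share a label.
- SASA bands: atoms with no neighbours short-circuit to the closed form;
  engulfed atoms report zero; polar bands degenerate to inside/outside tests.
- Anchor series window statistics require at least one frame in the window;
  RMSF requires two production frames.
- Metropolis with β = 0 accepts everything; ΔE ≤ 0 always accepts.
- AUROC and the class tests refuse single-class inputs rather than returning
  a default.

## Problem sizes used in the bundled analyses

The acceptance script and test suite run: 100 000-step discrete chains for
estimator recovery; 6 000-frame toy trajectories for the end-to-end MSM
pipeline; 100-frame perturbed-geometry batches for graph oracles; sequence
tasks with 100 training and 250 test peptides per arm; graph tasks with 20
training and 30–50 test peptides (1–2 frames each); 20 + 20 anchor
trajectories of 80 frames; and 10 + 10 splits over 10 000 Monte Carlo steps
with 200-permutation nulls. These sizes give each statistical check a
comfortable margin at interactive runtimes.

## Known limitations

- No Bayesian uncertainty on transition matrices or timescales; no hidden
  Markov models or transition-path theory.
- The exponential edge-weighting constants and distance-bin edges are package
  conventions, not externally fixed values.
- The SASA reference classifier is a plain dense network stand-in; richer
  published variants exist.
- Peptide-level aggregation of frame predictions is fixed to the mean.
- The reversible estimator assumes the trimmed active set is the relevant
  ergodic core; weakly connected fringe states are silently dropped (with
  the mapping recorded).
- mmCIF output, structure repair and protonation are out of scope.
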