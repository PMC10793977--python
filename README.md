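# mhcdyn

Analysis of MHC class I (HLA-A2)–peptide complex molecular-dynamics ensembles
and prediction of peptide immunogenicity. The package combines an unsupervised
kinetics stack — Markov state models built from backbone-dihedral features —
with supervised classifiers over distance-resolved molecular contact graphs,
and a Metropolis Monte Carlo procedure that removes trivial sequence
similarity between training and test splits. It is aimed at computational
immunologists and molecular modellers who want to go beyond sequence-only
epitope prediction by exploiting the structure and dynamics of presented
peptides.

## What it computes

**Markov state models.** Trajectories are featurized as sin/cos of the
peptide-backbone dihedrals (φ, ψ), reduced by time-lagged independent
component analysis (tICA) — the generalized eigenproblem
C(τ) v = λ C(0) v on symmetrized covariances — discretized by k-means
(k = 3000 at production scale), and estimated with a reversible
maximum-likelihood transition matrix T at a fixed lag τ (25 ns at production
scale). Detailed balance π_i T_ij = π_j T_ji holds by construction; implied
timescales follow t_i = −τ / ln λ_i. Spectral tools cover propagation
p_n = p₀ Tⁿ, eigenvector modes (the conformational sets interchanging on each
slow process), and population-weighted observables over the most-populated
states.

**Observables.** Per-residue solvent-accessible surface area over full
residues (with a hydrophobic/hydrophilic split that partitions the total
exactly), heavy-atom peptide RMSD and per-position RMSF after superposition
on the MHC binding domain, and P2/P9 anchor-pocket minimum heavy-atom
distances with Welch-test class statistics on window means and fluctuations.

**Classifiers.** The MD-graph model encodes two heavy-atom contact graphs per
frame, both with a global 8 Å cutoff — the intramolecular peptide (LL) graph,
excluding pairs within two covalent bonds, and the intermolecular MHC–peptide
(LP) graph — through three convolutional modules with per-distance-bin
submodules and exponential distance weighting, then gathers over peptide
atoms, max/average-pools, and classifies with a binary softmax. Reference
models: a 2-D CNN over one-hot sequences ordered by six residue similarity
classes, and a dense network over per-position SASA statistics. Training uses
cross-entropy (Adam for the graph/SASA models, plain SGD for the sequence
model); peptide-level P(immunogenic) is the mean of per-frame softmax
outputs.

**Split debiasing.** Trial exchanges of same-class peptides between train and
test sets are accepted with the Metropolis probability
min(1, exp(−β ΔE)) for the energy

    E = mean(non-anchor positional similarity) + w_pos · max(P1, P3, …, P9 similarity)

with w_pos = 0.5, where the positional similarity S_p is the mean over test
sequences of the fraction of training sequences with the identical residue at
position p. Minimizing E breaks the trivial sequence correlations (e.g.
homologous peptide families straddling a random split) that inflate
classification benchmarks.

**Synthetic fixtures.** Every stage has a generator with known ground truth:
toy grooved receptor/9-mer complexes, trajectories from known reversible
kinetics, labeled sequence sets with planted positional signal or planted
family confounds, and anchor-dynamics ensembles with a planted class gap.

## Worked example

```python
import numpy as np
from mhcdyn import synthetic, msm, observables, debias

# 1. Markov-model recovery of known kinetics
complex_ = synthetic.make_toy_complex()
kin = synthetic.KineticSpec(
    transition_matrix=synthetic.example_reversible_matrix(4, seed=1),
    anchor_displacements=np.array([0.0, 0.0, 3.0, 3.0]),
    conformational_offsets=np.array([0.0, 2.0, 0.0, 2.0]),
    noise_sigma=0.05,
)
traj, _ = synthetic.make_kinetic_trajectory(complex_, kin, n_frames=6000, seed=21)
result = msm.build_msm([traj], n_states=4, lag_time=1.0, seed=0)
its = msm.implied_timescales(result.model, 3)
lam2 = np.sort(np.linalg.eigvals(kin.transition_matrix).real)[-2]
print(f"slowest implied timescales (ns): {np.round(its, 2)}")
print(f"analytic slowest timescale (ns): {-1.0 / np.log(lam2):.2f}")

# 2. Anchor-distance class gap
trajs, labels = synthetic.make_anchor_dynamics_ensemble(20, gap=1.0, seed=3)
series = {p: observables.anchor_min_distance(t, "P9") for p, t in trajs.items()}
stats = observables.class_compare(series, labels)
print(f"P9 anchor mean gap: {stats['mean_gap']:.2f} A (p = {stats['p_mean']:.1e})")

# 3. Metropolis split debiasing
records = synthetic.make_family_confounded_sequences(10, seed=7)
res = debias.run_debias(records, 10, 10,
                        debias.MCConfig(beta=50.0, n_steps=10_000, seed=8))
print(f"split energy: {res.energy_trace[0]:.3f} -> {res.energy_trace[-1]:.3f} "
      f"(acceptance {res.acceptance_rate:.2f})")
```

Output:

```
slowest implied timescales (ns): [9.37 7.67 6.6 ]
analytic slowest timescale (ns): 8.51
P9 anchor mean gap: 0.93 A (p = 1.7e-30)
split energy: 0.431 -> 0.000 (acceptance 0.01)
```

The slowest implied timescale recovered by the full
featurize → tICA → cluster → estimate pipeline (9.37 ns) agrees with the
analytic value −1/ln λ₂ = 8.51 ns of the generating matrix to within the
discretization error expected at this trajectory length. The planted 1 Å
P9 anchor gap between immunogenic and non-immunogenic ensembles is recovered
as 0.93 Å with overwhelming significance, and the Metropolis run drives the
split energy of the family-confounded dataset from 0.431 (a random split)
to 0.000 — train and test no longer share any peptide family.

A command-line interface mirrors the analysis stages:

```bash
mhcdyn --seed 1 simulate complex --out toy.pdb
mhcdyn --seed 1 simulate trajectory --topology toy.pdb --n-frames 400 --out traj.npz
mhcdyn --seed 1 msm --topology toy.pdb --trajectories manifest.csv --outdir msm_out
mhcdyn --seed 1 debias --dataset seqs.csv --train-size 10 --test-size 10 --outdir splits
```

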