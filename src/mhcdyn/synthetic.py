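"""Synthetic fixtures with known ground truth for every analysis stage.

Generators produce desk-scale stand-ins for the real MD inputs: a toy grooved
receptor-peptide complex (two parallel helical strands flanking a binding
channel holding a 9-mer), trajectories sampled from known discrete-state
kinetics, labeled sequence sets with planted positional signal and planted
train/test confounds, and anchor-dynamics ensembles with a planted
class gap. Toy complexes use idealized helices and hard-sphere sanity checks,
not physical energetics: geometric realism is irrelevant to exercising the
graph, observable and Markov-model code paths. All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import (
    AA1_TO_3,
    PeptideRecord,
    Structure,
    Trajectory,
    ValidationError,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


class GenerationError(ValueError):
    """The requested geometry cannot be built."""


# ---------------------------------------------------------------------------
# Toy complex
# ---------------------------------------------------------------------------


@dataclass
class ToyComplexSpec:
    """Geometry of the toy grooved receptor + 9-mer complex."""

    n_mhc_residues: int = 40  # split across the two groove helices
    peptide_sequence: str = "FLIYLDVSV"
    groove_half_width: float = 4.8  # A, helix-axis offset from the channel
    helix_radius: float = 2.3  # A
    helix_rise: float = 1.5  # A per residue
    anchor_depth: float = 2.5  # A, downward dip of P2/P9 side chains
    peptide_y_offset: float = 0.0  # A, lateral shift of the peptide strand

    def __post_init__(self):
        if len(self.peptide_sequence) != 9:
            raise ValidationError("peptide_sequence must be a 9-mer")


def _helix_backbone(n_res: int, axis_y: float, radius: float, rise: float):
    """Idealized alpha-helix backbone atoms along x at the given y offset."""
    names, elements, res_idx, coords = [], [], [], []
    twist = np.deg2rad(100.0)
    for i in range(n_res):
        # N, CA, C sit on the helical curve at staggered phases; carbonyl
        # oxygens are omitted so the strand keeps a clean cylindrical surface
        # facing the channel (the receptor's chemistry is irrelevant here).
        for name, el, dphase, dx in (("N", "N", -0.45, -0.55),
                                     ("CA", "C", 0.0, 0.0),
                                     ("C", "C", 0.45, 0.55)):
            phi = i * twist + dphase
            coords.append([
                i * rise + dx,
                axis_y + radius * np.cos(phi),
                radius * np.sin(phi),
            ])
            names.append(name)
            elements.append(el)
            res_idx.append(i + 1)
    return names, elements, res_idx, np.array(coords)


def make_toy_complex(spec: ToyComplexSpec | None = None, seed: int = 0) -> Structure:
    """Deterministic toy MHC-peptide complex passing all structure invariants.

    Chain M: two parallel groove helices (role MHC_alpha); chain B: a short
    strand standing in for beta-2-microglobulin; chain P: the 9-mer peptide,
    extended along the channel with P2/P9 side chains dipped ``anchor_depth``
    toward the groove so both anchors start < 5 A from the receptor.
    """
    spec = spec or ToyComplexSpec()
    # the construction is fully deterministic; ``seed`` is accepted for
    # interface symmetry with the stochastic generators
    names, elements, res_idx, chain_ids, res_names = [], [], [], [], []
    coords_list = []

    n_per_helix = spec.n_mhc_residues // 2
    offset = 0
    for axis_y in (-spec.groove_half_width, spec.groove_half_width):
        hn, he, hr, hc = _helix_backbone(n_per_helix, axis_y,
                                         spec.helix_radius, spec.helix_rise)
        names += hn
        elements += he
        res_idx += [r + offset for r in hr]
        chain_ids += ["M"] * len(hn)
        res_names += ["ALA"] * len(hn)
        coords_list.append(hc)
        offset += n_per_helix

    # beta2m stand-in: short strand well below the groove
    for i in range(4):
        for name, el, dx, dy in (("N", "N", -1.15, 0.45), ("CA", "C", 0.0, 0.0),
                                 ("C", "C", 1.15, 0.45), ("O", "O", 1.35, 1.6)):
            names.append(name)
            elements.append(el)
            res_idx.append(i + 1)
            chain_ids.append("B")
            res_names.append("GLY")
            coords_list.append(np.array([[i * 3.5 + dx, dy, -9.0]]))

    # peptide: extended strand in the channel, above the helix mid-plane so
    # anchor dips move monotonically toward the receptor surface
    z0 = 3.0
    pep_start = 0.5 * ((n_per_helix - 1) * spec.helix_rise - 8 * 3.5)
    for i, aa in enumerate(spec.peptide_sequence):
        x = pep_start + i * 3.5
        depth = spec.anchor_depth if (i + 1) in (2, 9) else 0.0
        atoms = [("N", "N", (-1.15, 0.45, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
                 ("C", "C", (1.15, 0.45, 0.0)), ("O", "O", (1.35, 1.6, 0.1))]
        if aa != "G":
            atoms.append(("CB", "C", (0.0, -1.2, -depth)))
        for name, el, (dx, dy, dz) in atoms:
            names.append(name)
            elements.append(el)
            res_idx.append(i + 1)
            chain_ids.append("P")
            res_names.append(AA1_TO_3[aa])
            coords_list.append(np.array([[x + dx, spec.peptide_y_offset + dy, z0 + dz]]))

    coords = np.concatenate(coords_list, axis=0)
    structure = Structure(
        atom_name=names, element=elements, residue_name=res_names,
        residue_index=res_idx, chain_id=chain_ids, coords=coords,
        chains={"M": "MHC_alpha", "B": "beta2m", "P": "peptide"},
    )
    _check_geometry(structure, spec)
    return structure


def _check_geometry(structure: Structure, spec: ToyComplexSpec) -> None:
    from scipy.spatial.distance import pdist

    if pdist(structure.coords).min() < 1.0:
        raise GenerationError("overlapping atoms (< 1 A) in generated complex")
    from .observables import anchor_min_distance

    traj = Trajectory(structure, structure.coords[None], np.array([0.0]),
                      equilibration_cutoff=0.0)
    for pos in ("P2", "P9"):
        d = anchor_min_distance(traj, pos).distances[0]
        if d >= 5.0:
            raise GenerationError(f"{pos} starts {d:.2f} A from the receptor (>= 5 A)")


# ---------------------------------------------------------------------------
# Kinetic trajectories
# ---------------------------------------------------------------------------


@dataclass
class KineticSpec:
    """Ground-truth discrete-state kinetics for trajectory synthesis."""

    transition_matrix: np.ndarray  # (m, m) row-stochastic, reversible
    anchor_displacements: np.ndarray  # (m,) A, +z shift of the P9 residue
    conformational_offsets: np.ndarray  # (m,) A, +y shift of the P5 residue
    frame_interval: float = 1.0  # ns
    noise_sigma: float = 0.05  # A, isotropic per-atom Gaussian

    def __post_init__(self):
        t = np.asarray(self.transition_matrix, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1] or t.shape[0] < 2:
            raise ValidationError("transition matrix must be square with m >= 2")
        if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
            raise ValidationError("transition matrix must be row-stochastic")
        self.transition_matrix = t
        pi = stationary_distribution(t)
        if not np.allclose(pi[:, None] * t, (pi[:, None] * t).T, atol=1e-8):
            raise ValidationError("transition matrix must satisfy detailed balance")

    @property
    def n_states(self) -> int:
        return len(self.transition_matrix)


def stationary_distribution(t: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eig(t.T)
    i = np.argmin(np.abs(evals - 1.0))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def example_reversible_matrix(m: int = 4, seed: int = 0, strength: float = 8.0) -> np.ndarray:
    """A deterministic m-state reversible row-stochastic matrix with metastable
    diagonal (off-diagonal rates ~ 1/strength)."""
    rng = np.random.default_rng(seed)
    s = rng.uniform(0.5, 1.5, size=(m, m))
    s = 0.5 * (s + s.T)  # symmetric flux => reversible after row normalization
    s += strength * m * np.diag(rng.uniform(0.8, 1.2, size=m))
    return s / s.sum(axis=1, keepdims=True)


def sample_markov_chain(
    t: np.ndarray, n_steps: int, seed: int = 0, start: int | None = None
) -> np.ndarray:
    """Discrete state path of length ``n_steps`` sampled from ``t``."""
    rng = np.random.default_rng(seed)
    m = len(t)
    cdf = np.cumsum(t, axis=1)
    path = np.empty(n_steps, dtype=int)
    state = int(start) if start is not None else int(rng.integers(m))
    for i in range(n_steps):
        path[i] = state
        state = int(np.searchsorted(cdf[state], rng.random()))
    return path


def make_kinetic_trajectory(
    base: Structure,
    spec: KineticSpec,
    n_frames: int,
    seed: int = 0,
    equilibration_cutoff: float = 0.0,
) -> tuple[Trajectory, np.ndarray]:
    """Trajectory whose frames follow a hidden Markov state path.

    Each frame is the base structure with the state's anchor displacement
    applied to the P9 residue (+z), the state's conformational offset applied
    to the P5 residue (+y), and isotropic Gaussian noise on every coordinate.
    Returns the trajectory and the true state path.
    """
    rng = np.random.default_rng(seed)
    path = sample_markov_chain(spec.transition_matrix, n_frames, seed=int(rng.integers(2**31)))
    pep = base.mask_role("peptide", heavy_only=False)
    p9 = pep & (base.residue_index == 9)
    p5 = pep & (base.residue_index == 5)
    frames = np.repeat(base.coords[None], n_frames, axis=0)
    frames[:, p9, 2] += np.asarray(spec.anchor_displacements)[path, None]
    frames[:, p5, 1] += np.asarray(spec.conformational_offsets)[path, None]
    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    times = spec.frame_interval * np.arange(n_frames)
    return (
        Trajectory(base, frames, times, equilibration_cutoff=equilibration_cutoff),
        path,
    )


# ---------------------------------------------------------------------------
# Labeled sequence sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalRule:
    """Planted label rule: membership of the residue at ``position`` in
    ``residues`` determines the immunogenic label."""

    position: int = 4  # P4
    residues: str = "AVLIMFW"  # hydrophobic signal class


#: label-correlated residue pools for the planted confound
_CONFOUND_POOLS = {"immunogenic": "DE", "non_immunogenic": "KR"}


def make_labeled_sequences(
    n_per_class: int,
    signal: SignalRule | None = None,
    confound_strength: float = 0.0,
    confound_position: int = 7,
    label_noise: float = 0.0,
    seed: int = 0,
) -> list[PeptideRecord]:
    """Random 9-mers whose labels follow a planted positional rule.

    With probability ``confound_strength`` a label-correlated residue is
    written at ``confound_position``, planting exactly the trivial train/test
    sequence correlation the Metropolis debiasing is designed to remove.
    ``label_noise`` flips the planted label with the given probability.
    """
    signal = signal or SignalRule()
    if confound_strength > 0 and confound_position == signal.position:
        raise ValidationError("confound and signal cannot share a position")
    rng = np.random.default_rng(seed)
    complement = "".join(a for a in _AA if a not in signal.residues)
    records = []
    for label, n in (("immunogenic", n_per_class), ("non_immunogenic", n_per_class)):
        pool = signal.residues if label == "immunogenic" else complement
        for _ in range(n):
            seq = list(rng.choice(list(_AA), size=9))
            seq[signal.position - 1] = pool[rng.integers(len(pool))]
            if confound_strength > 0 and rng.random() < confound_strength:
                cpool = _CONFOUND_POOLS[label]
                seq[confound_position - 1] = cpool[rng.integers(len(cpool))]
            out_label = label
            if label_noise > 0 and rng.random() < label_noise:
                out_label = "non_immunogenic" if label == "immunogenic" else "immunogenic"
            records.append(PeptideRecord(sequence="".join(seq), label=out_label,
                                         source="synthetic"))
    return records


#: sentinel: "use the default planted rule"
_DEFAULT_SIGNAL = SignalRule()


def make_family_confounded_sequences(
    n_per_class: int,
    n_families_per_class: int = 2,
    motif_fidelity: float = 0.98,
    family_fraction: float = 1.0,
    signal: SignalRule | None = _DEFAULT_SIGNAL,
    seed: int = 0,
) -> list[PeptideRecord]:
    """Labeled 9-mers built from homologous sequence families.

    A ``family_fraction`` share of each class consists of noisy copies of
    family motifs (each position copies the motif with probability
    ``motif_fidelity``, else mutates uniformly); the remainder are unrelated
    random sequences. This mimics clusters of near-identical peptides — e.g.
    viral variants — embedded in a diverse background, the structure that
    creates trivial train/test sequence similarity under naive random splits.
    Labels follow the planted positional rule when ``signal`` is given, so the
    family structure is a confound, not the signal; with ``signal=None`` the
    labels correlate with nothing but family membership, the pure-confound
    limit where a debiased split carries no learnable signal at all.
    """
    rng = np.random.default_rng(seed)
    complement = "".join(a for a in _AA if signal is None or a not in signal.residues)
    records = []
    seen: set[str] = set()
    for label, n in (("immunogenic", n_per_class), ("non_immunogenic", n_per_class)):
        pool = None
        if signal is not None:
            pool = signal.residues if label == "immunogenic" else complement
        motifs: list[list[str]] = []
        for _ in range(n_families_per_class):
            m = list(rng.choice(list(_AA), size=9))
            # within-class motifs are positionally disjoint so family
            # membership, not any single shared residue, carries the confound
            for p in range(9):
                while any(m[p] == prev[p] for prev in motifs):
                    m[p] = _AA[rng.integers(20)]
            if pool is not None:
                m[signal.position - 1] = pool[rng.integers(len(pool))]
            motifs.append(m)
        n_family = int(round(family_fraction * n))
        for k in range(n):
            in_family = k < n_family
            motif = motifs[k % n_families_per_class] if in_family else None
            while True:
                if in_family:
                    seq = [
                        a if rng.random() < motif_fidelity else _AA[rng.integers(20)]
                        for a in motif
                    ]
                else:
                    seq = list(rng.choice(list(_AA), size=9))
                if pool is not None and seq[signal.position - 1] not in pool:
                    # keep the label rule exact
                    seq[signal.position - 1] = pool[rng.integers(len(pool))]
                s = "".join(seq)
                if s not in seen:  # dataset holds unique peptides
                    seen.add(s)
                    break
            records.append(PeptideRecord(sequence=s, label=label, source="synthetic"))
    return records


def make_reference_scale_dataset(seed: int = 0) -> list[PeptideRecord]:
    """Synthetic stand-in for the full HLA-A2 sequence/label table.

    Generates 1038 immunogenic and 1845 non-immunogenic unique 9-mers with
    HLA-A2-like anchor preferences (L/M at P2, V/L/I at P9). The sequences are
    synthetic; only the bookkeeping (class sizes and totals) mirrors the
    reference dataset.
    """
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    records: list[PeptideRecord] = []
    for label, n in (("immunogenic", 1038), ("non_immunogenic", 1845)):
        made = 0
        while made < n:
            seq = list(rng.choice(list(_AA), size=9))
            seq[1] = "LM"[rng.integers(2)]
            seq[8] = "VLI"[rng.integers(3)]
            s = "".join(seq)
            if s in seen:
                continue
            seen.add(s)
            records.append(PeptideRecord(sequence=s, label=label, source="synthetic"))
            made += 1
    return records


# ---------------------------------------------------------------------------
# Conformational graph ensembles
# ---------------------------------------------------------------------------


def make_conformation_graph_ensemble(
    n_per_class: int,
    n_frames_per_peptide: int = 2,
    noise_sigma: float = 0.10,
    seed: int = 0,
):
    """Labeled contact-graph samples with a planted conformational signal.

    Immunogenic peptides adopt a folded-back conformation: the three
    C-terminal residues are lifted above the N-terminal half, creating
    long-range intramolecular (LL) contacts between sequence-distant atoms.
    Non-immunogenic peptides stay extended in the groove. Returns
    ``(records, graphs)`` where ``graphs`` maps each sequence to per-frame
    (LL, LP) pairs.
    """
    from .molgraphs import build_ll_graph, build_lp_graph

    rng = np.random.default_rng(seed)
    records: list[PeptideRecord] = []
    graphs: dict[str, list] = {}
    seen: set[str] = set()
    for label, n in (("immunogenic", n_per_class), ("non_immunogenic", n_per_class)):
        for _ in range(n):
            while True:
                seq = "".join(rng.choice(list(_AA), size=9))
                if seq not in seen:
                    seen.add(seq)
                    break
            base = make_toy_complex(ToyComplexSpec(peptide_sequence=seq))
            coords = base.coords.copy()
            if label == "immunogenic":
                pep = base.mask_role("peptide", heavy_only=False)
                for res, partner in ((9, 1), (8, 2), (7, 3)):
                    m = pep & (base.residue_index == res)
                    ref = pep & (base.residue_index == partner)
                    target = coords[ref].mean(axis=0) + np.array([0.0, 0.0, 4.5])
                    coords[m] += target - coords[m].mean(axis=0)
            samples = []
            for _f in range(n_frames_per_peptide):
                frame = base.with_coords(
                    coords + rng.normal(0.0, noise_sigma, size=coords.shape)
                )
                samples.append((build_ll_graph(frame), build_lp_graph(frame)))
            records.append(PeptideRecord(sequence=seq, label=label, source="synthetic"))
            graphs[seq] = samples
    return records, graphs


# ---------------------------------------------------------------------------
# Anchor-dynamics ensembles
# ---------------------------------------------------------------------------


def make_anchor_dynamics_ensemble(
    n_peptides_per_class: int,
    gap: float = 1.0,
    n_frames: int = 80,
    frame_interval: float = 1.0,
    equilibration_cutoff: float = 30.0,
    seed: int = 0,
) -> tuple[dict[str, Trajectory], dict[str, str]]:
    """Toy trajectories with a planted P9 anchor-distance class gap.

    Immunogenic peptides make mean P9 excursions larger by ``gap`` (A) with
    larger frame-to-frame fluctuations; non-immunogenic peptides stay bound.
    The excursion is applied along the outward direction from the nearest
    receptor atom, so the planted gap maps directly onto the measured minimum
    heavy-atom distance. Returns trajectories and labels keyed by peptide id.
    """
    if gap < 0:
        raise ValidationError("gap must be >= 0")
    rng = np.random.default_rng(seed)
    # ensemble-specific geometry: a wide groove with the peptide hugging one
    # wall, so the P9 anchor can excurse radially away from its pocket over
    # several Angstrom before any other contact takes over the minimum —
    # the planted excursion then maps 1:1 onto the measured minimum distance
    spec = ToyComplexSpec(groove_half_width=8.0, peptide_y_offset=-2.0,
                          anchor_depth=3.0)
    base = make_toy_complex(spec, seed=seed)
    topo = base

    # outward unit vector: radially away from the near groove wall's axis
    pep9 = topo.mask_role("peptide") & (topo.residue_index == 9)
    from scipy.spatial.distance import cdist

    cb = topo.coords[pep9][topo.atom_name[pep9] == "CB"][0]
    axis_point = np.array([cb[0], -spec.groove_half_width, 0.0])
    u = cb - axis_point
    u /= np.linalg.norm(u)

    p9_all = topo.mask_role("peptide", heavy_only=False) & (topo.residue_index == 9)
    trajectories: dict[str, Trajectory] = {}
    labels: dict[str, str] = {}
    times = frame_interval * np.arange(n_frames)
    for label, n in (("immunogenic", n_peptides_per_class),
                     ("non_immunogenic", n_peptides_per_class)):
        for k in range(n):
            pid = f"{label[:3]}_{k:03d}"
            if label == "immunogenic":
                disp = gap + 0.35 * rng.standard_normal(n_frames)
            else:
                disp = 0.10 * rng.standard_normal(n_frames)
            # excursions only past the equilibration window: bound at the start
            disp = np.where(times >= equilibration_cutoff, disp, 0.0)
            frames = np.repeat(base.coords[None], n_frames, axis=0)
            frames[:, p9_all, :] += disp[:, None, None] * u[None, None, :]
            frames += rng.normal(0.0, 0.03, size=frames.shape)
            trajectories[pid] = Trajectory(
                topo, frames, times.copy(), equilibration_cutoff=equilibration_cutoff
            )
            labels[pid] = label
    return trajectories, labels
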