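"""Distance-resolved molecular contact graphs feeding the classifier.

Two graphs are built per frame, both with a global 8 A heavy-atom cutoff:

* the LL (ligand-ligand) graph — intramolecular peptide contacts, excluding
  atom pairs within two covalent bonds of one another (1-2 and 1-3 pairs),
* the LP (ligand-protein) graph — intermolecular MHC-peptide contacts only.

Edges carry their distance, a distance-bin index, and an exponential distance
weight. The covalent bond graph used for the LL exclusion is derived from
residue templates plus inter-residue peptide bonds, never from distance
heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as bst
from scipy.spatial.distance import cdist

from .io import Structure, Trajectory, ValidationError

GLOBAL_CUTOFF = 8.0  # A

NODE_ELEMENTS = ("C", "N", "O", "S")


@dataclass(frozen=True)
class BinScheme:
    """Ordered distance-bin edges (A); the last edge is the global cutoff."""

    edges: tuple[float, ...] = (2.5, 4.0, 6.0, 8.0)

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValidationError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    @property
    def cutoff(self) -> float:
        return self.edges[-1]

    def assign(self, distances: np.ndarray) -> np.ndarray:
        """Bin index per distance; every d in (0, cutoff] maps to exactly one bin."""
        d = np.asarray(distances, dtype=float)
        if np.any(d > self.cutoff):
            raise ValidationError("distance beyond the global cutoff")
        return np.searchsorted(np.asarray(self.edges), d, side="left")


def edge_weight(
    distance: np.ndarray | float, d0: float = 1.5, sigma: float = 2.0
) -> np.ndarray | float:
    """Exponential distance weight w = min(1, exp(-(d - d0)/sigma)).

    Equals 1 at contact range (d <= d0) and decays strictly beyond it; always
    in (0, 1].
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("distances must be positive")
    w = np.minimum(1.0, np.exp(-(d - d0) / sigma))
    return float(w) if np.ndim(distance) == 0 else w


@dataclass
class MolecularGraph:
    """Undirected heavy-atom contact graph (edges stored once).

    ``atom_indices`` maps node rows back to atoms of the source structure;
    the first ``n_ligand_nodes`` rows are peptide atoms.
    """

    kind: str  # "LL" | "LP"
    node_features: np.ndarray  # (n_nodes, n_features)
    atom_indices: np.ndarray  # (n_nodes,) indices into the structure
    edges: np.ndarray  # (n_edges, 2) node-row pairs, i < j
    distances: np.ndarray  # (n_edges,) A
    bin_index: np.ndarray  # (n_edges,)
    weights: np.ndarray  # (n_edges,) in (0, 1]
    n_ligand_nodes: int
    bins: BinScheme = field(default_factory=BinScheme)
    #: node rows holding peptide atoms; defaults to the first n_ligand_nodes
    ligand_rows: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_features)

    @property
    def peptide_rows(self) -> np.ndarray:
        if self.ligand_rows is not None:
            return self.ligand_rows
        return np.arange(self.n_ligand_nodes)

    def permuted(self, perm: np.ndarray) -> "MolecularGraph":
        """Graph with node rows relabeled by ``perm`` (new row k holds old row
        perm[k]); semantically identical, used to test invariances."""
        perm = np.asarray(perm, dtype=int)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return MolecularGraph(
            kind=self.kind,
            node_features=self.node_features[perm],
            atom_indices=self.atom_indices[perm],
            edges=inv[self.edges] if len(self.edges) else self.edges,
            distances=self.distances,
            bin_index=self.bin_index,
            weights=self.weights,
            n_ligand_nodes=self.n_ligand_nodes,
            bins=self.bins,
            ligand_rows=inv[self.peptide_rows],
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_per_bin(self) -> list[np.ndarray]:
        """Dense symmetric weighted adjacency, one matrix per distance bin."""
        mats = []
        n = self.n_nodes
        for b in range(self.bins.n_bins):
            a = np.zeros((n, n))
            sel = self.bin_index == b
            i, j = self.edges[sel, 0], self.edges[sel, 1]
            a[i, j] = self.weights[sel]
            a[j, i] = self.weights[sel]
            mats.append(a)
        return mats

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            kind=np.array(self.kind),
            node_features=self.node_features,
            atom_indices=self.atom_indices,
            edges=self.edges,
            distances=self.distances,
            bin_index=self.bin_index,
            weights=self.weights,
            n_ligand_nodes=np.array(self.n_ligand_nodes),
            bin_edges=np.array(self.bins.edges),
        )

    @classmethod
    def load(cls, path: str | Path) -> "MolecularGraph":
        with np.load(path) as z:
            return cls(
                kind=str(z["kind"]),
                node_features=z["node_features"],
                atom_indices=z["atom_indices"],
                edges=z["edges"],
                distances=z["distances"],
                bin_index=z["bin_index"],
                weights=z["weights"],
                n_ligand_nodes=int(z["n_ligand_nodes"]),
                bins=BinScheme(tuple(float(e) for e in z["bin_edges"])),
            )


# ---------------------------------------------------------------------------
# Covalent bond graph
# ---------------------------------------------------------------------------


def covalent_neighbors_within_two(structure: Structure) -> set[tuple[int, int]]:
    """Atom-index pairs (i < j, structure indexing) separated by <= 2 covalent
    bonds, from residue templates plus inter-residue peptide bonds."""
    arr = structure.to_atom_array()
    bonds = bst.connect_via_residue_names(arr)
    adj: dict[int, set[int]] = {}
    for i, j, _ in bonds.as_array():
        adj.setdefault(int(i), set()).add(int(j))
        adj.setdefault(int(j), set()).add(int(i))
    pairs: set[tuple[int, int]] = set()
    for i, nbrs in adj.items():
        for j in nbrs:  # 1-2
            if i < j:
                pairs.add((i, j))
            for k in adj.get(j, ()):  # 1-3
                if i < k:
                    pairs.add((i, k))
    return pairs


# ---------------------------------------------------------------------------
# Node features
# ---------------------------------------------------------------------------


def _node_features(structure: Structure, atom_indices: np.ndarray) -> np.ndarray:
    """Element one-hot over {C, N, O, S} + backbone flag + peptide-position scalar."""
    pep_chain = structure.chain_for_role("peptide")
    feats = np.zeros((len(atom_indices), len(NODE_ELEMENTS) + 2))
    for row, idx in enumerate(atom_indices):
        el = structure.element[idx]
        if el in NODE_ELEMENTS:
            feats[row, NODE_ELEMENTS.index(el)] = 1.0
        feats[row, len(NODE_ELEMENTS)] = float(structure.is_backbone[idx])
        if structure.chain_id[idx] == pep_chain:
            feats[row, len(NODE_ELEMENTS) + 1] = structure.residue_index[idx] / 9.0
    return feats


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def build_ll_graph(
    frame: Structure,
    cutoff: float = GLOBAL_CUTOFF,
    bins: BinScheme | None = None,
    d0: float = 1.5,
    sigma: float = 2.0,
) -> MolecularGraph:
    """Intramolecular peptide contact graph.

    Edges are peptide heavy-atom pairs with distance <= cutoff whose covalent
    separation is >= 3 bonds (1-2 and 1-3 pairs excluded).
    """
    bins = bins or BinScheme(_edges_for_cutoff(cutoff))
    pep = np.flatnonzero(frame.mask_role("peptide"))
    coords = frame.coords[pep]
    d = cdist(coords, coords)
    iu, ju = np.triu_indices(len(pep), k=1)
    keep = d[iu, ju] <= cutoff
    excluded = covalent_neighbors_within_two(frame)
    pairs = []
    for i, j in zip(iu[keep], ju[keep]):
        gi, gj = int(pep[i]), int(pep[j])
        if (min(gi, gj), max(gi, gj)) not in excluded:
            pairs.append((i, j))
    edges = np.array(pairs, dtype=int).reshape(-1, 2)
    dist = d[edges[:, 0], edges[:, 1]] if len(edges) else np.empty(0)
    return MolecularGraph(
        kind="LL",
        node_features=_node_features(frame, pep),
        atom_indices=pep,
        edges=edges,
        distances=dist,
        bin_index=bins.assign(dist) if len(edges) else np.empty(0, dtype=int),
        weights=edge_weight(dist, d0, sigma) if len(edges) else np.empty(0),
        n_ligand_nodes=len(pep),
        bins=bins,
    )


def build_lp_graph(
    frame: Structure,
    cutoff: float = GLOBAL_CUTOFF,
    bins: BinScheme | None = None,
    d0: float = 1.5,
    sigma: float = 2.0,
) -> MolecularGraph:
    """Intermolecular MHC-peptide contact graph: cross-molecule heavy-atom
    contacts only, no intramolecular edges of either molecule.

    Node rows are the peptide heavy atoms followed by the MHC heavy atoms that
    participate in at least one contact.
    """
    bins = bins or BinScheme(_edges_for_cutoff(cutoff))
    pep = np.flatnonzero(frame.mask_role("peptide"))
    mhc = np.flatnonzero(frame.mask_role("MHC_alpha"))
    d = cdist(frame.coords[pep], frame.coords[mhc])
    pi, mi = np.nonzero(d <= cutoff)
    used_mhc = np.unique(mi)
    mhc_row = {int(m): len(pep) + r for r, m in enumerate(used_mhc)}
    edges = np.array(
        [(int(p), mhc_row[int(m)]) for p, m in zip(pi, mi)], dtype=int
    ).reshape(-1, 2)
    dist = d[pi, mi]
    atom_indices = np.concatenate([pep, mhc[used_mhc]]).astype(int)
    return MolecularGraph(
        kind="LP",
        node_features=_node_features(frame, atom_indices),
        atom_indices=atom_indices,
        edges=edges,
        distances=dist,
        bin_index=bins.assign(dist) if len(edges) else np.empty(0, dtype=int),
        weights=edge_weight(dist, d0, sigma) if len(edges) else np.empty(0),
        n_ligand_nodes=len(pep),
        bins=bins,
    )


def _edges_for_cutoff(cutoff: float) -> tuple[float, ...]:
    if cutoff == GLOBAL_CUTOFF:
        return (2.5, 4.0, 6.0, 8.0)
    return tuple(np.linspace(cutoff / 4, cutoff, 4))


def graphs_for_trajectory(
    traj: Trajectory,
    stride: int = 1,
    cutoff: float = GLOBAL_CUTOFF,
    bins: BinScheme | None = None,
) -> Iterator[tuple[int, MolecularGraph, MolecularGraph]]:
    """(frame index, LL, LP) for production frames at the given stride.

    Frames within the equilibration window are excluded; raises if nothing
    survives.
    """
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    keep = np.flatnonzero(traj.production_mask())[::stride]
    if len(keep) == 0:
        raise ValidationError("no frames survive the equilibration exclusion")
    for i in keep:
        frame = traj.frame(int(i))
        yield int(i), build_ll_graph(frame, cutoff, bins), build_lp_graph(frame, cutoff, bins)
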