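"""Structure, trajectory and sequence-dataset IO.

Conventions used throughout the package:

* coordinates in Angstrom,
* residue indices 1-based within each chain (peptide positions P1..P9 map to
  residue_index 1..9 of the peptide chain),
* frame times in nanoseconds,
* hydrogens are parsed but flagged ``is_heavy = False`` and excluded from every
  distance, graph, SASA, RMSD and RMSF computation.

Structures are read and written as PDB through biotite; trajectories are
multi-model PDB (always accepted) or a simple ``.npz`` container holding the
frame stack and times (one binary dialect behind the same reader contract).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class StructureError(ValueError):
    """The file does not describe a usable MHC-peptide complex."""


class ValidationError(ValueError):
    """An invariant of the domain types is violated."""


class TopologyError(ValueError):
    """Trajectory frames do not match the supplied topology."""


class LabelError(ValueError):
    """Unknown immunogenicity label token."""


# ---------------------------------------------------------------------------
# van der Waals radii
# ---------------------------------------------------------------------------

with resources.files("mhcdyn.data").joinpath("vdw_radii.json").open() as _fh:
    VDW_RADII: dict[str, float] = {k.upper(): float(v) for k, v in json.load(_fh)["radii"].items()}


def vdw_radius(element: str) -> float:
    """Van der Waals radius (A) for an element symbol; raises for unknown elements."""
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise ValidationError(f"no van der Waals radius for element {element!r}") from None


BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
VALID_AA = frozenset(AA1_TO_3)

CHAIN_ROLES = ("MHC_alpha", "beta2m", "peptide")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """Single-atom view; ``Structure`` stores columns, this is a convenience row."""

    atom_name: str
    element: str
    residue_name: str
    residue_index: int  # 1-based within chain
    chain_id: str
    coords: np.ndarray  # (3,), Angstrom
    is_backbone: bool
    is_heavy: bool


class Structure:
    """Ordered atom table of one MHC-peptide complex with chain roles.

    Column arrays (all length ``n_atoms``): ``atom_name``, ``element``,
    ``residue_name``, ``residue_index`` (1-based within chain), ``chain_id``,
    ``coords`` (n, 3), ``is_backbone``, ``is_heavy``.
    """

    def __init__(
        self,
        atom_name: Sequence[str],
        element: Sequence[str],
        residue_name: Sequence[str],
        residue_index: Sequence[int],
        chain_id: Sequence[str],
        coords: np.ndarray,
        chains: Mapping[str, str],
    ):
        n = len(atom_name)
        self.atom_name = np.asarray(atom_name, dtype=object)
        self.element = np.asarray([e.upper() for e in element], dtype=object)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.residue_index = np.asarray(residue_index, dtype=int)
        self.chain_id = np.asarray(chain_id, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.chains = dict(chains)
        self.is_heavy = self.element != "H"
        self.is_backbone = np.isin(self.atom_name, sorted(BACKBONE_ATOMS))
        self._validate()

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        unknown = set(self.chains.values()) - set(CHAIN_ROLES)
        if unknown:
            raise ValidationError(f"unknown chain roles {sorted(unknown)}")
        present = set(self.chain_id.tolist())
        missing = present - set(self.chains)
        if missing:
            raise ValidationError(f"chains {sorted(missing)} present but have no role")
        peptide_chains = [c for c, r in self.chains.items() if r == "peptide"]
        if len(peptide_chains) != 1:
            raise StructureError(
                f"expected exactly one peptide chain, found {len(peptide_chains)}"
            )
        (pep,) = peptide_chains
        if pep not in present:
            raise StructureError(f"peptide chain {pep!r} has no atoms")
        n_res = len(np.unique(self.residue_index[self.chain_id == pep]))
        if n_res != 9:
            raise ValidationError(
                f"peptide chain {pep!r} has {n_res} residues; 9-mers are required"
            )
        for el in np.unique(self.element[self.is_heavy]):
            vdw_radius(el)  # raises if unresolvable

    # -- accessors ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(
                self.atom_name[i], self.element[i], self.residue_name[i],
                int(self.residue_index[i]), self.chain_id[i], self.coords[i],
                bool(self.is_backbone[i]), bool(self.is_heavy[i]),
            )
            for i in range(self.n_atoms)
        ]

    def chain_for_role(self, role: str) -> str:
        for cid, r in self.chains.items():
            if r == role:
                return cid
        raise StructureError(f"no chain with role {role!r}")

    def mask_role(self, role: str, heavy_only: bool = True) -> np.ndarray:
        m = self.chain_id == self.chain_for_role(role)
        return m & self.is_heavy if heavy_only else m

    @property
    def peptide_sequence(self) -> str:
        mask = self.mask_role("peptide", heavy_only=False)
        seq = []
        for ri in sorted(set(self.residue_index[mask])):
            name = self.residue_name[mask & (self.residue_index == ri)][0]
            seq.append(AA3_TO_1.get(name, "X"))
        return "".join(seq)

    def radii(self, mask: np.ndarray | None = None) -> np.ndarray:
        els = self.element if mask is None else self.element[mask]
        return np.array([vdw_radius(e) for e in els])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Shallow copy sharing annotations, replacing coordinates."""
        new = object.__new__(Structure)
        new.__dict__.update(self.__dict__)
        new.coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        return new

    # -- interop -----------------------------------------------------------

    def to_atom_array(self) -> bst.AtomArray:
        arr = bst.AtomArray(self.n_atoms)
        arr.coord = self.coords.astype(np.float32)
        arr.chain_id = self.chain_id.astype("U4")
        arr.res_id = self.residue_index
        arr.res_name = self.residue_name.astype("U5")
        arr.atom_name = self.atom_name.astype("U6")
        arr.element = self.element.astype("U2")
        arr.hetero = np.zeros(self.n_atoms, dtype=bool)
        return arr


@dataclass
class Trajectory:
    """Frame stack over a fixed topology; times in ns, strictly increasing."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    frame_times: np.ndarray  # ns
    equilibration_cutoff: float = 30.0  # ns, matching the training exclusion window

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] == 0:
            raise TopologyError("trajectory holds zero frames")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if len(self.frame_times) != len(self.frames):
            raise TopologyError("frame_times length mismatch")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")
        if len(self.frame_times) > 2:
            dt = np.diff(self.frame_times)
            if np.max(np.abs(dt - dt.mean())) > 1e-6 + 1e-3 * dt.mean():
                raise ValidationError("frame_times must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def production_mask(self) -> np.ndarray:
        """Frames past the equilibration cutoff."""
        return self.frame_times >= self.equilibration_cutoff


@dataclass(frozen=True)
class PeptideRecord:
    """A 9-mer with its binary immunogenicity label."""

    sequence: str
    label: str  # "immunogenic" | "non_immunogenic"
    source: str | None = None
    trajectory_ref: str | None = None

    def __post_init__(self):
        if len(self.sequence) != 9:
            raise ValidationError(
                f"sequence {self.sequence!r} has length {len(self.sequence)}, expected 9"
            )
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise ValidationError(f"invalid amino-acid letters {sorted(bad)} in {self.sequence!r}")
        if self.label not in ("immunogenic", "non_immunogenic"):
            raise LabelError(f"unknown label {self.label!r}")

    @property
    def is_immunogenic(self) -> bool:
        return self.label == "immunogenic"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def infer_chain_roles(chain_ids: Sequence[str], n_residues: Mapping[str, int]) -> dict[str, str]:
    """Default role inference: 9-residue chain -> peptide, longest -> MHC_alpha,
    remaining chains -> beta2m."""
    roles: dict[str, str] = {}
    nine = [c for c in chain_ids if n_residues[c] == 9]
    if len(nine) == 1:
        roles[nine[0]] = "peptide"
    rest = [c for c in chain_ids if c not in roles]
    if rest:
        longest = max(rest, key=lambda c: n_residues[c])
        roles[longest] = "MHC_alpha"
        for c in rest:
            if c != longest:
                roles[c] = "beta2m"
    return roles


def _atom_array_to_structure(arr: bst.AtomArray, chain_roles: Mapping[str, str] | None) -> Structure:
    if arr.array_length() == 0:
        raise StructureError("no ATOM records found")
    # re-number residues 1-based within each chain, preserving order
    res_index = np.empty(arr.array_length(), dtype=int)
    n_res: dict[str, int] = {}
    chain_order: list[str] = []
    for cid in arr.chain_id:
        if cid not in chain_order:
            chain_order.append(cid)
    for cid in chain_order:
        m = arr.chain_id == cid
        ids = arr.res_id[m]
        uniq = list(dict.fromkeys(ids.tolist()))
        remap = {r: i + 1 for i, r in enumerate(uniq)}
        res_index[m] = [remap[r] for r in ids]
        n_res[cid] = len(uniq)
    if chain_roles is None:
        chain_roles = infer_chain_roles(chain_order, n_res)
    missing = set(chain_order) - set(chain_roles)
    if missing:
        raise StructureError(f"chain_roles does not cover chains {sorted(missing)}")
    element = [e if e else "C" for e in arr.element]
    return Structure(
        atom_name=arr.atom_name.tolist(),
        element=element,
        residue_name=arr.res_name.tolist(),
        residue_index=res_index,
        chain_id=arr.chain_id.tolist(),
        coords=np.asarray(arr.coord, dtype=float),
        chains=dict(chain_roles),
    )


def read_structure(path: str | Path, chain_roles: Mapping[str, str] | None = None) -> Structure:
    """Read a PDB file into a validated :class:`Structure`.

    ``chain_roles`` maps chain id -> role in {MHC_alpha, beta2m, peptide}; if
    omitted, roles are inferred (longest chain -> MHC_alpha, 9-residue chain ->
    peptide).
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    arr = arr[~arr.hetero]
    return _atom_array_to_structure(arr, chain_roles)


def write_structure(structure: Structure, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(structure.to_atom_array())
    pdb.write(str(path))


def read_trajectory(
    topology: Structure,
    path: str | Path,
    frame_interval: float = 1.0,
    start_time: float = 0.0,
    equilibration_cutoff: float = 30.0,
) -> Trajectory:
    """Read a frame stack against ``topology``.

    Multi-model PDB is always accepted; a ``.npz`` container with arrays
    ``frames`` (n, n_atoms, 3) and optionally ``frame_times`` is the binary
    dialect. For PDB input, frame times are synthesised as
    ``start_time + i * frame_interval`` (ns).
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            frames = npz["frames"]
            if "frame_times" in npz:
                times = npz["frame_times"]
            else:
                times = start_time + frame_interval * np.arange(len(frames))
    else:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()
        if isinstance(stack, bst.AtomArray):  # single model
            stack = bst.stack([stack])
        frames = np.asarray(stack.coord, dtype=float)
        times = start_time + frame_interval * np.arange(len(frames))
    return Trajectory(topology, frames, times, equilibration_cutoff=equilibration_cutoff)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB or as the ``.npz`` dialect."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, frames=traj.frames, frame_times=traj.frame_times)
        return
    arr = traj.topology.to_atom_array()
    stack = bst.stack([arr] * traj.n_frames)
    stack.coord = traj.frames.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


_LABEL_TOKENS = {
    "immunogenic": "immunogenic", "non_immunogenic": "non_immunogenic",
    "imm": "immunogenic", "non": "non_immunogenic", "nonimmunogenic": "non_immunogenic",
    "1": "immunogenic", "0": "non_immunogenic",
    "true": "immunogenic", "false": "non_immunogenic",
}


def read_dataset(path: str | Path) -> list[PeptideRecord]:
    """Read a sequence/label CSV (columns ``sequence,label[,source,trajectory_ref]``).

    Rows are validated individually (9-mer sequences, known label tokens);
    duplicate sequences are reported through logging but retained.
    """
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    if "sequence" not in cols or "label" not in cols:
        raise ValidationError("dataset CSV needs at least columns 'sequence' and 'label'")
    records: list[PeptideRecord] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        raw = getattr(row, cols["sequence"])
        seq = str(raw).strip().upper()
        token = str(getattr(row, cols["label"])).strip().lower()
        if token not in _LABEL_TOKENS:
            raise LabelError(f"row {row_number}: unknown label token {token!r}")
        source = getattr(row, cols["source"], None) if "source" in cols else None
        tref = getattr(row, cols["trajectory_ref"], None) if "trajectory_ref" in cols else None
        try:
            rec = PeptideRecord(
                sequence=seq,
                label=_LABEL_TOKENS[token],
                source=None if pd.isna(source) else source,
                trajectory_ref=None if pd.isna(tref) else tref,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {row_number}: {exc}") from None
        records.append(rec)
    seqs = [r.sequence for r in records]
    n_dup = len(seqs) - len(set(seqs))
    if n_dup:
        logger.warning("dataset contains %d duplicate sequences (retained)", n_dup)
    return records


def write_dataset(records: Iterable[PeptideRecord], path: str | Path) -> None:
    records = list(records)
    df = pd.DataFrame({"sequence": [r.sequence for r in records]})
    df["label"] = [r.label for r in records]
    if any(r.source for r in records):
        df["source"] = [r.source or "" for r in records]
    if any(r.trajectory_ref for r in records):
        df["trajectory_ref"] = [r.trajectory_ref or "" for r in records]
    df.to_csv(path, index=False)
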