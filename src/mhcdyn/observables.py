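"""Per-frame and ensemble observables that separate immunogenicity classes.

Implements per-residue solvent-accessible surface area (Shrake-Rupley sphere
sampling with Bondi radii), the hydrophobic/hydrophilic SASA split, heavy-atom
peptide RMSD and per-position RMSF after superposition on the MHC binding
domain, anchor-pocket minimum distances at P2/P9, and two-sample class
statistics on window means and fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy import stats

from .io import Structure, Trajectory, ValidationError

# Hydrophobic residue set (one-letter); fixed default, overridable per call.
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWPG")

#: MHC-alpha heavy atoms within this distance (A) of the peptide in the
#: reference frame define the superposition frame of reference.
BINDING_DOMAIN_CUTOFF = 8.0


class SelectionError(ValueError):
    """An atom selection came up empty or otherwise unusable."""


class InsufficientDataError(ValueError):
    """Too few frames for the requested statistic."""


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere quadrature points."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Solvent-accessible surface area (A^2) per atom.

    Each atom's extended sphere (radius ``r_vdw + probe``) is integrated over
    ``n_points`` latitude bands; within a band the azimuthal arcs occluded by
    neighbouring spheres are resolved exactly as a union of intervals. This is
    a sharpened variant of Shrake-Rupley sphere sampling: the quadrature error
    comes only from the polar discretization, so per-residue values converge
    rapidly (and deterministically) in ``n_points``.
    """
    if n_points < 32:
        raise ValidationError("n_points must be >= 32 for a usable quadrature")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    ext = radii + probe_radius
    tree = cKDTree(coords)
    max_ext = ext.max()
    # midpoint rule in cos(theta): equal-area bands
    mu = 1.0 - (np.arange(n_points) + 0.5) * (2.0 / n_points)  # cos(theta) midpoints
    sin_t = np.sqrt(np.clip(1.0 - mu**2, 0.0, None))
    band_area_frac = 1.0 / n_points  # of the total 4*pi*R^2, per band
    out = np.empty(n)
    for i in range(n):
        neigh = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                 if j != i]
        if not neigh:
            out[i] = 4.0 * np.pi * ext[i] ** 2
            continue
        rel = coords[neigh] - coords[i]
        d = np.linalg.norm(rel, axis=1)
        close = d < ext[i] + ext[neigh]
        rel, dj, ej = rel[close], d[close], ext[np.asarray(neigh)][close]
        if len(dj) == 0:
            out[i] = 4.0 * np.pi * ext[i] ** 2
            continue
        # spherical-cap half-angle of each occluding neighbour
        cos_alpha = (dj**2 + ext[i] ** 2 - ej**2) / (2.0 * dj * ext[i])
        if np.any(cos_alpha <= -1.0):
            out[i] = 0.0  # engulfed by a neighbour
            continue
        keep = cos_alpha < 1.0
        if not keep.any():
            out[i] = 4.0 * np.pi * ext[i] ** 2
            continue
        cos_alpha = np.clip(cos_alpha[keep], -1.0, 1.0)
        u = rel[keep] / dj[keep, None]  # cap centre directions
        cos_tj = np.clip(u[:, 2], -1.0, 1.0)
        sin_tj = np.sqrt(np.clip(1.0 - cos_tj**2, 0.0, None))
        phi_j = np.arctan2(u[:, 1], u[:, 0])
        # blocked azimuthal half-width per (band, neighbour):
        # cos(alpha) = mu*cos_tj + sin*sin_tj*cos(dphi)
        denom = sin_t[:, None] * sin_tj[None, :]
        numer = cos_alpha[None, :] - mu[:, None] * cos_tj[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(denom > 0, numer / np.maximum(denom, 1e-300), np.inf)
        half = np.where(c <= -1.0, np.pi, np.where(c >= 1.0, 0.0, np.arccos(np.clip(c, -1, 1))))
        # degenerate bands at the poles: blocked entirely iff inside some cap
        pole = denom <= 0
        half[pole] = np.where(numer[pole] <= 0, np.pi, 0.0)
        exposed_frac = np.array(
            [_free_arc(phi_j[row > 0], row[row > 0]) for row in half]
        ) / (2.0 * np.pi)
        out[i] = 4.0 * np.pi * ext[i] ** 2 * band_area_frac * exposed_frac.sum()
    return out


def _free_arc(centers: np.ndarray, half_widths: np.ndarray) -> float:
    """Measure of the circle not covered by arcs [c - w, c + w] (radians)."""
    if len(centers) == 0:
        return 2.0 * np.pi
    if np.any(half_widths >= np.pi):
        return 0.0
    start = np.mod(centers - half_widths, 2.0 * np.pi)
    end = np.mod(centers + half_widths, 2.0 * np.pi)
    events = []
    for s, e in zip(start, end):
        if s <= e:
            events.append((s, e))
        else:  # wraps
            events.append((s, 2.0 * np.pi))
            events.append((0.0, e))
    events.sort()
    covered = 0.0
    cur_s, cur_e = events[0]
    for s, e in events[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return 2.0 * np.pi - covered


@dataclass
class ResidueSASA:
    """Per-residue SASA (A^2) for one frame, with the hydrophobic partition mask."""

    residue_index: np.ndarray  # 1-based
    residue_name: np.ndarray  # 3-letter codes
    values: np.ndarray  # A^2
    hydrophobic_mask: np.ndarray  # boolean per residue

    @property
    def total(self) -> float:
        return float(self.values.sum())


def residue_sasa(
    frame: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    chain_role: str | None = "peptide",
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_RESIDUES,
) -> ResidueSASA:
    """Per-residue SASA over full residues of one chain (default: the peptide).

    Occlusion is computed against every heavy atom in the complex; hydrogen
    atoms are ignored entirely. ``chain_role=None`` reports all residues.
    """
    from .io import AA3_TO_1  # local to avoid a cycle in type-only imports

    heavy = frame.is_heavy
    if not heavy.any():
        raise SelectionError("structure has no heavy atoms")
    per_atom = atom_sasa(frame.coords[heavy], frame.radii(heavy), probe_radius, n_points)
    chain_ids = frame.chain_id[heavy]
    res_idx = frame.residue_index[heavy]
    res_name = frame.residue_name[heavy]
    if chain_role is not None:
        cid = frame.chain_for_role(chain_role)
        sel = chain_ids == cid
    else:
        sel = np.ones(len(per_atom), dtype=bool)
    keys = list(dict.fromkeys(zip(chain_ids[sel], res_idx[sel])))
    values = np.empty(len(keys))
    names = []
    for k, (c, r) in enumerate(keys):
        m = sel & (chain_ids == c) & (res_idx == r)
        values[k] = per_atom[m].sum()
        names.append(res_name[m][0])
    one = np.array([AA3_TO_1.get(n, "X") for n in names])
    return ResidueSASA(
        residue_index=np.array([r for _, r in keys], dtype=int),
        residue_name=np.array(names, dtype=object),
        values=values,
        hydrophobic_mask=np.isin(one, sorted(hydrophobic_set)),
    )


def hydrophobic_split(sasa: ResidueSASA) -> tuple[float, float]:
    """(hydrophobic, hydrophilic) SASA; the two sum exactly to the total."""
    hydrophobic = float(sasa.values[sasa.hydrophobic_mask].sum())
    return hydrophobic, float(sasa.total - hydrophobic)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rotation/translation of ``mobile`` onto ``ref``.

    Returns (R, t, mobile_centroid) with the fit being
    ``(x - mobile_centroid) @ R + t``.
    """
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, d]) @ vt
    return r, rc, mc


def binding_domain_mask(reference: Structure, cutoff: float = BINDING_DOMAIN_CUTOFF) -> np.ndarray:
    """Heavy MHC-alpha atoms within ``cutoff`` of any peptide heavy atom."""
    mhc = reference.mask_role("MHC_alpha")
    pep = reference.mask_role("peptide")
    if not mhc.any() or not pep.any():
        raise SelectionError("binding-domain selection requires MHC_alpha and peptide atoms")
    tree = cKDTree(reference.coords[pep])
    d, _ = tree.query(reference.coords[mhc])
    mask = np.zeros(reference.n_atoms, dtype=bool)
    mask[np.flatnonzero(mhc)[d <= cutoff]] = True
    if not mask.any():
        raise SelectionError("no MHC_alpha atoms within the binding-domain cutoff")
    return mask


def superpose_frames(traj: Trajectory, reference: int = 0) -> np.ndarray:
    """All frames superposed onto ``reference`` by the MHC binding-domain fit."""
    fit = binding_domain_mask(traj.frame(reference))
    ref = traj.frames[reference][fit]
    out = np.empty_like(traj.frames)
    for i, x in enumerate(traj.frames):
        r, rc, mc = _kabsch(x[fit], ref)
        out[i] = (x - mc) @ r + rc
    return out


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------


def peptide_rmsd(traj: Trajectory, reference: int = 0) -> np.ndarray:
    """Per-frame heavy-atom RMSD (A) of the peptide after binding-domain superposition."""
    if not 0 <= reference < traj.n_frames:
        raise SelectionError(f"reference frame {reference} out of range")
    pep = traj.topology.mask_role("peptide")
    if not pep.any():
        raise SelectionError("no peptide heavy atoms")
    aligned = superpose_frames(traj, reference)
    diff = aligned[:, pep, :] - traj.frames[reference][pep]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


def rmsf(
    traj: Trajectory,
    selection: str = "backbone",
    group_by: str = "peptide_position",
) -> dict[int, float]:
    """Per-position RMSF (A) about the time-average structure.

    ``selection`` is ``backbone`` or ``sidechain`` (heavy atoms only);
    ``group_by`` is ``peptide_position`` (P1..P9 -> keys 1..9) or
    ``mhc_residue``. Positions with no atoms in the selection (e.g. glycine
    side chains) are reported as NaN. Only frames past the equilibration
    cutoff contribute.
    """
    if selection not in ("backbone", "sidechain"):
        raise SelectionError(f"unknown selection {selection!r}")
    if group_by not in ("peptide_position", "mhc_residue"):
        raise SelectionError(f"unknown group_by {group_by!r}")
    keep = traj.production_mask()
    if keep.sum() < 2:
        raise InsufficientDataError("need >= 2 frames past the equilibration cutoff")
    aligned = superpose_frames(traj, int(np.flatnonzero(keep)[0]))[keep]
    mean = aligned.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))

    topo = traj.topology
    role = "peptide" if group_by == "peptide_position" else "MHC_alpha"
    chain = topo.mask_role(role)
    sel = topo.is_backbone if selection == "backbone" else ~topo.is_backbone
    sel = chain & sel & topo.is_heavy
    out: dict[int, float] = {}
    for pos in sorted(set(topo.residue_index[chain])):
        m = sel & (topo.residue_index == pos)
        out[int(pos)] = float(np.mean(per_atom[m])) if m.any() else float("nan")
    return out


# ---------------------------------------------------------------------------
# Anchor distances
# ---------------------------------------------------------------------------

ANCHOR_POSITIONS = {"P2": 2, "P9": 9}


@dataclass
class AnchorDistanceSeries:
    """Per-frame minimum heavy-atom distance (A) from one anchor to the MHC alpha chain."""

    position: str  # "P2" | "P9"
    times: np.ndarray  # ns
    distances: np.ndarray  # A
    equilibration_cutoff: float = 30.0

    def window_stats(self, window: tuple[float, float] | None = None) -> tuple[float, float]:
        """(mean, SD) over the window (default: everything past equilibration)."""
        if window is None:
            m = self.times >= self.equilibration_cutoff
        else:
            m = (self.times >= window[0]) & (self.times <= window[1])
        if not m.any():
            raise InsufficientDataError("window selects no frames")
        vals = self.distances[m]
        return float(vals.mean()), float(vals.std(ddof=1)) if m.sum() > 1 else 0.0


def anchor_min_distance(traj: Trajectory, position: str = "P9") -> AnchorDistanceSeries:
    """Per-frame minimum over all (anchor heavy atom, MHC-alpha heavy atom) pairs."""
    if position not in ANCHOR_POSITIONS:
        raise SelectionError(f"position must be P2 or P9, got {position!r}")
    topo = traj.topology
    pep = topo.mask_role("peptide")
    anchor = pep & (topo.residue_index == ANCHOR_POSITIONS[position])
    mhc = topo.mask_role("MHC_alpha")
    if not anchor.any() or not mhc.any():
        raise SelectionError("anchor or MHC_alpha selection is empty")
    a = traj.frames[:, anchor, :]
    b = traj.frames[:, mhc, :]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=3)
    return AnchorDistanceSeries(
        position=position,
        times=traj.frame_times.copy(),
        distances=d.min(axis=(1, 2)),
        equilibration_cutoff=traj.equilibration_cutoff,
    )


# ---------------------------------------------------------------------------
# Class statistics
# ---------------------------------------------------------------------------


class ClassError(ValueError):
    """Both immunogenicity classes are required."""


def class_compare(
    series_by_peptide: Mapping[str, AnchorDistanceSeries],
    labels: Mapping[str, str],
    window: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Compare per-peptide window means and SDs between immunogenicity classes.

    Returns ``mean_gap`` and ``sd_gap`` (immunogenic minus non-immunogenic, A)
    and Welch two-sample two-sided p-values ``p_mean`` and ``p_sd``.
    """
    means: dict[str, list[float]] = {"immunogenic": [], "non_immunogenic": []}
    sds: dict[str, list[float]] = {"immunogenic": [], "non_immunogenic": []}
    for pid, series in series_by_peptide.items():
        lab = labels[pid]
        if lab not in means:
            raise ClassError(f"unknown label {lab!r} for peptide {pid!r}")
        m, s = series.window_stats(window)
        means[lab].append(m)
        sds[lab].append(s)
    if not means["immunogenic"] or not means["non_immunogenic"]:
        raise ClassError("both classes must be non-empty")
    mi, mn = np.array(means["immunogenic"]), np.array(means["non_immunogenic"])
    si, sn = np.array(sds["immunogenic"]), np.array(sds["non_immunogenic"])
    p_mean = stats.ttest_ind(mi, mn, equal_var=False).pvalue
    p_sd = stats.ttest_ind(si, sn, equal_var=False).pvalue
    return {
        "mean_gap": float(mi.mean() - mn.mean()),
        "sd_gap": float(si.mean() - sn.mean()),
        "p_mean": float(p_mean),
        "p_sd": float(p_sd),
    }
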