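"""Markov-state-model stack for MHC-peptide trajectory ensembles.

The pipeline mirrors common MSM practice: backbone-dihedral featurization
(sin/cos of phi and psi), time-lagged independent component analysis (tICA),
k-means discretization of the projected coordinates, a reversible
maximum-likelihood transition-matrix estimate at a fixed lag, and spectral
analysis (implied timescales, eigenvector modes, propagation, and
population-weighted state observables).

Defaults mirror the production-scale protocol (k = 3000 states, 25 ns lag)
but shrink automatically, with a warning, when a dataset is too small to
support them, since desk-scale tests run on toy systems.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .io import Structure, Trajectory, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_STATES = 3000
DEFAULT_LAG_NS = 25.0


class LagError(ValueError):
    """Lag time incompatible with trajectory length."""


class ConnectivityError(ValueError):
    """No usable strongly connected set of states."""


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------


def _dihedral(p0, p1, p2, p3):
    """Signed dihedral angle (rad), IUPAC convention, for stacked arrays (..., 3)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1_hat = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b1_hat, axis=-1)
    return np.arctan2(y, x)


@dataclass
class FeatureSeries:
    """Per-frame sin/cos of backbone dihedrals; all entries in [-1, 1]."""

    values: np.ndarray  # (n_frames, n_features)
    angle_labels: list[str]
    source: str | None = None

    @property
    def n_frames(self) -> int:
        return len(self.values)


def backbone_dihedrals(traj: Trajectory, scope: str = "peptide") -> tuple[np.ndarray, list[str]]:
    """Phi/psi angles (rad) per frame for the chosen scope.

    Chain-terminal angles that are undefined (phi of the first residue, psi of
    the last) are omitted consistently, so a 9-mer peptide yields 8 phi + 8 psi.
    """
    topo = traj.topology
    if scope == "peptide":
        chains = [topo.chain_for_role("peptide")]
    elif scope == "complex":
        chains = list(topo.chains)
    else:
        raise ValidationError(f"unknown scope {scope!r}")

    angles = []
    labels = []
    for cid in chains:
        cmask = topo.chain_id == cid
        residues = sorted(set(topo.residue_index[cmask]))
        if len(residues) < 3:
            raise ValidationError(f"scope selects < 3 residues in chain {cid!r}")

        def atom_idx(res, name):
            m = cmask & (topo.residue_index == res) & (topo.atom_name == name)
            idx = np.flatnonzero(m)
            return int(idx[0]) if len(idx) else None

        for k, res in enumerate(residues):
            n_i, ca_i, c_i = (atom_idx(res, a) for a in ("N", "CA", "C"))
            if None in (n_i, ca_i, c_i):
                continue
            if k > 0:  # phi: C(i-1), N, CA, C
                c_prev = atom_idx(residues[k - 1], "C")
                if c_prev is not None:
                    angles.append(
                        _dihedral(
                            traj.frames[:, c_prev], traj.frames[:, n_i],
                            traj.frames[:, ca_i], traj.frames[:, c_i],
                        )
                    )
                    labels.append(f"{cid}:phi{res}")
            if k < len(residues) - 1:  # psi: N, CA, C, N(i+1)
                n_next = atom_idx(residues[k + 1], "N")
                if n_next is not None:
                    angles.append(
                        _dihedral(
                            traj.frames[:, n_i], traj.frames[:, ca_i],
                            traj.frames[:, c_i], traj.frames[:, n_next],
                        )
                    )
                    labels.append(f"{cid}:psi{res}")
    return np.stack(angles, axis=1), labels


def featurize_dihedrals(traj: Trajectory, scope: str = "peptide") -> FeatureSeries:
    """Sin/cos pairs of each defined phi/psi angle, per frame."""
    ang, labels = backbone_dihedrals(traj, scope)
    values = np.concatenate([np.sin(ang), np.cos(ang)], axis=1)
    return FeatureSeries(values=values, angle_labels=labels)


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------


@dataclass
class TICAModel:
    """Solution of the generalized eigenproblem C(tau) v = lambda C(0) v."""

    lag: int  # frames
    eigenvalues: np.ndarray  # descending
    components: np.ndarray  # (n_features, n_components), columns are tICs
    mean: np.ndarray
    n_components: int
    regularization: float = 1e-10

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x) - self.mean) @ self.components

    def timescales(self, dt: float = 1.0) -> np.ndarray:
        """Relaxation timescales -lag*dt / ln|lambda| (same unit as dt per frame)."""
        lam = np.abs(self.eigenvalues)
        with np.errstate(divide="ignore"):
            return np.where(lam < 1.0, -self.lag * dt / np.log(lam), np.inf)


def _tica_covariances(series: list[np.ndarray], lag: int):
    """Mean-free instantaneous and symmetrized time-lagged covariances."""
    blocks_0, blocks_t = [], []
    for x in series:
        if len(x) <= lag:
            raise LagError(f"series of length {len(x)} <= lag {lag}")
        blocks_0.append(x[:-lag])
        blocks_t.append(x[lag:])
    x0 = np.concatenate(blocks_0, axis=0)
    xt = np.concatenate(blocks_t, axis=0)
    mean = np.concatenate([x0, xt], axis=0).mean(axis=0)
    x0 = x0 - mean
    xt = xt - mean
    n = len(x0)
    c0 = (x0.T @ x0 + xt.T @ xt) / (2.0 * n)
    ct = x0.T @ xt / n
    ct = 0.5 * (ct + ct.T)
    return c0, ct, mean


def fit_tica(
    features: Sequence[FeatureSeries] | Sequence[np.ndarray],
    lag: int,
    n_components: int = 5,
    regularization: float = 1e-10,
) -> TICAModel:
    """Fit tICA on one or more feature series.

    Covariances are estimated mean-free with the symmetrized (reversible)
    estimator; a shrinkage term ``regularization * I`` keeps the instantaneous
    covariance positive definite (applied and logged when needed).
    """
    series = [f.values if isinstance(f, FeatureSeries) else np.asarray(f, float) for f in features]
    if not series:
        raise ValidationError("no feature series supplied")
    dims = {s.shape[1] if s.ndim > 1 else 1 for s in series}
    if len(dims) != 1:
        raise ValidationError("feature series have inconsistent dimensions")
    series = [s.reshape(len(s), -1) for s in series]
    c0, ct, mean = _tica_covariances(series, lag)
    dim = c0.shape[0]
    cond = np.linalg.cond(c0)
    if cond > 1e12:
        logger.warning("singular instantaneous covariance (cond=%.2e); regularizing", cond)
    c0r = c0 + regularization * np.eye(dim)
    evals, evecs = linalg.eigh(ct, c0r)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    n_components = min(n_components, dim)
    return TICAModel(
        lag=lag,
        eigenvalues=evals[:n_components],
        components=evecs[:, :n_components],
        mean=mean,
        n_components=n_components,
        regularization=regularization,
    )


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


@dataclass
class StateDecomposition:
    """k-means microstates in tIC space with per-frame labels."""

    centers: np.ndarray  # (k, n_tics)
    dtrajs: list[np.ndarray]  # per-trajectory integer labels
    populations: np.ndarray  # empirical, sums to 1

    @property
    def n_states(self) -> int:
        return len(self.centers)

    def assign(self, x: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(x[:, None, :] - self.centers[None, :, :], axis=2)
        return d.argmin(axis=1)


def cluster_kmeans(
    projected: Sequence[np.ndarray],
    k: int = DEFAULT_N_STATES,
    seed: int = 0,
) -> StateDecomposition:
    """k-means++ discretization of projected coordinates.

    ``k`` shrinks (with a warning) to the number of available samples when the
    data cannot support the requested state count.
    """
    series = [np.asarray(p, float).reshape(len(p), -1) for p in projected]
    x = np.concatenate(series, axis=0)
    if len(x) < k:
        warnings.warn(
            f"requested k={k} exceeds n_samples={len(x)}; shrinking k", stacklevel=2
        )
        k = len(x)
    if k < 1:
        raise ValidationError("no samples to cluster")
    km = KMeans(n_clusters=k, init="k-means++", n_init=5, max_iter=500, tol=1e-6,
                random_state=seed)
    labels = km.fit_predict(x)
    dtrajs = []
    off = 0
    for s in series:
        dtrajs.append(labels[off : off + len(s)].astype(int))
        off += len(s)
    pops = np.bincount(labels, minlength=k).astype(float)
    return StateDecomposition(centers=km.cluster_centers_, dtrajs=dtrajs,
                              populations=pops / pops.sum())


# ---------------------------------------------------------------------------
# Counting and reversible estimation
# ---------------------------------------------------------------------------


def count_matrix(dtrajs: Sequence[np.ndarray], lag: int, k: int | None = None) -> np.ndarray:
    """Sliding-window transition counts at the given lag.

    Counts never cross trajectory boundaries; C sums to sum_i (len_i - lag).
    """
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    if k is None:
        k = int(max(d.max() for d in dtrajs)) + 1
    if any(d.max() >= k for d in dtrajs):
        raise ValidationError("state label >= k")
    if lag < 1:
        raise LagError("lag must be >= 1")
    if all(len(d) <= lag for d in dtrajs):
        raise LagError(f"lag {lag} >= every trajectory length")
    c = np.zeros((k, k))
    for d in dtrajs:
        if len(d) <= lag:
            continue
        np.add.at(c, (d[:-lag], d[lag:]), 1.0)
    return c


def largest_connected_set(counts: np.ndarray) -> np.ndarray:
    """States in the largest strongly connected component of the count graph."""
    graph = csr_matrix((counts > 0).astype(int))
    n_comp, assignment = connected_components(graph, directed=True, connection="strong")
    if n_comp == 0 or counts.sum() == 0:
        raise ConnectivityError("empty count matrix")
    sizes = np.array([
        counts[np.ix_(assignment == i, assignment == i)].sum() for i in range(n_comp)
    ])
    return np.flatnonzero(assignment == sizes.argmax())


@dataclass
class MarkovModel:
    """Reversible Markov model at a fixed lag time.

    ``transition_matrix`` is row-stochastic over the active (ergodically
    trimmed) state set; ``active_set`` maps active indices back to the original
    state labels. Detailed balance pi_i T_ij = pi_j T_ji holds by construction.
    """

    lag_time: float  # ns
    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    active_set: np.ndarray
    counts: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return len(self.transition_matrix)

    # eigen-decomposition in the pi-weighted (symmetrized) form; cached
    def _spectrum(self):
        if not hasattr(self, "_spec"):
            pi = self.stationary_distribution
            sqrt_pi = np.sqrt(pi)
            sym = self.transition_matrix * (sqrt_pi[:, None] / sqrt_pi[None, :])
            sym = 0.5 * (sym + sym.T)
            evals, evecs = np.linalg.eigh(sym)
            order = np.argsort(evals)[::-1]
            self._spec = (evals[order], evecs[:, order], sqrt_pi)
        return self._spec

    @property
    def eigenvalues(self) -> np.ndarray:
        return self._spectrum()[0]

    def right_eigenvector(self, index: int) -> np.ndarray:
        """Right eigenvector u_index (1-based; index 1 is the stationary mode),
        normalized in the pi-weighted inner product."""
        evals, evecs, sqrt_pi = self._spectrum()
        u = evecs[:, index - 1] / sqrt_pi
        return u / np.sqrt(np.sum(self.stationary_distribution * u * u))


def estimate_reversible(
    counts: np.ndarray,
    lag_time: float = DEFAULT_LAG_NS,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> MarkovModel:
    """Reversible maximum-likelihood transition matrix from transition counts.

    Counts are first trimmed to the largest strongly connected component; the
    detailed-balance-constrained likelihood is then maximized by the standard
    self-consistent fixed-point iteration on the symmetric flux matrix
    x_ij = x_ji, with T_ij = x_ij / x_i and pi_i = x_i / sum(x).
    """
    counts = np.asarray(counts, dtype=float)
    active = largest_connected_set(counts)
    c = counts[np.ix_(active, active)]
    c_row = c.sum(axis=1)
    c_sym = c + c.T
    x = c_sym.copy()  # symmetric start
    x_row = x.sum(axis=1)
    for _ in range(max_iter):
        denom = (c_row / x_row)[:, None] + (c_row / x_row)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = np.where(c_sym > 0, c_sym / denom, 0.0)
        x_new_row = x_new.sum(axis=1)
        rel = np.max(np.abs(x_new_row - x_row) / np.maximum(x_new_row, 1e-300))
        x, x_row = x_new, x_new_row
        if rel < tol:
            break
    t = x / x_row[:, None]
    pi = x_row / x_row.sum()
    return MarkovModel(
        lag_time=lag_time,
        transition_matrix=t,
        stationary_distribution=pi,
        active_set=active,
        counts=c,
    )


# ---------------------------------------------------------------------------
# Spectral analysis
# ---------------------------------------------------------------------------


def implied_timescales(model: MarkovModel, n: int = 5) -> np.ndarray:
    """Slowest ``n`` implied timescales t_i = -tau / ln(lambda_i), i >= 2.

    Negative eigenvalues have no real timescale; those entries are NaN with a
    warning.
    """
    evals = model.eigenvalues
    n = min(n, model.n_states - 1)
    out = np.full(n, np.nan)
    for j in range(n):
        lam = evals[j + 1]
        if lam <= 0:
            warnings.warn(f"eigenvalue {j + 2} is non-positive; timescale undefined",
                          stacklevel=2)
        elif lam < 1.0:
            out[j] = -model.lag_time / np.log(lam)
        else:
            out[j] = np.inf
    return out


def propagate(model: MarkovModel, p0: np.ndarray, steps: int) -> np.ndarray:
    """Distribution series p_n = p0 T^n, shape (steps + 1, n_states)."""
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (model.n_states,):
        raise ValidationError("p0 must live on the active state set")
    if abs(p0.sum() - 1.0) > 1e-8:
        raise ValidationError("p0 must sum to 1")
    out = np.empty((steps + 1, model.n_states))
    out[0] = p0
    for i in range(steps):
        out[i + 1] = out[i] @ model.transition_matrix
    return out


def weighted_observable(
    model: MarkovModel, values: np.ndarray, top_m: int | None = None
) -> np.ndarray | float:
    """Population-weighted average of per-state values over the ``top_m``
    most-populated states (weights renormalized over those states)."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != model.n_states:
        raise ValidationError("per-state values must match the active set")
    pi = model.stationary_distribution
    if top_m is None:
        top_m = model.n_states
    if top_m > model.n_states:
        raise ValidationError(f"top_m={top_m} exceeds n_states={model.n_states}")
    top = np.argsort(pi)[::-1][:top_m]
    w = pi[top] / pi[top].sum()
    result = np.tensordot(w, values[top], axes=(0, 0))
    return float(result) if np.ndim(result) == 0 else result


def eigenvector_modes(
    model: MarkovModel, index: int, n_top: int = 5
) -> dict[str, np.ndarray]:
    """Signed weights of the ``index``-th right eigenvector (index >= 2) and the
    states with extreme positive/negative components — the two conformational
    sets that interchange on that mode's timescale."""
    if index < 2:
        raise ValidationError("mode index must be >= 2 (index 1 is stationary)")
    u = model.right_eigenvector(index)
    order = np.argsort(u)
    return {
        "weights": u,
        "top_positive": order[::-1][:n_top],
        "top_negative": order[:n_top],
    }


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------


@dataclass
class MSMPipelineResult:
    features: list[FeatureSeries]
    tica: TICAModel
    decomposition: StateDecomposition
    model: MarkovModel
    lag_frames: int


def build_msm(
    trajectories: Sequence[Trajectory],
    scope: str = "peptide",
    tica_lag: int | None = None,
    n_tics: int = 5,
    n_states: int = DEFAULT_N_STATES,
    lag_time: float = DEFAULT_LAG_NS,
    seed: int = 0,
) -> MSMPipelineResult:
    """Full featurize -> tICA -> k-means -> reversible MLE pipeline.

    ``lag_time`` (ns) is converted to frames from the trajectory spacing; both
    the state count and the lags shrink with warnings when the data are small.
    """
    feats = [featurize_dihedrals(t, scope) for t in trajectories]
    dt = float(np.mean(np.diff(trajectories[0].frame_times)))
    lag_frames = max(1, int(round(lag_time / dt)))
    shortest = min(f.n_frames for f in feats)
    if lag_frames >= shortest:
        warnings.warn(
            f"lag of {lag_frames} frames >= shortest trajectory ({shortest}); shrinking",
            stacklevel=2,
        )
        lag_frames = max(1, shortest // 4)
    if tica_lag is None:
        tica_lag = lag_frames
    tica = fit_tica([f.values for f in feats], lag=tica_lag, n_components=n_tics)
    projected = [tica.transform(f.values) for f in feats]
    decomp = cluster_kmeans(projected, k=n_states, seed=seed)
    c = count_matrix(decomp.dtrajs, lag=lag_frames, k=decomp.n_states)
    model = estimate_reversible(c, lag_time=lag_frames * dt)
    return MSMPipelineResult(feats, tica, decomp, model, lag_frames)
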