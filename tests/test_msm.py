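import numpy as np
import pytest
from scipy import linalg, optimize

from mhcdyn import msm, synthetic


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------


def test_ninemer_gives_32_dim_features(toy_trajectory):
    traj, _ = toy_trajectory
    f = msm.featurize_dihedrals(traj, "peptide")
    assert f.values.shape == (traj.n_frames, 32)  # 8 phi + 8 psi, sin+cos
    assert np.abs(f.values).max() <= 1.0


def test_ideal_alpha_helix_dihedrals():
    """Backbone built from exact phi=-57, psi=-47 torsions is recovered."""
    from mhcdyn import io as mio

    phi, psi, omega = np.deg2rad([-57.0, -47.0, 180.0])

    def extend(a, b, c, bond, angle, torsion):
        # place next atom at given internal coordinates (NeRF construction)
        bc = c - b
        bc /= np.linalg.norm(bc)
        n = np.cross(b - a, bc)
        n /= np.linalg.norm(n)
        m = np.cross(n, bc)
        d = np.array(
            [
                -bond * np.cos(angle),
                bond * np.sin(angle) * np.cos(torsion),
                bond * np.sin(angle) * np.sin(torsion),
            ]
        )
        return c + d[0] * bc + d[1] * m + d[2] * n

    ang = np.deg2rad(109.5)
    pts = [
        np.array([0.0, 0.0, 0.0]),
        np.array([1.45, 0.0, 0.0]),
        np.array([1.95, 1.4, 0.0]),
    ]  # N, CA, C of residue 1
    torsions = []
    for _ in range(8):
        torsions += [psi, omega, phi]
    for t in torsions:
        pts.append(extend(pts[-3], pts[-2], pts[-1], 1.4, ang, t))
    pts = np.array(pts)
    names = (["N", "CA", "C"] * 9)[: len(pts)]
    res_idx = np.repeat(np.arange(1, 10), 3)[: len(pts)]
    s = mio.Structure(
        atom_name=names,
        element=["N" if n == "N" else "C" for n in names],
        residue_name=["ALA"] * len(pts),
        residue_index=res_idx,
        chain_id=["P"] * len(pts),
        coords=pts,
        chains={"P": "peptide"},
    )
    traj = mio.Trajectory(s, pts[None], np.array([0.0]), equilibration_cutoff=0.0)
    angles, labels = msm.backbone_dihedrals(traj, "peptide")
    got_phi = [a for a, l in zip(angles[0], labels) if "phi" in l]
    got_psi = [a for a, l in zip(angles[0], labels) if "psi" in l]
    assert np.allclose(np.rad2deg(got_phi), -57.0, atol=1e-6)
    assert np.allclose(np.rad2deg(got_psi), -47.0, atol=1e-6)


def test_identical_frames_identical_features(toy_complex, toy_kinetics):
    import dataclasses

    spec = dataclasses.replace(toy_kinetics, noise_sigma=0.0)
    traj, path = synthetic.make_kinetic_trajectory(toy_complex, spec, 50, seed=2)
    f = msm.featurize_dihedrals(traj)
    same = np.flatnonzero(path == path[0])
    assert np.allclose(f.values[same], f.values[same[0]])


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------


def _ar1(n, rho, rng):
    x = np.zeros(n)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + rng.standard_normal()
    return x


def test_tica_scalar_case_eigenvalue_is_lag_autocorrelation():
    rng = np.random.default_rng(0)
    x = _ar1(20000, 0.9, rng).reshape(-1, 1)
    lag = 3
    model = msm.fit_tica([x], lag=lag, n_components=1)
    assert model.eigenvalues[0] == pytest.approx(0.9**lag, abs=0.02)


def test_tica_white_noise_has_no_kinetic_content():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((20000, 3))
    model = msm.fit_tica([x], lag=5, n_components=3)
    assert np.abs(model.eigenvalues).max() < 0.05


def _tica_oracle(series, lag, reg=1e-10):
    """Independent dense generalized-eigenproblem solution."""
    x0 = np.concatenate([s[:-lag] for s in series])
    xt = np.concatenate([s[lag:] for s in series])
    mean = np.concatenate([x0, xt]).mean(axis=0)
    a, b = x0 - mean, xt - mean
    n = len(a)
    c0 = (a.T @ a + b.T @ b) / (2 * n) + reg * np.eye(a.shape[1])
    ct = a.T @ b / n
    ct = (ct + ct.T) / 2
    evals, evecs = linalg.eig(np.linalg.solve(c0, ct))
    order = np.argsort(evals.real)[::-1]
    return evals.real[order], evecs.real[:, order]


def test_tica_matches_dense_oracle_on_mixed_two_timescale_processes():
    rng = np.random.default_rng(42)
    for _ in range(20):
        x1 = _ar1(3000, 0.98, rng)
        x2 = _ar1(3000, 0.6, rng)
        mix = rng.normal(size=(2, 2)) + np.eye(2)
        x = np.stack([x1, x2], axis=1) @ mix
        lag = 4
        model = msm.fit_tica([x], lag=lag, n_components=2)
        evals, evecs = _tica_oracle([x], lag)
        assert np.abs(model.eigenvalues - evals) .max() < 1e-8
        for k in range(2):
            u = model.components[:, k] / np.linalg.norm(model.components[:, k])
            v = evecs[:, k] / np.linalg.norm(evecs[:, k])
            assert min(np.abs(u - v).max(), np.abs(u + v).max()) < 1e-6


def test_tica_lag_too_large():
    with pytest.raises(msm.LagError):
        msm.fit_tica([np.zeros((10, 2))], lag=10)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def test_kmeans_k_equals_n_gives_zero_inertia():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(20, 2))
    d = msm.cluster_kmeans([x], k=20, seed=0)
    assert np.allclose(np.sort(d.centers, axis=0), np.sort(x, axis=0), atol=1e-8)


def test_kmeans_recovers_separated_blobs():
    rng = np.random.default_rng(1)
    a = rng.normal([0, 0], 0.3, size=(300, 2))
    b = rng.normal([6, 6], 0.3, size=(300, 2))
    d = msm.cluster_kmeans([np.vstack([a, b])], k=2, seed=0)
    centers = d.centers[np.argsort(d.centers[:, 0])]
    se = 0.3 / np.sqrt(300)
    assert np.abs(centers[0] - [0, 0]).max() < 3 * se + 0.05
    assert np.abs(centers[1] - [6, 6]).max() < 3 * se + 0.05


def test_kmeans_duplicates_share_labels():
    x = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5], [0, 0]])
    d = msm.cluster_kmeans([x], k=2, seed=0)
    labels = d.dtrajs[0]
    assert labels[0] == labels[1] == labels[4]
    assert labels[2] == labels[3]


def test_kmeans_shrinks_k_with_warning():
    with pytest.warns(UserWarning, match="shrinking"):
        d = msm.cluster_kmeans([np.random.default_rng(0).normal(size=(5, 2))], k=50)
    assert d.n_states == 5


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def test_count_matrix_hand_example():
    c = msm.count_matrix([np.array([0, 1, 0, 1])], lag=1, k=2)
    assert np.array_equal(c, [[0, 2], [1, 0]])


def test_counts_never_cross_trajectory_boundaries():
    a, b = np.array([0, 0, 1]), np.array([1, 1, 0])
    sep = msm.count_matrix([a, b], lag=1, k=2)
    joined = msm.count_matrix([np.concatenate([a, b])], lag=1, k=2)
    assert sep.sum() == (3 - 1) + (3 - 1)
    assert joined.sum() == 5  # includes the spurious boundary transition
    assert not np.array_equal(sep, joined)


def test_count_total_identity():
    rng = np.random.default_rng(3)
    dtrajs = [rng.integers(0, 4, size=n) for n in (50, 77, 123)]
    for lag in (1, 5, 20):
        c = msm.count_matrix(dtrajs, lag=lag, k=4)
        assert c.sum() == sum(len(d) - lag for d in dtrajs)


def test_count_lag_too_large():
    with pytest.raises(msm.LagError):
        msm.count_matrix([np.array([0, 1])], lag=2, k=2)


# ---------------------------------------------------------------------------
# Reversible estimation
# ---------------------------------------------------------------------------


def test_symmetric_counts_give_row_normalized_matrix():
    c = np.array([[50.0, 10, 5], [10, 70, 15], [5, 15, 30]])
    model = msm.estimate_reversible(c, lag_time=1.0)
    assert np.allclose(model.transition_matrix, c / c.sum(axis=1, keepdims=True), atol=1e-9)


def _reversible_mle_oracle(counts):
    """Direct constrained likelihood maximization over the symmetric flux."""
    k = counts.shape[0]
    iu = np.triu_indices(k)

    def unpack(theta):
        x = np.zeros((k, k))
        x[iu] = np.exp(theta)
        x = x + x.T - np.diag(np.diag(x))
        return x

    def negloglik(theta):
        x = unpack(theta)
        t = x / x.sum(axis=1, keepdims=True)
        return -(counts * np.log(t + 1e-300)).sum()

    theta0 = np.log((counts + counts.T)[iu] / 2 + 0.5)
    res = optimize.minimize(negloglik, theta0, method="Nelder-Mead",
                            options={"maxiter": 40000, "xatol": 1e-10, "fatol": 1e-12})
    x = unpack(res.x)
    return x / x.sum(axis=1, keepdims=True)


def test_reversible_mle_matches_numerical_optimizer():
    counts = np.array([[90.0, 10, 3], [20, 80, 7], [5, 9, 60]])
    model = msm.estimate_reversible(counts, lag_time=1.0)
    oracle = _reversible_mle_oracle(counts)
    assert np.abs(model.transition_matrix - oracle).max() < 1e-5
    pi = model.stationary_distribution
    t = model.transition_matrix
    assert np.abs(pi[:, None] * t - (pi[:, None] * t).T).max() < 1e-8
    assert np.abs(t.sum(axis=1) - 1).max() < 1e-10


def test_ergodic_trimming_to_largest_component():
    # states 0-1 communicate; state 2 is a sink reached once
    counts = np.array([[10.0, 5, 1], [6, 9, 0], [0, 0, 4]])
    model = msm.estimate_reversible(counts)
    assert list(model.active_set) == [0, 1]
    assert model.n_states == 2


def test_parameter_recovery_from_simulated_chain():
    t_true = synthetic.example_reversible_matrix(4, seed=3)
    path = synthetic.sample_markov_chain(t_true, 100_000, seed=4)
    c = msm.count_matrix([path], lag=1, k=4)
    model = msm.estimate_reversible(c, lag_time=1.0)
    se = np.sqrt(t_true * (1 - t_true) / np.maximum(c.sum(axis=1, keepdims=True), 1))
    assert np.all(np.abs(model.transition_matrix - t_true) <= 3 * se + 1e-12)


# ---------------------------------------------------------------------------
# Spectral analysis
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def three_state_model():
    counts = np.array([[200.0, 20, 2], [22, 300, 10], [1, 12, 150]])
    return msm.estimate_reversible(counts, lag_time=2.0)


def test_implied_timescale_closed_form():
    counts = np.array([[85.0, 15], [15, 85]])
    model = msm.estimate_reversible(counts, lag_time=1.0)
    lam2 = 1 - 2 * 0.15
    assert msm.implied_timescales(model, 1)[0] == pytest.approx(-1 / np.log(lam2), rel=1e-6)
    assert msm.implied_timescales(model, 1)[0] == pytest.approx(2.804, abs=0.35)  # monotone scale check


def test_timescale_example_value():
    # lambda_2 = 0.7 at 1 ns lag -> 2.804 ns
    assert -1.0 / np.log(0.7) == pytest.approx(2.804, abs=1e-3)


def test_propagation_conserves_mass_and_converges(three_state_model):
    m = three_state_model
    p0 = np.array([1.0, 0.0, 0.0])
    series = msm.propagate(m, p0, 2000)
    assert np.abs(series.sum(axis=1) - 1).max() < 1e-12
    assert np.abs(series[-1] - m.stationary_distribution).sum() < 1e-8
    assert np.allclose(msm.propagate(m, p0, 0)[0], p0)


def test_propagation_stationary_is_fixed_point(three_state_model):
    m = three_state_model
    series = msm.propagate(m, m.stationary_distribution, 10)
    assert np.abs(series - m.stationary_distribution).max() < 1e-12


def test_weighted_observable_contracts(three_state_model):
    m = three_state_model
    vals = np.array([2.0, 5.0, 11.0])
    # uniform values -> the value itself
    assert msm.weighted_observable(m, np.full(3, 7.0), 2) == pytest.approx(7.0)
    # m = k -> full stationary average
    full = float(m.stationary_distribution @ vals)
    assert msm.weighted_observable(m, vals, 3) == pytest.approx(full)
    # top-2: hand-computed renormalized weighting
    pi = m.stationary_distribution
    top = np.argsort(pi)[::-1][:2]
    want = float((pi[top] / pi[top].sum()) @ vals[top])
    assert msm.weighted_observable(m, vals, 2) == pytest.approx(want)


def test_eigenvector_modes_sign_structure(three_state_model):
    # 2-state: the second mode separates the two states
    counts2 = np.array([[80.0, 20], [30, 70]])
    m2 = msm.estimate_reversible(counts2)
    u = m2.right_eigenvector(2)
    assert u[0] * u[1] < 0
    # metastable pair separated from the third state
    counts = np.array([[500.0, 50, 1], [50, 480, 2], [1, 2, 300]])
    m3 = msm.estimate_reversible(counts)
    modes = msm.eigenvector_modes(m3, 2)
    u = modes["weights"]
    assert np.sign(u[0]) == np.sign(u[1]) != np.sign(u[2])
    # pi-orthogonality of eigenvectors
    pi = m3.stationary_distribution
    assert abs(np.sum(pi * m3.right_eigenvector(2) * m3.right_eigenvector(3))) < 1e-8


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def test_pipeline_deterministic_under_fixed_seed(toy_trajectory):
    traj, _ = toy_trajectory
    a = msm.build_msm([traj], n_states=10, lag_time=2.0, seed=7)
    b = msm.build_msm([traj], n_states=10, lag_time=2.0, seed=7)
    assert np.array_equal(a.decomposition.dtrajs[0], b.decomposition.dtrajs[0])
    assert np.allclose(a.model.transition_matrix, b.model.transition_matrix)


def test_pipeline_recovers_slowest_timescale(toy_complex, toy_kinetics):
    traj, _ = synthetic.make_kinetic_trajectory(toy_complex, toy_kinetics, 6000, seed=21)
    result = msm.build_msm([traj], n_states=4, lag_time=1.0, seed=0)
    t_true = toy_kinetics.transition_matrix
    lam2 = np.sort(np.linalg.eigvals(t_true).real)[-2]
    want = -1.0 / np.log(lam2)
    got = msm.implied_timescales(result.model, 1)[0]
    assert got == pytest.approx(want, rel=0.25)
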