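import dataclasses

import numpy as np
import pytest

from mhcdyn import classifiers as clf
from mhcdyn import molgraphs as mg
from mhcdyn import nn
from mhcdyn import synthetic


# ---------------------------------------------------------------------------
# Sequence encoding
# ---------------------------------------------------------------------------


def test_encoding_is_one_hot_ordered_by_similarity_classes():
    enc = clf.encode_sequence("FLIYLDVSV")
    assert enc.shape == (9, 20)
    assert np.allclose(enc.sum(axis=1), 1.0)
    assert len(clf.RESIDUE_ORDER) == 20 and len(set(clf.RESIDUE_ORDER)) == 20
    # residues of one class occupy contiguous columns
    col = {aa: i for i, aa in enumerate(clf.RESIDUE_ORDER)}
    for members in clf.RESIDUE_SIMILARITY_CLASSES.values():
        idx = sorted(col[a] for a in members)
        assert idx == list(range(idx[0], idx[0] + len(idx)))
    assert enc[0, col["F"]] == 1.0


def test_encoding_rejects_bad_input():
    with pytest.raises(Exception):
        clf.encode_sequence("FLIYLDVS")
    with pytest.raises(Exception):
        clf.encode_sequence("FLIYLDVSX")


# ---------------------------------------------------------------------------
# Forward-pass contracts
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def toy_graph_pair():
    s = synthetic.make_toy_complex()
    return mg.build_ll_graph(s), mg.build_lp_graph(s)


def test_graphnet_deterministic_and_normalized(toy_graph_pair):
    net = clf.GraphConvNet(seed=0)
    a = net.forward(*toy_graph_pair).data
    b = net.forward(*toy_graph_pair).data
    assert np.array_equal(a, b)
    p = nn.softmax(a)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)


def test_graphnet_permutation_invariance(toy_graph_pair):
    ll, lp = toy_graph_pair
    net = clf.GraphConvNet(seed=3)
    base = net.forward(ll, lp).data
    rng = np.random.default_rng(7)
    worst = 0.0
    for _ in range(50):
        out = net.forward(
            ll.permuted(rng.permutation(ll.n_nodes)),
            lp.permuted(rng.permutation(lp.n_nodes)),
        ).data
        worst = max(worst, np.abs(out - base).max())
    assert worst < 1e-6


def test_graphnet_handles_empty_lp_edges(toy_graph_pair):
    ll, _ = toy_graph_pair
    s = synthetic.make_toy_complex()
    coords = s.coords.copy()
    pep = s.mask_role("peptide", heavy_only=False)
    coords[pep] += np.array([0.0, 0.0, 50.0])
    lp_empty = mg.build_lp_graph(s.with_coords(coords))
    assert lp_empty.n_edges == 0
    out = clf.GraphConvNet(seed=0).forward(ll, lp_empty).data
    assert np.isfinite(out).all()


def test_graphnet_tiny_hand_computed_forward(toy_graph_pair):
    """2-node, 1-edge LL graph with identity-style weights against pencil math."""
    ll, lp = toy_graph_pair
    bins = mg.BinScheme()
    feats = np.zeros((2, clf.N_NODE_FEATURES))
    feats[0, 0] = 1.0  # C
    feats[1, 1] = 1.0  # N
    w = 0.5
    tiny = mg.MolecularGraph(
        kind="LL", node_features=feats, atom_indices=np.array([0, 1]),
        edges=np.array([[0, 1]]), distances=np.array([3.0]),
        bin_index=np.array([1]), weights=np.array([w]), n_ligand_nodes=2, bins=bins,
    )
    cfg = clf.GraphNetConfig(hidden_width=clf.N_NODE_FEATURES,
                             fc_width=clf.N_NODE_FEATURES)
    net = clf.GraphConvNet(cfg, seed=0)
    eye = np.eye(clf.N_NODE_FEATURES)
    for mod in net.encoders["LL"]["modules"]:
        mod["self"].data = eye.copy()
        for b in mod["bins"]:
            b.data = eye.copy()
        mod["bias"].data[:] = 0.0
    net.encoders["LL"]["fc_w"].data = eye.copy()
    net.encoders["LL"]["fc_b"].data[:] = 0.0
    # hand computation: each module maps h -> h + w * (neighbour h)
    h = feats.copy()
    for _ in range(3):
        h = h + w * h[::-1]
    expect = np.concatenate([h.max(axis=0), h.mean(axis=0)])
    got = net._encode(tiny, "LL").data
    assert np.allclose(got, expect, atol=1e-12)


def test_sequence_forward_contracts():
    net = clf.SequenceConvNet(seed=0)
    enc = np.stack([clf.encode_sequence("FLIYLDVSV"), clf.encode_sequence("FLIYLDVSV")])
    out = net.forward_batch(enc).data
    assert np.array_equal(out[0], out[1])
    p = nn.softmax(out)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
    with pytest.raises(Exception):
        net.forward_batch(np.zeros((1, 8, 20)))


def test_sequence_conv_hand_computed_single_channel():
    """1x1-kernel convolution with hand-set weights matches manual arithmetic."""
    cfg = clf.SequenceNetConfig(channels=1, kernel_positions=1, kernel_residues=1,
                                dense_width=2)
    net = clf.SequenceConvNet(cfg, seed=0)
    net.kernel.data[:] = 2.0
    net.kernel_b.data[:] = 0.5
    enc = clf.encode_sequence("FLIYLDVSV")[None]
    patches = enc.reshape(1, -1)[:, net.patch_idx]  # (1, 180, 1)
    manual = np.maximum(patches[..., 0] * 2.0 + 0.5, 0).reshape(1, 9, 20).max(axis=2)
    x = nn.Tensor(enc.reshape(1, -1))
    conv = (x.take_axis1(net.patch_idx) @ net.kernel + net.kernel_b).relu()
    pooled = conv.reshape(1, 9, 20, 1).max(axis=2).reshape(1, -1)
    assert np.allclose(pooled.data, manual)


def test_sasa_model_contracts():
    net = clf.SasaNet(n_features=36, seed=0)
    f = np.random.default_rng(0).random((3, 36))
    p = net.predict_proba(f)
    assert np.all((p >= 0) & (p <= 1))
    assert np.array_equal(net.predict_proba(f[:1]), net.predict_proba(f[:1]))
    with pytest.raises(Exception):
        net.forward_batch(np.zeros((1, 10)))


# ---------------------------------------------------------------------------
# Training on planted signals
# ---------------------------------------------------------------------------


def test_sequence_model_learns_planted_rule_and_not_shuffled_labels():
    train = synthetic.make_labeled_sequences(100, seed=1)
    test = synthetic.make_labeled_sequences(50, seed=2)
    cfg = clf.SequenceNetConfig(max_epochs=140)
    trained = clf.train("sequence", train, config=cfg, seed=0)
    preds = clf.predict(trained, {r.sequence: r.sequence for r in test})
    auc = clf.evaluate_auc(preds, {r.sequence: r.label for r in test})
    assert auc > 0.9
    # label-shuffled control: no leakage pathway
    rng = np.random.default_rng(3)
    labels = [r.label for r in train]
    rng.shuffle(labels)
    shuffled = [dataclasses.replace(r, label=l) for r, l in zip(train, labels)]
    t2 = clf.train("sequence", shuffled, config=cfg, seed=0)
    p2 = clf.predict(t2, {r.sequence: r.sequence for r in test})
    auc2 = clf.evaluate_auc(p2, {r.sequence: r.label for r in test})
    assert 0.35 < auc2 < 0.65


def test_sasa_model_learns_linearly_separable_features():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(4)
    n = 160
    x = rng.normal(size=(n, 36))
    w_true = rng.normal(size=36)
    y = (x @ w_true > 0).astype(int)
    model = clf.SasaNet(36, seed=0)
    log = clf._fit(model, x[:120], y[:120], seed=0)
    assert log.epoch_losses[-1] < log.epoch_losses[0]
    assert roc_auc_score(y[120:], model.predict_proba(x[120:])) > 0.95


def test_graph_model_learns_conformational_signal():
    train_recs, train_graphs = synthetic.make_conformation_graph_ensemble(20, seed=1)
    test_recs, test_graphs = synthetic.make_conformation_graph_ensemble(10, seed=2)
    cfg = clf.GraphNetConfig(max_epochs=30, plateau_min_epochs=10)
    trained = clf.train("graph", train_recs, graphs=train_graphs, config=cfg, seed=0)
    preds = clf.predict(trained, {r.sequence: test_graphs[r.sequence] for r in test_recs})
    auc = clf.evaluate_auc(preds, {r.sequence: r.label for r in test_recs})
    assert auc > 0.9


def test_training_is_seed_deterministic():
    train = synthetic.make_labeled_sequences(30, seed=5)
    cfg = clf.SequenceNetConfig(max_epochs=10, plateau_min_epochs=10)
    a = clf.train("sequence", train, config=cfg, seed=11)
    b = clf.train("sequence", train, config=cfg, seed=11)
    assert a.log.epoch_losses == b.log.epoch_losses


def test_training_requires_both_classes():
    recs = [r for r in synthetic.make_labeled_sequences(10, seed=0) if r.is_immunogenic]
    with pytest.raises(clf.ClassError):
        clf.train("sequence", recs)


# ---------------------------------------------------------------------------
# Prediction and evaluation
# ---------------------------------------------------------------------------


def test_peptide_level_prediction_is_mean_of_frames():
    p = clf.Prediction("x", np.array([0.2, 0.8]))
    assert p.p_immunogenic == pytest.approx(0.5)
    single = clf.Prediction("y", np.array([0.3]))
    assert single.p_immunogenic == pytest.approx(0.3)


def test_prediction_order_independent():
    train = synthetic.make_labeled_sequences(20, seed=6)
    cfg = clf.SequenceNetConfig(max_epochs=5, plateau_min_epochs=5)
    trained = clf.train("sequence", train, config=cfg, seed=0)
    seqs = [r.sequence for r in train[:8]]
    a = {p.peptide_id: p.p_immunogenic
         for p in clf.predict(trained, {s: s for s in seqs})}
    b = {p.peptide_id: p.p_immunogenic
         for p in clf.predict(trained, {s: s for s in reversed(seqs)})}
    assert a == b


def _auc_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


@pytest.mark.parametrize(
    "scores,labels",
    [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]),
        ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]),
        ([0.3, 0.7, 0.3, 0.9, 0.1, 0.7], [1, 1, 0, 1, 0, 0]),
    ],
)
def test_auroc_matches_pairwise_oracle(scores, labels):
    preds = [clf.Prediction(f"p{i}", np.array([s])) for i, s in enumerate(scores)]
    lab = {f"p{i}": ("immunogenic" if l else "non_immunogenic")
           for i, l in enumerate(labels)}
    assert clf.evaluate_auc(preds, lab) == pytest.approx(_auc_oracle(scores, labels))


def test_auroc_single_class_raises():
    preds = [clf.Prediction("a", np.array([0.5]))]
    with pytest.raises(clf.ClassError):
        clf.evaluate_auc(preds, {"a": "immunogenic"})


def test_compare_models_contracts():
    rng = np.random.default_rng(0)
    ids = [f"p{i}" for i in range(1000)]
    a = [clf.Prediction(i, np.array([v])) for i, v in zip(ids, rng.random(1000))]
    same = clf.compare_models(a, a)
    assert same["pearson_r"] == pytest.approx(1.0)
    assert same["r_squared"] == pytest.approx(1.0)
    b = [clf.Prediction(i, np.array([v])) for i, v in zip(ids, rng.random(1000))]
    indep = clf.compare_models(a, b)
    assert abs(indep["pearson_r"]) < 0.1
    anti = [clf.Prediction(p.peptide_id, 1.0 - p.frame_probs) for p in a]
    assert clf.compare_models(a, anti)["pearson_r"] == pytest.approx(-1.0)


def test_compare_models_degenerate_input():
    a = [clf.Prediction(f"p{i}", np.array([0.5])) for i in range(5)]
    with pytest.raises(Exception):
        clf.compare_models(a, a)
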