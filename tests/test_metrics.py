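"""Cluster fits, JSD/CSI, nearest-cluster decoding, permutation tests."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import voxstate as vs
from voxstate.metrics import permute_labels, permuted_label_chance
from voxstate.types import Gaussian, StateTrajectory


def traj_of(coords, labels, names=None):
    coords = np.asarray(coords, dtype=float)
    names = names or [f"d{i}" for i in range(coords.shape[1])]
    return StateTrajectory(coords=coords, dim_names=names, labels=labels)


def jsd_quadrature(m1, s1, m2, s2):
    """Adaptive numerical-integration oracle for the 1-D Gaussian JSD (bits)."""
    def integrand(x):
        px, qx = norm.pdf(x, m1, s1), norm.pdf(x, m2, s2)
        mx = 0.5 * (px + qx)
        out = 0.0
        if px > 0:
            out += 0.5 * px * np.log2(px / mx)
        if qx > 0:
            out += 0.5 * qx * np.log2(qx / mx)
        return out

    lo = min(m1 - 10 * s1, m2 - 10 * s2)
    hi = max(m1 + 10 * s1, m2 + 10 * s2)
    return quad(integrand, lo, hi, limit=200)[0]


# --- fit_cluster_gaussians ---------------------------------------------------


def test_unit_square_corners_hand_computation():
    t = traj_of([[0, 0], [1, 0], [0, 1], [1, 1]], ["s"] * 4)
    c = vs.fit_cluster_gaussians(t, shrinkage=0.0)
    g = c["s"]
    assert np.allclose(g.mean, [0.5, 0.5])
    assert np.allclose(g.cov, np.diag([0.25, 0.25]))
    assert g.count == 4


def test_full_shrinkage_gives_scaled_identity(rng):
    t = traj_of(rng.normal(size=(30, 3)), ["s"] * 30)
    c = vs.fit_cluster_gaussians(t, shrinkage=1.0)
    cov = c["s"].cov
    assert np.allclose(cov, cov[0, 0] * np.eye(3))


def test_covariance_matches_direct_oracle(rng):
    pts = rng.normal(size=(200, 3))
    t = traj_of(pts, ["s"] * 200)
    c = vs.fit_cluster_gaussians(t, shrinkage=0.0)
    dev = pts - pts.mean(axis=0)
    assert np.max(np.abs(c["s"].cov - dev.T @ dev / 200)) < 1e-8


def test_singleton_cluster_errors_naming_label():
    t = traj_of([[0, 0], [1, 1], [2, 2]], ["a", "a", "lonely"])
    with pytest.raises(ValueError, match="lonely"):
        vs.fit_cluster_gaussians(t)


def test_small_clusters_flagged(rng):
    labels = ["big"] * 20 + ["tiny"] * 3
    t = traj_of(rng.normal(size=(23, 4)), labels)
    c = vs.fit_cluster_gaussians(t)
    assert "tiny" in c.flagged and "big" not in c.flagged


def test_multilabel_tr_contributes_to_every_cluster(rng):
    labels = [("a", "b")] * 10 + [("a",)] * 5
    t = traj_of(rng.normal(size=(15, 2)), labels)
    c = vs.fit_cluster_gaussians(t)
    assert c["a"].count == 15 and c["b"].count == 10


# --- jsd_gaussian ------------------------------------------------------------


def test_identical_gaussians_have_zero_divergence():
    g = Gaussian(mean=[0.0, 1.0], cov=np.eye(2), count=10)
    assert vs.jsd_gaussian(g, g, mc_samples=100_000, seed=0) < 1e-3


def test_disjoint_gaussians_saturate_at_one():
    g1 = Gaussian(mean=[0.0], cov=[[1.0]], count=10)
    g2 = Gaussian(mean=[100.0], cov=[[1.0]], count=10)
    assert vs.jsd_gaussian(g1, g2, mc_samples=20_000, seed=0) >= 0.999


def test_jsd_matches_quadrature_oracle():
    g1 = Gaussian(mean=[0.0], cov=[[1.0]], count=10)
    g2 = Gaussian(mean=[1.0], cov=[[1.0]], count=10)
    est = vs.jsd_gaussian(g1, g2, mc_samples=100_000, seed=3)
    assert abs(est - jsd_quadrature(0, 1, 1, 1)) < 0.005


def test_jsd_symmetric_and_bounded(rng):
    for i in range(25):
        m1, m2 = rng.normal(0, 3, 2)
        s1, s2 = rng.uniform(0.3, 3, 2)
        g1 = Gaussian(mean=[m1], cov=[[s1**2]], count=5)
        g2 = Gaussian(mean=[m2], cov=[[s2**2]], count=5)
        a = vs.jsd_gaussian(g1, g2, mc_samples=2000, seed=i)
        b = vs.jsd_gaussian(g2, g1, mc_samples=2000, seed=i)
        assert a == b
        assert 0.0 <= a <= 1.0


def test_degenerate_covariance_suggests_shrinkage():
    g1 = Gaussian(mean=[0.0, 0.0], cov=np.zeros((2, 2)), count=5)
    g2 = Gaussian(mean=[1.0, 1.0], cov=np.eye(2), count=5)
    with pytest.raises(ValueError, match="shrinkage"):
        vs.jsd_gaussian(g1, g2, mc_samples=100, seed=0)


# --- csi ---------------------------------------------------------------------


def test_csi_identical_clusters_is_zero(rng):
    g = {lab: Gaussian(mean=[0.0, 0.0], cov=np.eye(2), count=10)
         for lab in "abc"}
    c = vs.ClusterSet(clusters=g)
    r = vs.csi(c, mc_samples=50_000, seed=0)
    assert r.csi < 1e-3


def test_csi_separated_tight_clusters_saturates():
    means = [[0, 0], [100, 0], [0, 100]]
    g = {lab: Gaussian(mean=m, cov=1e-4 * np.eye(2), count=10)
         for lab, m in zip("abc", means)}
    r = vs.csi(vs.ClusterSet(clusters=g), mc_samples=5_000, seed=0)
    assert r.csi > 0.999


def test_csi_matches_mean_of_pairwise_oracles(rng):
    means = rng.normal(0, 2, size=(4, 3))
    covs = []
    for _ in range(4):
        a = rng.normal(size=(3, 3))
        covs.append(a @ a.T / 3 + 0.5 * np.eye(3))
    g = {f"s{i}": Gaussian(mean=means[i], cov=covs[i], count=10) for i in range(4)}
    c = vs.ClusterSet(clusters=g)
    r = vs.csi(c, mc_samples=100_000, seed=0)
    # high-sample MC oracle per pair, independent seeds
    oracle = []
    labs = sorted(g)
    for i in range(4):
        for j in range(i + 1, 4):
            oracle.append(vs.jsd_gaussian(g[labs[i]], g[labs[j]],
                                          mc_samples=400_000, seed=777 + i * 7 + j))
    assert abs(r.csi - np.mean(oracle)) < 0.01
    # invariant: csi equals the mean of the strict upper triangle
    triu = r.pairwise_jsd.to_numpy()[np.triu_indices(4, k=1)]
    assert r.csi == pytest.approx(triu.mean())
    assert np.all((triu >= 0) & (triu <= 1))


def test_csi_invariant_under_rotation_and_translation(rng):
    means = rng.normal(size=(3, 3))
    covs = [np.eye(3) * s for s in (0.5, 1.0, 2.0)]
    g = {f"s{i}": Gaussian(mean=means[i], cov=covs[i], count=9) for i in range(3)}
    r1 = vs.csi(vs.ClusterSet(clusters=g), mc_samples=60_000, seed=4)
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    shift = rng.normal(size=3)
    g2 = {k: Gaussian(mean=q @ v.mean + shift, cov=q @ v.cov @ q.T, count=9)
          for k, v in g.items()}
    r2 = vs.csi(vs.ClusterSet(clusters=g2), mc_samples=60_000, seed=4)
    assert abs(r1.csi - r2.csi) < 0.01


def test_csi_requires_two_clusters():
    g = {"only": Gaussian(mean=[0.0], cov=[[1.0]], count=5)}
    with pytest.raises(ValueError):
        vs.csi(vs.ClusterSet(clusters=g), mc_samples=100, seed=0)


# --- classification ----------------------------------------------------------


def test_points_at_centroids_classify_perfectly(rng):
    train = traj_of(np.vstack([rng.normal([0, 0], 0.1, (20, 2)),
                               rng.normal([5, 5], 0.1, (20, 2))]),
                    ["a"] * 20 + ["b"] * 20)
    cents = {lab: train.coords[np.array([l == (lab,) for l in train.labels])].mean(axis=0)
             for lab in ("a", "b")}
    test = traj_of(np.vstack([cents["a"], cents["b"]]), ["a", "b"])
    assert vs.classify_states(train, test) == ["a", "b"]


def test_exact_tie_goes_to_lexicographically_first_label():
    train = traj_of([[-1.0], [-1.0], [1.0], [1.0]], ["zed", "zed", "ape", "ape"])
    test = traj_of([[0.0]], [])
    # centroids at -1 (zed) and +1 (ape): tie at 0 -> 'ape'
    assert vs.classify_states(train, test) == ["ape"]


def test_classifier_matches_exhaustive_loop_oracle(rng):
    centers = np.array([[0, 0], [8, 0], [0, 8]])
    labels, pts = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(c, 1.0, (40, 2)))
        labels += [f"c{i}"] * 40
    train = traj_of(np.vstack(pts), labels)
    test_pts = rng.normal(3, 4, size=(500, 2))
    test = traj_of(test_pts, [])
    preds = vs.classify_states(train, test)
    labs, cents = sorted(set(labels)), []
    cents = [np.vstack(pts)[np.array(labels) == lab].mean(axis=0) for lab in labs]
    for p, pt in zip(preds, test_pts):
        dists = [np.sum((pt - c) ** 2) for c in cents]
        assert p == labs[int(np.argmin(dists))]


def test_mahalanobis_metric_respects_cluster_shape(rng):
    # wide cluster 'w' along x, tight cluster 't': point near t's edge
    pts_w = rng.normal(0, [5.0, 0.2], (300, 2))
    pts_t = rng.normal([8, 0], 0.2, (300, 2))
    train = traj_of(np.vstack([pts_w, pts_t]), ["w"] * 300 + ["t"] * 300)
    test = traj_of([[5.5, 0.0]], [])
    assert vs.classify_states(train, test, metric="euclidean") == ["t"]
    assert vs.classify_states(train, test, metric="mahalanobis") == ["w"]


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.lists(st.integers(0, 50), min_size=4, max_size=4),
                min_size=4, max_size=4))
def test_balanced_accuracy_property_matches_loop_oracle(conf_rows):
    conf = np.array(conf_rows) + np.eye(4, dtype=int)  # nonzero rows
    oracle = np.mean([conf[i, i] / conf[i].sum() for i in range(4)])
    assert vs.balanced_accuracy(conf) == pytest.approx(oracle)
    assert 0.0 <= vs.balanced_accuracy(conf) <= 1.0


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.floats(-20, 20), st.floats(-20, 20),
       st.floats(0.1, 5), st.floats(0.1, 5),
       st.integers(0, 2**31 - 1))
def test_jsd_property_symmetric_bounded(m1, m2, s1, s2, seed):
    g1 = Gaussian(mean=[m1], cov=[[s1**2]], count=5)
    g2 = Gaussian(mean=[m2], cov=[[s2**2]], count=5)
    a = vs.jsd_gaussian(g1, g2, mc_samples=500, seed=seed)
    assert a == vs.jsd_gaussian(g2, g1, mc_samples=500, seed=seed)
    assert 0.0 <= a <= 1.0


def test_balanced_accuracy_examples(rng):
    assert vs.balanced_accuracy(np.diag([5, 3, 2])) == 1.0
    # 90/10, always predict majority: recalls 1.0 and 0.0
    conf = np.array([[90, 0], [10, 0]])
    assert vs.balanced_accuracy(conf) == 0.5
    conf = rng.integers(1, 20, size=(4, 4))
    oracle = np.mean([conf[i, i] / conf[i].sum() for i in range(4)])
    assert vs.balanced_accuracy(conf) == pytest.approx(oracle)
    with pytest.raises(ValueError):
        vs.balanced_accuracy(np.array([[3, 0], [0, 0]]))


def test_crossval_high_snr_near_perfect():
    spec = vs.SyntheticSpec(n_trs=600, n_voxels=150, snr=10.0,
                            drift_amplitude=0, hrf="delta", seed=2)
    d, b, _ = vs.generate(spec)
    y = vs.zscore_voxels(b)
    res = vs.crossval_classify(d, y, folds=5, n_components=24, seed=0)
    assert res.mean_accuracy >= 0.95
    assert res.n_labels == 12 and res.chance == pytest.approx(1 / 12)
    assert len(res.fold_accuracies) == 5
    # confusion row sums equal per-label test counts
    assert int(res.confusion.to_numpy().sum()) == sum(
        1 for labs in d.labels if labs
    )


def test_crossval_on_permuted_labels_is_at_chance(rng):
    spec = vs.SyntheticSpec(n_trs=600, n_voxels=100, snr=10.0,
                            drift_amplitude=0, hrf="delta", seed=3)
    d, b, _ = vs.generate(spec)
    y = vs.zscore_voxels(b)
    permuted = [d.labels[i] for i in rng.permutation(len(d.labels))]
    res = vs.crossval_classify(d, y, labels=permuted, folds=5,
                               n_components=24, seed=0,
                               fold_scheme="stratified")
    se = np.std(res.fold_accuracies, ddof=1) / np.sqrt(len(res.fold_accuracies))
    assert abs(res.mean_accuracy - res.chance) <= 3 * max(se, 0.01)


def test_crossval_game_scheme_nine_labels():
    spec = vs.SyntheticSpec(n_trs=800, n_voxels=120, scheme="game", snr=10.0,
                            drift_amplitude=0, hrf="delta", seed=1)
    d, b, _ = vs.generate(spec)
    y = vs.zscore_voxels(b)
    res = vs.crossval_classify(d, y, folds=5, n_components=24, seed=0,
                               fold_scheme="stratified")
    assert res.n_labels == 9
    assert res.mean_accuracy > res.chance


def test_crossval_rejects_too_many_folds(attention_trajectory, attention_dataset):
    d, y, _ = attention_dataset
    with pytest.raises(ValueError, match="folds"):
        vs.crossval_classify(d, y, folds=y.n_trs + 1)


# --- permutation test --------------------------------------------------------


def test_p_value_boundary_cases():
    labels = ["a"] * 10 + ["b"] * 10
    original = tuple(("a",) if l == "a" else ("b",) for l in labels)

    # constant statistic: every null ties the observed -> p = (1+n)/(1+n) = 1
    r = vs.permutation_test(lambda labs: 0.0, labels, n_permutations=50, seed=0)
    assert r.p_value == pytest.approx(1.0)

    # statistic maximal only at the original labeling -> p hits the
    # add-one floor 1/(n+1)
    def stat_identity(labs):
        return float(tuple(labs) == original)

    r2 = vs.permutation_test(stat_identity, labels, n_permutations=99, seed=1)
    assert r2.p_value == pytest.approx(1.0 / 100)
    assert 0 < r2.p_value <= 1


def test_block_permutation_preserves_runs():
    from voxstate.types import normalize_labels

    labels = normalize_labels(["a"] * 5 + ["b"] * 3 + ["a"] * 4)
    rng = np.random.default_rng(0)
    out = permute_labels(labels, rng, permute_unit="block")
    # same multiset, and 'b's stay contiguous
    assert sorted(out) == sorted(labels)
    b_pos = [i for i, l in enumerate(out) if l == ("b",)]
    assert b_pos == list(range(b_pos[0], b_pos[0] + 3))


def test_permutation_pvalues_uniform_for_uninformative_statistic():
    """Data independent of labels => permutation p-values ~ Uniform(0,1)."""
    from scipy.stats import kstest

    rng = np.random.default_rng(42)
    pvals = []
    for _ in range(200):
        x = rng.normal(size=30)
        labels = ["a"] * 15 + ["b"] * 15

        def stat(labs, x=x):
            return float(np.mean([xi for xi, l in zip(x, labs) if l == ("a",)]))

        r = vs.permutation_test(stat, labels, n_permutations=99,
                                seed=int(rng.integers(2**31)))
        pvals.append(r.p_value)
    assert kstest(pvals, "uniform").pvalue > 0.01


# --- chance estimation -------------------------------------------------------


def test_permuted_label_chance_matches_one_over_k(attention_trajectory):
    c = permuted_label_chance(attention_trajectory, n_permutations=300, seed=0)
    assert abs(c - 1 / 12) < 0.02


# --- cross projection --------------------------------------------------------


def test_orthogonal_states_have_null_off_diagonals(rng):
    # two mutually exclusive states on orthogonal dimensions
    n = 400
    on_a = rng.random(n) < 0.5
    coords = np.zeros((n, 2))
    coords[on_a, 0] = 1.0
    coords[~on_a, 1] = 1.0
    coords += rng.normal(0, 0.05, coords.shape)
    labels = [("a",) if z else ("b",) for z in on_a]
    t = traj_of(coords, labels, names=["dim_a", "dim_b"])
    r = vs.cross_projection(t, n_permutations=500, seed=0)
    assert abs(r.means.loc["a", "dim_b"]) < 0.05
    assert abs(r.means.loc["b", "dim_a"]) < 0.05
    assert not r.significant.loc["a", "dim_b"]
    assert not r.significant.loc["b", "dim_a"]


def test_anticorrelated_states_project_negatively(rng):
    n = 400
    on_a = rng.random(n) < 0.5
    coords = np.zeros((n, 2))
    coords[on_a] = [1.0, -0.8]
    coords[~on_a] = [-0.8, 1.0]
    coords += rng.normal(0, 0.05, coords.shape)
    labels = [("a",) if z else ("b",) for z in on_a]
    t = traj_of(coords, labels, names=["dim_a", "dim_b"])
    r = vs.cross_projection(t, n_permutations=500, seed=0)
    assert r.means.loc["a", "dim_b"] < -0.5
    assert r.means.loc["b", "dim_a"] < -0.5
    assert r.significant.loc["a", "dim_b"]
    assert r.significant.loc["b", "dim_a"]


def test_cross_projection_can_be_asymmetric(rng):
    n = 600
    coords = rng.normal(0, 0.01, (n, 2))
    on_a = np.zeros(n, dtype=bool); on_a[:300] = True
    on_b = np.zeros(n, dtype=bool); on_b[150:450] = True
    coords[on_a, 0] += 1.0
    coords[on_b, 1] += 1.0
    labels = []
    for i in range(n):
        labs = []
        if on_a[i]:
            labs.append("a")
        if on_b[i]:
            labs.append("b")
        labels.append(tuple(labs))
    t = traj_of(coords, labels, names=["dim_a", "dim_b"])
    r = vs.cross_projection(t, n_permutations=200, seed=0)
    assert r.means.loc["a", "dim_b"] != pytest.approx(r.means.loc["b", "dim_a"], abs=1e-6)


def test_mutually_exclusive_anticorrelated_states_project_negatively():
    """End-to-end: generator plants mutually exclusive states with
    anticorrelated maps; each projects negatively on the other's axis."""
    from voxstate.synthetic import GAME_STATES

    rng = np.random.default_rng(0)
    i_ec = GAME_STATES.index("engage_close")
    i_se = GAME_STATES.index("safe_explore")
    bias = np.zeros((9, 9))
    bias[i_ec, i_se] = bias[i_se, i_ec] = -8.0
    spec = vs.SyntheticSpec(n_trs=1500, n_voxels=300, scheme="game",
                            state_correlation=bias, seed=8)
    w = rng.standard_normal((9, 300)) * (rng.random((9, 300)) < 0.4)
    w[i_ec] = -0.8 * w[i_se] + 0.3 * rng.standard_normal(300)
    spec.weight_maps = w
    design, bold, _ = vs.generate(spec)
    y = vs.zscore_voxels(vs.detrend_voxels(bold))
    model = vs.fit_state_space(design, y, n_components=24)
    traj = vs.project(y, model.basis_qs, model.variable_names,
                      labels=design.labels)
    r = vs.cross_projection(traj, states=["engage_close", "safe_explore"],
                            n_permutations=4000, seed=0, alpha=0.01)
    assert r.means.loc["engage_close", "safe_explore"] < 0
    assert r.means.loc["safe_explore", "engage_close"] < 0
    assert r.significant.loc["engage_close", "safe_explore"]
    assert r.significant.loc["safe_explore", "engage_close"]


def test_missing_state_flagged(rng):
    t = traj_of(rng.normal(size=(50, 2)), [("a",)] * 25 + [("b",)] * 25)
    r = vs.cross_projection(t, states=["a", "b", "ghost"], n_permutations=50, seed=0)
    assert "ghost" in r.missing
    assert np.isnan(r.means.loc["ghost"]).all()
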