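"""Quantification of recovered state spaces.

Two convergent checks are provided. The cluster separation index (CSI)
asks whether distinct task states occupy distinct regions of the state
space: a multivariate normal is fitted to each state's cloud of projected
TRs, the Jensen-Shannon divergence (JSD) is estimated for every pair, and
the CSI is the mean of all pairwise JSDs. With base-2 logarithms the JSD
lies in [0, 1], so CSI = 0 means no separation and CSI = 1 complete
separation. Cross-validated nearest-cluster classification asks whether
the space predicts the state of held-out TRs; the whole subspace recovery
is refit inside each training fold so no information leaks from test TRs.
Significance for either statistic comes from permutation tests that
shuffle the state labels and re-run the full analysis.

Multi-label TRs (states need not be mutually exclusive) are supported
throughout: a TR contributes to every cluster it is labeled with, and a
classified TR counts as correct when the prediction matches any of its
held labels. TRs with an empty label set are ignored by the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .statespace import fit_state_space, project
from .types import (
    ActivityMatrix,
    ClusterSet,
    Gaussian,
    StateTrajectory,
    TaskDesign,
    normalize_labels,
)

__all__ = [
    "fit_cluster_gaussians",
    "jsd_gaussian",
    "csi",
    "CsiResult",
    "classify_states",
    "crossval_classify",
    "ClassificationResult",
    "balanced_accuracy",
    "permutation_test",
    "PermutationResult",
    "cross_projection",
    "CrossProjectionResult",
]

LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# cluster fitting


def _label_members(labels) -> dict:
    """Map each state label to the indices of TRs carrying it."""
    members: dict[str, list[int]] = {}
    for i, labs in enumerate(labels):
        for lab in labs:
            members.setdefault(lab, []).append(i)
    return {k: np.asarray(v) for k, v in members.items()}


def fit_cluster_gaussians(
    t: StateTrajectory, shrinkage: float = 0.05
) -> ClusterSet:
    """Fit a multivariate normal to each state's projected TRs.

    The mean is the sample mean; the covariance is the population
    covariance (divide by N) shrunk toward a scaled identity:
    ``(1 - shrinkage) * S + shrinkage * (trace(S)/dims) * I``. Shrinkage
    keeps small clusters positive definite in higher-dimensional spaces.
    Labels with fewer points than ``dims + 2`` are flagged.
    """
    if not 0 <= shrinkage <= 1:
        raise ValueError(f"shrinkage must be in [0, 1], got {shrinkage}")
    if not t.labels:
        raise ValueError("trajectory has no state labels")
    members = _label_members(t.labels)
    dims = t.n_dims
    clusters: dict[str, Gaussian] = {}
    flagged = []
    for lab in sorted(members):
        idx = members[lab]
        if idx.size < 2:
            raise ValueError(f"state '{lab}' has {idx.size} TR(s); need >= 2")
        pts = t.coords[idx]
        mean = pts.mean(axis=0)
        dev = pts - mean
        cov = dev.T @ dev / idx.size  # population convention
        cov = (1 - shrinkage) * cov + shrinkage * (np.trace(cov) / dims) * np.eye(dims)
        clusters[lab] = Gaussian(mean=mean, cov=cov, count=int(idx.size))
        if idx.size < dims + 2:
            flagged.append(lab)
    return ClusterSet(clusters=clusters, dim_names=t.dim_names, flagged=tuple(flagged))


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence and CSI


class _MVN:
    """Cholesky-backed Gaussian sampler/log-density."""

    def __init__(self, g: Gaussian, what: str = "cluster"):
        self.mean = g.mean
        cov = 0.5 * (g.cov + g.cov.T)
        try:
            self.chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"covariance of {what} is not positive definite; "
                "increase the shrinkage used when fitting clusters"
            ) from None
        self.logdet = 2.0 * np.log(np.diag(self.chol)).sum()
        self.dim = self.mean.size

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, self.dim))
        return self.mean + z @ self.chol.T


def _mvn_logpdf(m: _MVN, x: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    dev = (x - m.mean).T
    sol = solve_triangular(m.chol, dev, lower=True)
    maha = (sol**2).sum(axis=0)
    return -0.5 * (m.dim * np.log(2 * np.pi) + m.logdet + maha)


def jsd_gaussian(
    g1: Gaussian, g2: Gaussian, mc_samples: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo Jensen-Shannon divergence between two Gaussians, in bits.

    The JSD is the average Kullback-Leibler divergence of each
    distribution from their equal-weight mixture. With base-2 logarithms
    its supremum is exactly 1 (disjoint supports), so the estimate is
    clipped to [0, 1]. There is no closed form for Gaussians, hence the
    seeded Monte-Carlo estimator: ``mc_samples`` draws from each Gaussian,
    scoring the mixture density with log-sum-exp.

    The construction is symmetric in (g1, g2) by design, so
    ``jsd(a, b) == jsd(b, a)`` exactly for the same seed.
    """
    if mc_samples < 1:
        raise ValueError("mc_samples must be >= 1")
    # canonical order makes the estimator exactly symmetric
    pair = sorted([g1, g2], key=lambda g: tuple(g.mean) + (float(np.sum(g.cov)),))
    m1, m2 = _MVN(pair[0]), _MVN(pair[1])
    rng = np.random.default_rng(seed)
    total = 0.0
    for m_self, m_other in ((m1, m2), (m2, m1)):
        x = m_self.sample(mc_samples, rng)
        lp_self = _mvn_logpdf(m_self, x)
        lp_other = _mvn_logpdf(m_other, x)
        log_mix = np.logaddexp(lp_self, lp_other) - np.log(2.0)
        total += 0.5 * float(np.mean(lp_self - log_mix)) / LOG2
    return float(np.clip(total, 0.0, 1.0))


@dataclass
class CsiResult:
    """Cluster separation index with its pairwise JSD matrix."""

    csi: float
    pairwise_jsd: pd.DataFrame
    mc_samples: int
    seed: int


def csi(c: ClusterSet, mc_samples: int = 100_000, seed: int = 0) -> CsiResult:
    """Cluster separation index: mean of all pairwise inter-cluster JSDs."""
    labels = c.labels
    if len(labels) < 2:
        raise ValueError("CSI needs at least 2 state clusters")
    jsd_mat = pd.DataFrame(0.0, index=labels, columns=labels)
    ss = np.random.SeedSequence(seed)
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    child_seeds = ss.generate_state(len(pairs)) % (2**31)
    vals = []
    for (i, j), s in zip(pairs, child_seeds):
        v = jsd_gaussian(c[labels[i]], c[labels[j]], mc_samples=mc_samples, seed=int(s))
        jsd_mat.iloc[i, j] = jsd_mat.iloc[j, i] = v
        vals.append(v)
    return CsiResult(
        csi=float(np.mean(vals)), pairwise_jsd=jsd_mat,
        mc_samples=mc_samples, seed=seed,
    )


# ---------------------------------------------------------------------------
# nearest-cluster classification


def _centroids(train: StateTrajectory) -> tuple[list, np.ndarray]:
    members = _label_members(train.labels)
    labels = sorted(members)
    if len(labels) < 2:
        raise ValueError("training labels must cover at least 2 classes")
    cents = np.stack([train.coords[members[lab]].mean(axis=0) for lab in labels])
    return labels, cents


def classify_states(
    train: StateTrajectory,
    test: StateTrajectory,
    metric: str = "euclidean",
    shrinkage: float = 0.05,
) -> list[str]:
    """Assign each test TR the label of its nearest training cluster.

    Distance is Euclidean to the cluster centroid by default; with
    ``metric="mahalanobis"`` each cluster's shrunk covariance whitens its
    own distance. Exact ties resolve to the lexicographically first label.
    """
    labels, cents = _centroids(train)
    if metric == "euclidean":
        d2 = ((test.coords[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    elif metric == "mahalanobis":
        from scipy.linalg import solve_triangular

        cs = fit_cluster_gaussians(train, shrinkage=shrinkage)
        d2 = np.empty((test.n_trs, len(labels)))
        for k, lab in enumerate(labels):
            m = _MVN(cs[lab], what=f"cluster '{lab}'")
            sol = solve_triangular(m.chol, (test.coords - m.mean).T, lower=True)
            d2[:, k] = (sol**2).sum(axis=0)
    else:
        raise ValueError(f"unknown metric '{metric}'")
    # argmin returns the first (lexicographically smallest) label on ties
    return [labels[k] for k in np.argmin(d2, axis=1)]


@dataclass
class ClassificationResult:
    """Cross-validated nearest-cluster decoding summary.

    ``confusion`` counts each test TR once per held label (rows: true
    label, columns: predicted), so row sums equal per-label test counts
    and ``balanced_accuracy`` is the mean per-class recall under the
    multi-label correctness rule.
    """

    fold_accuracies: list
    mean_accuracy: float
    balanced_accuracy: float
    confusion: pd.DataFrame
    n_labels: int
    chance: float
    fold_balanced_accuracies: list = field(default_factory=list)


def balanced_accuracy(confusion) -> float:
    """Mean per-class recall from a (true x predicted) confusion matrix."""
    conf = np.asarray(confusion, dtype=float)
    row_sums = conf.sum(axis=1)
    if np.any(row_sums == 0):
        empty = np.flatnonzero(row_sums == 0)
        names = (
            [confusion.index[i] for i in empty]
            if isinstance(confusion, pd.DataFrame)
            else list(empty)
        )
        raise ValueError(f"true class(es) with no test instances: {names}")
    return float(np.mean(np.diag(conf) / row_sums))


def _contiguous_folds(n: int, folds: int) -> list[np.ndarray]:
    edges = np.linspace(0, n, folds + 1).astype(int)
    return [np.arange(a, b) for a, b in zip(edges, edges[1:])]


def _stratified_folds(labels, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled folds dealing each primary label round-robin across folds."""
    by_label: dict = {}
    for i, labs in enumerate(labels):
        key = labs[0] if labs else ""
        by_label.setdefault(key, []).append(i)
    assignment = np.empty(len(labels), dtype=int)
    offset = 0
    for key in sorted(by_label):
        idx = np.array(by_label[key])
        rng.shuffle(idx)
        assignment[idx] = (np.arange(idx.size) + offset) % folds
        offset += idx.size
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def crossval_classify(
    x: TaskDesign,
    y: ActivityMatrix,
    labels=None,
    folds: int = 10,
    balanced: bool = True,
    seed: int = 0,
    n_components: int = 24,
    metric: str = "euclidean",
    fold_scheme: str = "contiguous",
    on_missing_class: str = "stratify",
) -> ClassificationResult:
    """Cross-validated state decoding with the full pipeline refit per fold.

    In each fold the held-out TRs are set aside, the state space is
    learned from the remaining TRs only (OLS fit, PCA denoiser, QR basis,
    cluster centroids), and each held-out TR is projected into that space
    and assigned to the nearest cluster. Folds are contiguous temporal
    blocks by default. If a contiguous split leaves some state absent from
    a training fold, behavior follows ``on_missing_class``: "stratify"
    rebuilds the folds as a seeded label-stratified shuffle, "error"
    raises.

    ``chance`` is 1 / n_labels. ``balanced`` additionally reports the mean
    per-class recall (from the pooled confusion matrix and per fold).
    """
    labels = normalize_labels(labels if labels is not None else x.labels)
    if len(labels) != y.n_trs:
        raise ValueError("labels length must match number of TRs")
    if folds > y.n_trs:
        raise ValueError(f"folds={folds} exceeds number of TRs {y.n_trs}")
    all_states = sorted({lab for labs in labels for lab in labs})
    if len(all_states) < 2:
        raise ValueError("need at least 2 distinct state labels")

    rng = np.random.default_rng(seed)
    if fold_scheme == "contiguous":
        fold_list = _contiguous_folds(y.n_trs, folds)
    elif fold_scheme == "stratified":
        fold_list = _stratified_folds(labels, folds, rng)
    else:
        raise ValueError(f"unknown fold_scheme '{fold_scheme}'")

    def _covers_all(fold_list):
        for test_idx in fold_list:
            mask = np.ones(y.n_trs, dtype=bool)
            mask[test_idx] = False
            seen = {lab for i in np.flatnonzero(mask) for lab in labels[i]}
            if set(all_states) - seen:
                return False
        return True

    if not _covers_all(fold_list):
        if on_missing_class == "stratify" and fold_scheme != "stratified":
            fold_list = _stratified_folds(labels, folds, rng)
        if not _covers_all(fold_list):
            raise ValueError(
                "some state label is absent from a training fold; use fewer "
                "folds or fold_scheme='stratified'"
            )

    confusion = pd.DataFrame(0, index=all_states, columns=all_states, dtype=int)
    fold_acc: list[float] = []
    fold_bal: list[float] = []
    for test_idx in fold_list:
        train_mask = np.ones(y.n_trs, dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        x_tr = x.subset(train_idx)
        y_tr = y.subset(train_idx)
        n_comp = min(n_components, len(train_idx), y.n_voxels)
        model = fit_state_space(x_tr, y_tr, n_components=n_comp)
        traj_tr = project(y_tr, model.basis_qs, model.variable_names,
                          labels=[labels[i] for i in train_idx])
        test_labeled = [i for i in test_idx if labels[i]]
        if not test_labeled:
            continue
        y_te = y.subset(test_labeled)
        traj_te = project(y_te, model.basis_qs, model.variable_names)
        preds = classify_states(traj_tr, traj_te, metric=metric)
        correct = 0
        fold_conf = pd.DataFrame(0, index=all_states, columns=all_states, dtype=int)
        for i, pred in zip(test_labeled, preds):
            true_set = labels[i]
            correct += pred in true_set
            for true_lab in true_set:
                fold_conf.loc[true_lab, pred] += 1
        confusion += fold_conf
        fold_acc.append(correct / len(test_labeled))
        present = fold_conf.sum(axis=1) > 0
        if balanced and present.any():
            fold_bal.append(balanced_accuracy(fold_conf.loc[present, :]))

    present = confusion.sum(axis=1) > 0
    bal = balanced_accuracy(confusion.loc[present, :]) if balanced else float("nan")
    return ClassificationResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        balanced_accuracy=bal,
        confusion=confusion,
        n_labels=len(all_states),
        chance=1.0 / len(all_states),
        fold_balanced_accuracies=fold_bal,
    )


def permuted_label_chance(
    t: StateTrajectory,
    n_permutations: int = 1000,
    seed: int = 0,
    train_fraction: float = 0.8,
    balanced: bool = False,
) -> float:
    """Empirical chance level of nearest-cluster decoding under label permutation.

    Per permutation, all state labels are shuffled across TRs, cluster
    centroids are fitted on the first ``train_fraction`` of TRs using the
    permuted labels, the remaining TRs are classified, and accuracy (or
    mean per-class recall when ``balanced``) is scored against the
    permuted labels — i.e. the decoding analysis run on its own null.
    Returns the mean over permutations; for K states this estimates the
    1/K chance level that any real decoding result must beat.
    """
    if not t.labels:
        raise ValueError("trajectory has no state labels")
    split = int(train_fraction * t.n_trs)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_permutations)
    for k in range(n_permutations):
        perm = permute_labels(t.labels, rng)
        train = StateTrajectory(t.coords[:split], t.dim_names, labels=perm[:split])
        test_labels = perm[split:]
        keep = [i for i, labs in enumerate(test_labels) if labs]
        test = StateTrajectory(t.coords[split:][keep], t.dim_names)
        preds = classify_states(train, test)
        truths = [test_labels[i] for i in keep]
        if balanced:
            recall: dict[str, list[bool]] = {}
            for pred, labs in zip(preds, truths):
                for lab in labs:
                    recall.setdefault(lab, []).append(pred == lab)
            scores[k] = np.mean([np.mean(v) for v in recall.values()])
        else:
            scores[k] = np.mean([p in labs for p, labs in zip(preds, truths)])
    return float(scores.mean())


# ---------------------------------------------------------------------------
# permutation testing


@dataclass
class PermutationResult:
    """One-sided permutation test with the add-one p convention."""

    observed: float
    null_values: np.ndarray
    p_value: float
    n_permutations: int
    seed: int


def permute_labels(
    labels, rng: np.random.Generator, permute_unit: str = "TR"
) -> list:
    """Uniformly permute per-TR label sets, per TR or in contiguous blocks.

    Block permutation treats each maximal run of identical label sets as a
    unit and shuffles the run order, preserving label dwell structure.
    """
    labels = list(labels)
    if permute_unit == "TR":
        idx = rng.permutation(len(labels))
        return [labels[i] for i in idx]
    if permute_unit == "block":
        blocks = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                blocks.append(labels[start:i])
                start = i
        order = rng.permutation(len(blocks))
        return [lab for bi in order for lab in blocks[bi]]
    raise ValueError(f"unknown permute_unit '{permute_unit}'")


def permutation_test(
    statistic,
    labels,
    n_permutations: int = 10_000,
    seed: int = 0,
    permute_unit: str = "TR",
) -> PermutationResult:
    """Permutation null for any label statistic; full analysis per permutation.

    ``statistic`` must be a pure function of the labels (with the data
    closed over), returning a scalar. The one-sided p-value uses the
    add-one convention ``p = (1 + #{null >= observed}) / (1 + n)``, so the
    smallest attainable p is ``1 / (n_permutations + 1)`` and p is never 0.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels = normalize_labels(labels)
    observed = float(statistic(labels))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        null[k] = statistic(permute_labels(labels, rng, permute_unit))
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_permutations)
    return PermutationResult(
        observed=observed, null_values=null, p_value=p,
        n_permutations=n_permutations, seed=seed,
    )


# ---------------------------------------------------------------------------
# cross-projection of states onto other state dimensions


@dataclass
class CrossProjectionResult:
    """Mean state-on-dimension projections with permutation significance.

    ``means[s, d]`` is the mean coordinate on dimension ``d`` over TRs
    labeled ``s``; correlated states show non-zero projections on each
    other's dimension, and the matrix need not be symmetric. ``significant``
    marks cells whose two-sided permutation p falls below the
    Bonferroni-corrected threshold ``alpha / n_cells``. States with no
    labeled TRs yield NaN rows, flagged in ``missing``.
    """

    means: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    n_permutations: int
    seed: int
    missing: tuple = ()


def cross_projection(
    t: StateTrajectory,
    labels=None,
    states=None,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
) -> CrossProjectionResult:
    """Mean projection of each state on every state dimension, with nulls.

    Significance per cell: label sets are permuted across TRs (keeping
    each TR's set intact), the mean matrix recomputed per permutation, and
    a two-sided add-one p compares |observed| with |null|; the threshold
    is Bonferroni corrected over non-missing cells.
    """
    labels = normalize_labels(labels if labels is not None else t.labels)
    if len(labels) != t.n_trs:
        raise ValueError("labels length must match trajectory length")
    state_list = list(states) if states is not None else sorted(
        {lab for labs in labels for lab in labs}
    )
    dims = list(t.dim_names)
    # membership matrix: TRs x states
    member = np.zeros((t.n_trs, len(state_list)))
    index = {s: k for k, s in enumerate(state_list)}
    for i, labs in enumerate(labels):
        for lab in labs:
            if lab in index:
                member[i, index[lab]] = 1.0
    counts = member.sum(axis=0)
    missing = tuple(s for s, c in zip(state_list, counts) if c == 0)
    safe = np.where(counts > 0, counts, 1.0)

    def mean_matrix(mem: np.ndarray) -> np.ndarray:
        m = (mem.T @ t.coords) / safe[:, None]
        m[counts == 0] = np.nan
        return m

    obs = mean_matrix(member)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_permutations):
        perm = rng.permutation(t.n_trs)
        null = mean_matrix(member[perm])
        exceed += np.abs(null) >= np.abs(obs)
    p = (1.0 + exceed) / (1.0 + n_permutations)
    p[np.isnan(obs)] = np.nan
    n_cells = int(np.isfinite(obs).sum())
    sig = p < (alpha / max(n_cells, 1))

    return CrossProjectionResult(
        means=pd.DataFrame(obs, index=state_list, columns=dims),
        p_values=pd.DataFrame(p, index=state_list, columns=dims),
        significant=pd.DataFrame(sig, index=state_list, columns=dims),
        alpha=alpha,
        n_permutations=n_permutations,
        seed=seed,
        missing=missing,
    )
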