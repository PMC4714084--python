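"""Discriminant analysis of principal components (DAPC) and PGMPs.

The classifier works in two stages: features are centred and reduced to
``n_pca`` principal components, then linear discriminant axes are found
that maximise the between-group to pooled-within-group variance ratio in
that reduced space. Group centroids are stored in *whitened* discriminant
coordinates (pooled within-group covariance = identity), so the posterior
group membership probability of a specimen is the homoscedastic Gaussian
posterior

    PGMP(g) ∝ prior(g) · exp(−½ · d²(x, centroid_g)),

with ``d`` the Euclidean distance in discriminant space; rows normalise
to 1. The number of retained PCs is chosen by replicated stratified
cross-validation: at each candidate retention level the model is refit on
90% training splits and scored by the fraction of held-out specimens
whose highest PGMP matches their prior label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PcaResult:
    """Principal component decomposition of a centred feature matrix."""

    scores: np.ndarray  # (n, r)
    loadings: np.ndarray  # (p, r), orthonormal columns
    explained_variance_fraction: np.ndarray  # (r,)


@dataclass
class DapcModel:
    """A fitted DAPC classifier.

    ``pc_basis`` maps centred features to the retained-PC space;
    ``disc_axes`` maps PC scores to whitened discriminant coordinates in
    which the pooled within-group covariance is the identity.
    """

    n_pca: int
    n_da: int
    feature_means: np.ndarray  # (p,)
    pc_basis: np.ndarray  # (p, n_pca)
    disc_axes: np.ndarray  # (n_pca, n_da)
    centroids: np.ndarray  # (g, n_da), whitened discriminant space
    priors: np.ndarray  # (g,)
    groups: list  # group labels, order matches centroids/priors
    feature_kind: str = "landmarks"

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        if np.any(self.priors <= 0) or abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must be positive and sum to 1")
        if self.n_da > len(self.groups) - 1:
            raise ValueError("n_da must be ≤ number of groups − 1")

    def transform(self, features: np.ndarray) -> np.ndarray:
        """Project raw features into whitened discriminant coordinates."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.feature_means.shape[0]:
            raise ValueError(
                f"feature dimension mismatch: model expects "
                f"{self.feature_means.shape[0]}, got {features.shape[1]}"
            )
        return (features - self.feature_means) @ self.pc_basis @ self.disc_axes

    def to_dict(self) -> dict:
        return {
            "n_pca": self.n_pca,
            "n_da": self.n_da,
            "feature_means": self.feature_means.tolist(),
            "pc_basis": self.pc_basis.tolist(),
            "disc_axes": self.disc_axes.tolist(),
            "centroids": self.centroids.tolist(),
            "priors": self.priors.tolist(),
            "groups": list(self.groups),
            "feature_kind": self.feature_kind,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DapcModel":
        return cls(
            n_pca=int(d["n_pca"]),
            n_da=int(d["n_da"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            pc_basis=np.asarray(d["pc_basis"], dtype=float),
            disc_axes=np.asarray(d["disc_axes"], dtype=float),
            centroids=np.asarray(d["centroids"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
            groups=list(d["groups"]),
            feature_kind=d.get("feature_kind", "landmarks"),
        )


@dataclass
class CrossvalReport:
    """Cross-validation summary for PC-retention choice."""

    pc_grid: list
    mean_success: dict  # grid level -> mean held-out success
    success_sd: dict  # grid level -> SD across replicates
    chosen_n_pca: int
    pgmp: pd.DataFrame  # per-specimen averaged held-out PGMPs
    replicate_counts: pd.Series  # times each specimen was held out
    replicates: int

    def to_dict(self) -> dict:
        return {
            "pc_grid": list(self.pc_grid),
            "mean_success": {str(k): v for k, v in self.mean_success.items()},
            "success_sd": {str(k): v for k, v in self.success_sd.items()},
            "chosen_n_pca": self.chosen_n_pca,
            "replicates": self.replicates,
        }


def center_features(matrix: np.ndarray, scale: bool = False):
    """Centre columns to zero mean; optionally scale to unit variance.

    Returns ``(centered, means)`` or ``(centered, means, sds)`` when
    scaling. Scaling a constant column is an error.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to centre")
    means = matrix.mean(axis=0)
    centered = matrix - means
    if not scale:
        return centered, means
    sds = centered.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("cannot scale constant columns")
    return centered / sds, means, sds


def pca(matrix: np.ndarray, r: int | None = None) -> PcaResult:
    """PCA of an already-centred matrix via SVD.

    ``r`` defaults to the matrix rank; requesting more axes than the rank
    is an error. Explained fractions are eigenvalues over their total.
    """
    matrix = np.asarray(matrix, dtype=float)
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    tol = s.max(initial=0.0) * max(matrix.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if r is None:
        r = rank
    if not 1 <= r <= rank:
        raise ValueError(f"r must be in [1, rank]; rank is {rank}, got {r}")
    eigvals = s**2
    total = eigvals.sum()
    return PcaResult(
        scores=u[:, :r] * s[:r],
        loadings=vt[:r].T,
        explained_variance_fraction=eigvals[:r] / total,
    )


def _pooled_within_cov(scores: np.ndarray, codes: np.ndarray, g: int) -> np.ndarray:
    n, r = scores.shape
    w = np.zeros((r, r))
    for gi in range(g):
        sub = scores[codes == gi]
        dev = sub - sub.mean(axis=0)
        w += dev.T @ dev
    return w / (n - g)


def fit_dapc(
    features: np.ndarray,
    labels,
    n_pca: int,
    n_da: int | None = None,
    priors: str = "proportional",
    feature_kind: str = "landmarks",
) -> DapcModel:
    """Fit a DAPC model.

    Every group needs ≥ 2 members; ``n_pca ≤ min(n − g, p)``. Priors are
    group proportions by default (``priors='uniform'`` for equal priors).
    Within-group covariance is pooled across groups (homoscedastic).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    groups, codes = np.unique(labels, return_inverse=True)
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    small = groups[counts < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 members: {list(small)}")
    n, p = features.shape
    max_pca = min(n - g, p)
    if not 1 <= n_pca <= max_pca:
        raise ValueError(f"n_pca must be in [1, {max_pca}], got {n_pca}")
    if n_da is None:
        n_da = g - 1
    n_da = min(n_da, g - 1)

    centered, means = center_features(features)
    pc = pca(centered, r=min(n_pca, np.linalg.matrix_rank(centered)))
    basis = pc.loadings  # (p, n_pca')
    scores = pc.scores
    n_pca_eff = basis.shape[1]
    n_da = min(n_da, n_pca_eff)

    # whiten by the pooled within-group covariance, then diagonalize the
    # between-group scatter of the whitened group means
    w = _pooled_within_cov(scores, codes, g)
    evals, evecs = np.linalg.eigh(w)
    floor = max(evals.max(), 1.0) * 1e-10
    evals = np.maximum(evals, floor)
    whiten = evecs @ np.diag(evals**-0.5)  # (n_pca, n_pca)

    grand = scores.mean(axis=0)
    b = np.zeros((n_pca_eff, n_pca_eff))
    for gi in range(g):
        diff = scores[codes == gi].mean(axis=0) - grand
        b += counts[gi] * np.outer(diff, diff)
    b_w = whiten.T @ b @ whiten
    bvals, bvecs = np.linalg.eigh(b_w)
    order = np.argsort(bvals)[::-1][:n_da]
    axes = whiten @ bvecs[:, order]  # (n_pca, n_da); whitened coords

    disc = scores @ axes
    centroids = np.stack([disc[codes == gi].mean(axis=0) for gi in range(g)])
    if priors == "proportional":
        pr = counts / counts.sum()
    elif priors == "uniform":
        pr = np.full(g, 1.0 / g)
    else:
        raise ValueError(f"unknown priors {priors!r}")

    return DapcModel(
        n_pca=n_pca_eff,
        n_da=n_da,
        feature_means=means,
        pc_basis=basis,
        disc_axes=axes,
        centroids=centroids,
        priors=pr,
        groups=[str(gr) for gr in groups],
        feature_kind=feature_kind,
    )


def posterior_memberships(
    model: DapcModel, features: np.ndarray, specimen_ids=None
) -> pd.DataFrame:
    """PGMP table (specimens × groups); every row sums to 1.

    PGMP(g) ∝ prior(g)·exp(−½·d²) with d Euclidean in the model's
    whitened discriminant space.
    """
    disc = model.transform(features)
    d2 = ((disc[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    log_post = np.log(model.priors)[None, :] - 0.5 * d2
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    index = (
        pd.Index(specimen_ids, name="specimen_id")
        if specimen_ids is not None
        else pd.RangeIndex(disc.shape[0], name="specimen_id")
    )
    return pd.DataFrame(post, index=index, columns=list(model.groups))


def default_pc_grid(n: int, g: int, p: int, step: int = 5) -> list[int]:
    """Candidate PC counts {step, 2·step, …} capped at min(n − g, p)."""
    cap = min(n - g, p)
    grid = list(range(step, cap + 1, step))
    if not grid and cap >= 1:
        grid = [cap]
    return grid


def _stratified_split(codes: np.ndarray, train_fraction: float, rng) -> np.ndarray:
    """Boolean train mask; per group, round to nearest with ≥1 held out
    and ≥2 kept for training whenever the group allows it."""
    n = codes.shape[0]
    mask = np.zeros(n, dtype=bool)
    for gi in np.unique(codes):
        idx = np.flatnonzero(codes == gi)
        n_g = len(idx)
        n_train = int(round(train_fraction * n_g))
        n_train = min(n_train, n_g - 1) if n_g > 2 else min(n_train, n_g)
        n_train = max(n_train, min(2, n_g))
        chosen = rng.choice(idx, size=n_train, replace=False)
        mask[chosen] = True
    return mask


def crossval_dapc(
    features: np.ndarray,
    labels,
    pc_grid=None,
    replicates: int = 1000,
    train_fraction: float = 0.9,
    seed: int | None = None,
    specimen_ids=None,
    priors: str = "proportional",
) -> CrossvalReport:
    """Replicated stratified cross-validation over PC retention levels.

    For each level of ``pc_grid``, ``replicates`` stratified
    ``train_fraction`` splits are fit and scored on the held-out
    specimens (success = highest PGMP matches the prior label). The
    chosen ``n_pca`` maximises mean success, ties going to fewer PCs.
    Held-out PGMPs at the chosen level are averaged per specimen over all
    replicates in which it was held out. All randomness flows from
    ``seed``; infeasible grid levels are skipped with a warning.
    """
    import warnings

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    groups, codes = np.unique(labels, return_inverse=True)
    g = len(groups)
    n, p = features.shape
    if specimen_ids is None:
        specimen_ids = [str(i) for i in range(n)]

    if pc_grid is None:
        pc_grid = default_pc_grid(n, g, p)
    # the training split keeps ~train_fraction of each group
    min_train = min(
        max(
            min(2, c),
            min(int(round(train_fraction * c)), c - 1) if c > 2 else int(round(train_fraction * c)),
        )
        for c in np.bincount(codes)
    )
    if min_train < 2:
        raise ValueError("every group must keep ≥ 2 training members per split")
    feasible = []
    for level in pc_grid:
        # bound uses the smallest training set the splits can produce
        cap = min(n - g, p)
        if 1 <= level <= cap:
            feasible.append(int(level))
        else:
            warnings.warn(f"skipping infeasible PC retention level {level}")
    if not feasible:
        raise ValueError("no feasible PC retention level in the grid")

    rng = np.random.default_rng(seed)
    # one independent child stream per replicate, shared across grid levels
    # so levels are compared on identical splits
    split_seeds = rng.integers(0, 2**31 - 1, size=replicates)

    mean_success: dict[int, float] = {}
    success_sd: dict[int, float] = {}
    per_level_success: dict[int, np.ndarray] = {}
    for level in feasible:
        succ = np.empty(replicates)
        for rep in range(replicates):
            rep_rng = np.random.default_rng(split_seeds[rep])
            train = _stratified_split(codes, train_fraction, rep_rng)
            if train.all():  # tiny groups: nothing held out, skip replicate
                succ[rep] = np.nan
                continue
            n_tr = int(train.sum())
            lvl = min(level, n_tr - g, p)
            if lvl < 1:
                succ[rep] = np.nan
                continue
            model = fit_dapc(
                features[train], labels[train], n_pca=lvl, priors=priors
            )
            post = posterior_memberships(model, features[~train])
            pred = post.to_numpy().argmax(axis=1)
            truth = np.array(
                [list(model.groups).index(str(groups[c])) if str(groups[c]) in model.groups else -1
                 for c in codes[~train]]
            )
            succ[rep] = float(np.mean(pred == truth))
        valid = succ[~np.isnan(succ)]
        mean_success[level] = float(valid.mean()) if len(valid) else float("nan")
        success_sd[level] = float(valid.std(ddof=1)) if len(valid) > 1 else 0.0
        per_level_success[level] = succ

    # highest mean success; ties → fewest PCs (iterate ascending, strict >)
    chosen = feasible[0]
    best = -np.inf
    for level in sorted(feasible):
        if mean_success[level] > best + 1e-12:
            best = mean_success[level]
            chosen = level

    # averaged held-out PGMPs at the chosen level, same replicate streams
    group_names = [str(gr) for gr in groups]
    pgmp_sum = pd.DataFrame(0.0, index=pd.Index(specimen_ids, name="specimen_id"),
                            columns=group_names)
    held_counts = pd.Series(0, index=pgmp_sum.index, dtype=int)
    ids_arr = np.asarray(specimen_ids)
    for rep in range(replicates):
        rep_rng = np.random.default_rng(split_seeds[rep])
        train = _stratified_split(codes, train_fraction, rep_rng)
        if train.all():
            continue
        n_tr = int(train.sum())
        lvl = min(chosen, n_tr - g, p)
        if lvl < 1:
            continue
        model = fit_dapc(features[train], labels[train], n_pca=lvl, priors=priors)
        post = posterior_memberships(model, features[~train])
        held_ids = ids_arr[~train]
        for col_i, col in enumerate(model.groups):
            pgmp_sum.loc[held_ids, col] += post.to_numpy()[:, col_i]
        held_counts.loc[held_ids] += 1

    seen = held_counts > 0
    pgmp = pgmp_sum.copy()
    pgmp.loc[seen] = pgmp_sum.loc[seen].div(held_counts[seen], axis=0)
    pgmp.loc[~seen] = np.nan

    return CrossvalReport(
        pc_grid=feasible,
        mean_success=mean_success,
        success_sd=success_sd,
        chosen_n_pca=chosen,
        pgmp=pgmp,
        replicate_counts=held_counts,
        replicates=replicates,
    )
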