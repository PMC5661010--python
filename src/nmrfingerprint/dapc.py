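"""Discriminant analysis of principal components (DAPC).

DAPC reduces the autoscaled bucket table with PCA, fits a linear discriminant
analysis on the retained principal-component scores, and assigns samples to
groups by Gaussian posterior membership in discriminant space.  With g groups
at most g − 1 discriminant axes exist, so the 4-group conformation design
always yields 3 axes.  Variable (bucket) contributions are obtained by
back-projecting the discriminant axes through the PCA basis, squaring and
normalizing; the number of retained PCs is chosen by repeated stratified
cross-validation of held-out assignment accuracy.

The implementation is self-contained linear algebra (SVD for the PCA step, a
generalized symmetric eigenproblem for the discriminant step); external
discriminant implementations are used only as cross-check oracles in the test
suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .data_model import BucketTable
from .preprocess import autoscale

__all__ = [
    "PCABasis",
    "DAPCModel",
    "XvalResult",
    "pca_fit",
    "lda_fit",
    "dapc_fit",
    "dapc_assign",
    "reclassification_accuracy",
    "xval_select_npca",
    "var_contributions",
    "top_contributors",
    "save_model",
]

logger = logging.getLogger(__name__)

_COND_LIMIT = 1e10
_RIDGE_EPS = 1e-8


@dataclass
class PCABasis:
    """Orthonormal PCA loadings with eigenvalues in variance units."""

    loadings: np.ndarray        # (n_features, n_retained), orthonormal columns
    eigenvalues: np.ndarray     # nonincreasing, = singular_value^2 / (n - 1)
    center: np.ndarray
    scale: np.ndarray
    n_retained: int


@dataclass
class DAPCModel:
    pca: PCABasis
    ld_axes: np.ndarray             # (n_retained_pcs, n_ld)
    ld_eigenvalues: np.ndarray      # between/within variance ratios, nonincreasing
    group_means: dict[str, np.ndarray]   # in LD space
    pooled_cov: np.ndarray          # LD space, ~identity under the axis scaling
    groups: list[str]
    bucket_ids: list[str]           # buckets retained after autoscaling
    var_contrib: np.ndarray         # (n_buckets, n_ld), columns sum to 1
    var_contrib_total: np.ndarray   # sums to 1

    @property
    def n_ld(self) -> int:
        return self.ld_axes.shape[1]


@dataclass
class XvalResult:
    grid: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    chosen_n_pca: int
    n_reps: int
    train_fraction: float
    seed: int


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive (deterministic
    orientation across runs and BLAS builds)."""
    V = V.copy()
    for j in range(V.shape[1]):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    return V


def pca_fit(X: np.ndarray, n_max: int) -> "PCABasis":
    """PCA of an already centered/scaled matrix via SVD.

    Eigenvalue k equals (singular value k)² / (n − 1).  ``center`` and
    ``scale`` are filled by :func:`dapc_fit`; direct callers get identity
    scaling.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= n_max <= min(n - 1, p):
        raise ValueError(
            f"n_max={n_max} out of range [1, {min(n - 1, p)}] for shape {X.shape}"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = _fix_signs(Vt[:n_max].T)
    eigenvalues = (s[:n_max] ** 2) / (n - 1)
    return PCABasis(
        loadings=loadings,
        eigenvalues=eigenvalues,
        center=np.zeros(p),
        scale=np.ones(p),
        n_retained=n_max,
    )


def _scatter_matrices(
    scores: np.ndarray, labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, np.ndarray]]:
    labels = list(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("LDA requires at least 2 groups")
    p = scores.shape[1]
    grand = scores.mean(axis=0)
    S_w = np.zeros((p, p))
    S_b = np.zeros((p, p))
    means: dict[str, np.ndarray] = {}
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        Xg = scores[idx]
        mg = Xg.mean(axis=0)
        means[g] = mg
        D = Xg - mg
        S_w += D.T @ D
        dm = (mg - grand)[:, None]
        S_b += len(idx) * (dm @ dm.T)
    return S_w, S_b, groups, means


def lda_fit(
    scores: np.ndarray, labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """Linear discriminant analysis of PC scores.

    Solves the generalized eigenproblem ``S_b v = λ S_w v`` on the between-
    and within-group scatter of the scores; returns min(g − 1, n_pcs) axes in
    order of decreasing λ, each scaled to unit pooled within-group variance
    (``vᵀ S_w v / (n − g) = 1``).  A small ridge is added to S_w when it is
    numerically singular.

    Returns
    -------
    (ld_axes, ld_eigenvalues, group_means in LD space, pooled covariance in
    LD space)
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    S_w, S_b, groups, _ = _scatter_matrices(scores, labels)
    g = len(groups)
    p = scores.shape[1]

    cond = np.linalg.cond(S_w)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        ridge = _RIDGE_EPS * np.trace(S_w) / p
        if ridge <= 0:
            ridge = _RIDGE_EPS
        S_w = S_w + ridge * np.eye(p)
        logger.debug("regularized within scatter (cond=%.3g, ridge=%.3g)", cond, ridge)

    eigvals, eigvecs = scipy.linalg.eigh(S_b, S_w)
    order = np.argsort(eigvals)[::-1]
    n_ld = min(g - 1, p)
    eigvals = np.maximum(eigvals[order[:n_ld]], 0.0)
    W = eigvecs[:, order[:n_ld]]
    # unit pooled within-group variance along every axis
    for j in range(n_ld):
        wv = float(W[:, j] @ S_w @ W[:, j]) / (n - g)
        W[:, j] /= np.sqrt(wv)
    W = _fix_signs(W)

    ld_means = {}
    labels = list(labels)
    Z = scores @ W
    for grp in groups:
        idx = [i for i, l in enumerate(labels) if l == grp]
        ld_means[grp] = Z[idx].mean(axis=0)
    pooled = np.zeros((n_ld, n_ld))
    for grp in groups:
        idx = [i for i, l in enumerate(labels) if l == grp]
        D = Z[idx] - ld_means[grp]
        pooled += D.T @ D
    pooled /= (n - g)
    return W, eigvals, ld_means, pooled


def var_contributions(
    pca_loadings: np.ndarray, ld_axes: np.ndarray, ld_eigenvalues: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Back-project discriminant axes to bucket space and square-normalize.

    The original-space discriminant loading is ``L = P W``; per-axis
    contributions are ``L²`` column-normalized to sum to 1, and the total is
    their average weighted by each axis's share of discriminatory power
    (eigenvalue share).
    """
    L = pca_loadings @ ld_axes
    per_axis = L ** 2
    col_sums = per_axis.sum(axis=0)
    if np.any(col_sums <= 0):
        raise ValueError("degenerate discriminant axis with zero loading norm")
    per_axis = per_axis / col_sums
    weights = ld_eigenvalues / ld_eigenvalues.sum() if ld_eigenvalues.sum() > 0 else (
        np.full(len(ld_eigenvalues), 1.0 / len(ld_eigenvalues))
    )
    total = per_axis @ weights
    return per_axis, total


def dapc_fit(
    table: BucketTable,
    labels: Mapping[str, str],
    n_pca: int,
    n_ld: int | None = None,
) -> DAPCModel:
    """Fit the full DAPC pipeline: autoscale → PCA → LDA on retained scores."""
    missing = [s for s in table.samples if s not in labels]
    if missing:
        raise ValueError(f"labels missing for samples {missing[:3]}")
    y = [labels[s] for s in table.samples]
    Z, means, sds, kept = autoscale(table)
    basis = pca_fit(Z, n_pca)
    basis.center = means
    basis.scale = sds
    scores = Z @ basis.loadings
    W, eigvals, ld_means, pooled = lda_fit(scores, y)
    if n_ld is not None:
        if n_ld > W.shape[1]:
            raise ValueError(f"n_ld={n_ld} exceeds available axes {W.shape[1]}")
        W = W[:, :n_ld]
        eigvals = eigvals[:n_ld]
        ld_means = {g: m[:n_ld] for g, m in ld_means.items()}
        pooled = pooled[:n_ld, :n_ld]
    per_axis, total = var_contributions(basis.loadings, W, eigvals)
    bucket_ids = [b.bucket_id for b, k in zip(table.buckets, kept) if k]
    return DAPCModel(
        pca=basis,
        ld_axes=W,
        ld_eigenvalues=eigvals,
        group_means=ld_means,
        pooled_cov=pooled,
        groups=sorted(set(y)),
        bucket_ids=bucket_ids,
        var_contrib=per_axis,
        var_contrib_total=total,
    )


def _project(model: DAPCModel, table: BucketTable) -> np.ndarray:
    ids = table.bucket_ids
    missing = [b for b in model.bucket_ids if b not in ids]
    if missing:
        raise ValueError(f"new data is missing model buckets {missing[:5]}")
    idx = [ids.index(b) for b in model.bucket_ids]
    X = table.values[:, idx]
    Z = (X - model.pca.center) / model.pca.scale
    return (Z @ model.pca.loadings) @ model.ld_axes


def dapc_assign(
    model: DAPCModel, table: BucketTable
) -> tuple[np.ndarray, list[str]]:
    """Posterior group membership in discriminant space.

    Gaussian class-conditional densities with the shared pooled covariance
    and equal priors (the study design is balanced); posterior rows sum to 1
    and the predicted label is the argmax, ties broken by group order.
    """
    Z = _project(model, table)
    g = len(model.groups)
    prec = np.linalg.inv(model.pooled_cov)
    log_dens = np.empty((Z.shape[0], g))
    for j, grp in enumerate(model.groups):
        D = Z - model.group_means[grp]
        log_dens[:, j] = -0.5 * np.einsum("ij,jk,ik->i", D, prec, D)
    log_dens -= log_dens.max(axis=1, keepdims=True)
    post = np.exp(log_dens)
    post /= post.sum(axis=1, keepdims=True)
    pred = [model.groups[int(np.argmax(row))] for row in post]
    return post, pred


def reclassification_accuracy(
    model: DAPCModel, table: BucketTable, labels: Mapping[str, str]
) -> tuple[float, dict[str, float]]:
    """Fraction of samples the fitted model assigns back to their true group."""
    _, pred = dapc_assign(model, table)
    truth = [labels[s] for s in table.samples]
    hits = np.array([p == t for p, t in zip(pred, truth)])
    per_group = {}
    for grp in sorted(set(truth)):
        idx = [i for i, t in enumerate(truth) if t == grp]
        per_group[grp] = float(hits[idx].mean())
    return float(hits.mean()), per_group


def _stratified_split(
    samples: Sequence[str],
    labels: Mapping[str, str],
    train_fraction: float,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    by_group: dict[str, list[str]] = {}
    for s in samples:
        by_group.setdefault(labels[s], []).append(s)
    train: list[str] = []
    test: list[str] = []
    for grp in sorted(by_group):
        members = list(by_group[grp])
        if len(members) < 2:
            raise ValueError(f"group {grp!r} too small to stratify (needs >= 2 samples)")
        k = int(np.floor(train_fraction * len(members)))
        k = min(max(k, 1), len(members) - 1)   # at least 1 held out, 1 trained
        perm = rng.permutation(len(members))
        train += [members[i] for i in perm[:k]]
        test += [members[i] for i in perm[k:]]
    return train, test


def xval_select_npca(
    table: BucketTable,
    labels: Mapping[str, str],
    grid: Sequence[int],
    train_fraction: float = 0.9,
    n_reps: int = 30,
    seed: int = 0,
) -> XvalResult:
    """Choose the retained-PC count by repeated stratified cross-validation.

    For each repetition a stratified train/test split is drawn (shared across
    candidates, which removes split-to-split noise from the comparison); a
    DAPC is fitted on the training samples at every feasible candidate and
    held-out assignment accuracy recorded.  The candidate with the highest
    mean accuracy wins; ties go to the smaller count.
    """
    grid = sorted(set(int(g) for g in grid))
    if not grid:
        raise ValueError("empty candidate grid")
    rng = np.random.default_rng(seed)
    acc = np.full((len(grid), n_reps), np.nan)
    for rep in range(n_reps):
        train_ids, test_ids = _stratified_split(table.samples, labels, train_fraction, rng)
        train_tab = table.subset_samples(train_ids)
        test_tab = table.subset_samples(test_ids)
        truth = [labels[s] for s in test_ids]
        n_train = len(train_ids)
        for ci, cand in enumerate(grid):
            if cand > min(n_train - 1, table.n_buckets):
                continue
            try:
                model = dapc_fit(train_tab, labels, n_pca=cand)
            except ValueError:
                continue
            _, pred = dapc_assign(model, test_tab)
            acc[ci, rep] = float(np.mean([p == t for p, t in zip(pred, truth)]))
    mean_acc = np.nanmean(acc, axis=1)
    if np.all(np.isnan(mean_acc)):
        raise ValueError("no candidate PC count was feasible for the training size")
    sd_acc = np.nanstd(acc, axis=1, ddof=1)
    # highest mean accuracy, ties toward fewer PCs (grid is ascending)
    best = int(np.nanargmax(mean_acc))
    chosen = grid[best]
    return XvalResult(
        grid=np.asarray(grid),
        mean_accuracy=mean_acc,
        sd_accuracy=sd_acc,
        chosen_n_pca=int(chosen),
        n_reps=n_reps,
        train_fraction=train_fraction,
        seed=seed,
    )


def top_contributors(
    total: np.ndarray,
    bucket_ids: Sequence[str],
    fraction: float = 0.10,
    annotation: Mapping[str, str] | None = None,
) -> list[tuple[str, float, str | None]]:
    """Buckets carrying the top ``fraction`` of ranked contributions.

    Returns the ``ceil(fraction × n_buckets)`` highest-contribution buckets
    in descending order (boundary ties all included), each with its
    metabolite annotation where one exists.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    total = np.asarray(total, dtype=float)
    if len(total) != len(bucket_ids):
        raise ValueError("contribution vector and bucket IDs disagree in length")
    order = sorted(range(len(total)), key=lambda i: (-total[i], bucket_ids[i]))
    k = int(np.ceil(fraction * len(total)))
    cutoff = total[order[k - 1]]
    chosen = [i for i in order if total[i] > cutoff]
    chosen += [i for i in order if total[i] == cutoff]  # boundary ties all in
    annotation = annotation or {}
    return [
        (bucket_ids[i], float(total[i]), annotation.get(bucket_ids[i]))
        for i in chosen
    ]


def save_model(model: DAPCModel, path: str | Path) -> None:
    """Serialize a fitted model as structured text (JSON)."""
    payload = {
        "groups": model.groups,
        "bucket_ids": model.bucket_ids,
        "center": model.pca.center.tolist(),
        "scale": model.pca.scale.tolist(),
        "pca_loadings": model.pca.loadings.tolist(),
        "pca_eigenvalues": model.pca.eigenvalues.tolist(),
        "ld_axes": model.ld_axes.tolist(),
        "ld_eigenvalues": model.ld_eigenvalues.tolist(),
        "group_means": {g: m.tolist() for g, m in model.group_means.items()},
        "pooled_cov": model.pooled_cov.tolist(),
        "var_contrib_total": model.var_contrib_total.tolist(),
        "contribution_aggregation": "per-axis squared loadings weighted by LD eigenvalue share",
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")
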