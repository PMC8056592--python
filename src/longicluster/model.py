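"""Joint latent-variable clustering across longitudinal views.

The model treats each time point's genes x subjects expression matrix as one
"view" of the same subjects.  Stacking views row-wise gives a single factor
model with diagonal noise,

    x_i = W z_i + eps_i,       z_i ~ N(0, I_q),   eps_i ~ N(0, diag(psi)),

where ``x_i`` concatenates subject *i*'s standardized expression over all
views, ``W`` holds one loading row per (gene, view) feature and ``q = K - 1``
latent dimensions for ``K`` clusters.  Conditional independence of views given
the latent score makes the stacked model identical to per-view models sharing
``z_i``.  Parameters are estimated by EM; an optional soft-threshold step
shrinks small loadings exactly to zero, performing feature selection.  Cluster
labels come from k-means on the posterior latent means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.cluster import KMeans

PSI_FLOOR = 1e-4
_LOG_2PI = float(np.log(2.0 * np.pi))


def soft_threshold(w, lam: float):
    """Elementwise shrinkage ``sign(w) * max(|w| - lam, 0)``.

    Parameters
    ----------
    w : float or ndarray
        Value(s) to shrink.
    lam : float
        Non-negative shrinkage amount.
    """
    if lam < 0:
        raise ValueError(f"shrinkage parameter must be >= 0, got {lam}")
    w = np.asarray(w, dtype=float)
    out = np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)
    return float(out) if out.ndim == 0 else out


def e_step(X: np.ndarray, W: np.ndarray, psi: np.ndarray):
    """Posterior mean and covariance of the latent scores.

    With diagonal residual variance ``psi`` the factor-analysis posterior is

        VarZ = (I_q + W' diag(psi)^-1 W)^-1
        EZ   = VarZ W' diag(psi)^-1 X

    Returns ``(EZ, VarZ)`` with shapes ``(q, n)`` and ``(q, q)``.
    """
    X = np.asarray(X, float)
    W = np.asarray(W, float)
    psi = np.asarray(psi, float)
    if not (np.isfinite(X).all() and np.isfinite(W).all() and np.isfinite(psi).all()):
        raise ValueError("non-finite values in e_step inputs")
    if np.any(psi < PSI_FLOOR):
        raise ValueError(f"residual variances must be >= {PSI_FLOOR}")
    q = W.shape[1]
    Wp = W / psi[:, None]                      # diag(psi)^-1 W
    M = np.eye(q) + W.T @ Wp
    VarZ = np.linalg.inv(M)
    VarZ = 0.5 * (VarZ + VarZ.T)               # keep exactly symmetric
    EZ = VarZ @ (Wp.T @ X)
    return EZ, VarZ


def m_step(X: np.ndarray, EZ: np.ndarray, VarZ: np.ndarray):
    """EM update of loadings and residual variances.

    ``W_new = (X EZ') (n VarZ + EZ EZ')^-1``; the residual variance of each
    feature is its second moment minus the explained part, floored at
    ``PSI_FLOOR`` to prevent Heywood collapse.
    """
    X = np.asarray(X, float)
    EZ = np.atleast_2d(np.asarray(EZ, float))
    VarZ = np.atleast_2d(np.asarray(VarZ, float))
    n = X.shape[1]
    A = X @ EZ.T                               # (p, q)
    B = n * VarZ + EZ @ EZ.T                   # (q, q)
    try:
        W_new = np.linalg.solve(B.T, A.T).T
    except np.linalg.LinAlgError as exc:  # guarded; impossible for PD VarZ
        raise np.linalg.LinAlgError(
            "singular latent second-moment matrix in M-step") from exc
    second_moment = np.mean(X * X, axis=1)
    psi_new = second_moment - np.sum(W_new * A, axis=1) / n
    psi_new = np.maximum(psi_new, PSI_FLOOR)
    return W_new, psi_new


def _log_likelihood(X: np.ndarray, W: np.ndarray, psi: np.ndarray) -> float:
    """Observed-data log-likelihood under Sigma = W W' + diag(psi).

    Evaluated through the Woodbury identity so the cost is O(p n q) rather
    than O(p^3).
    """
    p, n = X.shape
    q = W.shape[1]
    Wp = W / psi[:, None]
    M = np.eye(q) + W.T @ Wp
    sign, logdet_M = np.linalg.slogdet(M)
    logdet = logdet_M + np.sum(np.log(psi))
    U = Wp.T @ X                               # (q, n)
    VarZ = np.linalg.inv(M)
    quad = np.sum(X * X / psi[:, None]) - np.sum(U * (VarZ @ U))
    return -0.5 * (n * p * _LOG_2PI + n * logdet + quad)


class ClusterAssignment(NamedTuple):
    labels: np.ndarray          # 1..K integers, length n
    degenerate: bool            # fewer than K distinct points/clusters


def _kmeans_1d(x: np.ndarray, K: int) -> np.ndarray:
    """Exact 1-D k-means via dynamic programming over contiguous splits.

    The optimal 1-D k-means partition is contiguous in sorted order, so the
    global optimum is found by an O(K n^2) DP; no restarts are needed.
    Returns 0-based labels in sorted-cluster order.
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    xs = x[order]
    c1 = np.concatenate([[0.0], np.cumsum(xs)])
    c2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def sse(i, j):  # cost of segment xs[i:j]
        m = j - i
        s = c1[j] - c1[i]
        return (c2[j] - c2[i]) - s * s / m

    INF = np.inf
    cost = np.full((K + 1, n + 1), INF)
    back = np.zeros((K + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, K + 1):
        for j in range(k, n + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                c = cost[k - 1, i] + sse(i, j)
                if c < best - 1e-15:
                    best, arg = c, i
            cost[k, j] = best
            back[k, j] = arg
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for k in range(K, 0, -1):
        i = back[k, j]
        labels_sorted[i:j] = k - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def assign_clusters(EZ: np.ndarray, K: int, seed: int = 0) -> ClusterAssignment:
    """Cluster subjects by their posterior latent scores.

    One latent dimension is solved exactly (the optimal 1-D k-means partition
    is contiguous in sorted order, so a dynamic program finds the global
    optimum deterministically); higher dimensions use seeded k-means with 10
    restarts.  Label identity is arbitrary — mapping clusters to outcome
    classes happens downstream.
    """
    EZ = np.atleast_2d(np.asarray(EZ, float))
    pts = EZ.T                                 # (n, q)
    n = pts.shape[0]
    if n < K:
        raise ValueError(f"need at least K={K} subjects, got {n}")
    distinct = np.unique(pts, axis=0).shape[0]
    if distinct < K:
        # all-identical (or too few distinct) points: collapse
        labels0 = np.zeros(n, dtype=int) if distinct == 1 else _collapse(pts)
        return ClusterAssignment(labels0 + 1, True)
    if pts.shape[1] == 1:
        labels0 = _kmeans_1d(pts[:, 0], K)
    else:
        km = KMeans(n_clusters=K, n_init=10, random_state=seed % (2**31))
        labels0 = km.fit_predict(pts)
    degenerate = np.unique(labels0).size < K
    return ClusterAssignment(labels0.astype(int) + 1, degenerate)


def _collapse(pts: np.ndarray) -> np.ndarray:
    """Label by distinct point identity when there are fewer points than K."""
    _, inv = np.unique(pts, axis=0, return_inverse=True)
    return inv


@dataclass
class IClusterFit:
    """Result of one joint latent-variable fit.

    ``W`` is a list with one ``(genes, q)`` loading matrix per view; ``psi``
    stacks per-feature residual variances over views.  ``loglik_trace`` holds
    the observed-data log-likelihood per iteration when ``lambda_value == 0``
    and the max elementwise loading change otherwise (soft-thresholding breaks
    likelihood monotonicity, so the likelihood is not a valid convergence
    criterion there).
    """

    W: list
    psi: np.ndarray
    EZ: np.ndarray
    VarZ: np.ndarray
    cluster_labels: np.ndarray
    loglik_trace: list
    converged: bool
    n_iter: int
    lambda_value: float
    K: int
    seed: int
    degenerate: bool = False
    view_labels: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)

    @property
    def W_stacked(self) -> np.ndarray:
        return np.vstack(self.W)

    def abs_loading_sums(self) -> np.ndarray:
        """Per-gene importance: sum over views and latent dims of |W|."""
        return np.sum([np.abs(Wt).sum(axis=1) for Wt in self.W], axis=0)


def fit_icluster(
    views,
    K: int = 2,
    lam: float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> IClusterFit:
    """Fit the stacked multi-view factor model and cluster the subjects.

    Parameters
    ----------
    views : ViewStack or sequence of (genes, subjects) arrays
        Standardized per-time-point matrices sharing subject and gene order.
    K : int
        Number of clusters; the latent dimension is ``q = K - 1``.
    lam : float
        Soft-threshold level applied to the loadings after every M-step;
        ``0`` disables feature selection.
    max_iter, tol : convergence controls.  With ``lam == 0`` the stop rule is
        relative log-likelihood change < tol; with ``lam > 0`` it is max
        elementwise loading change < tol.
    seed : int
        Seeds the k-means label step (the EM itself is deterministic: the
        loadings start from the top-q scaled singular vectors of the stacked
        matrix and psi starts at 1).
    """
    mats, view_labels, gene_ids = _coerce_views(views)
    if K < 2:
        raise ValueError("K must be >= 2")
    n = mats[0].shape[1]
    if n < K:
        raise ValueError(f"need at least K={K} subjects, got {n}")
    q = K - 1
    X = np.vstack(mats)
    p = X.shape[0]

    # deterministic init: top-q left singular vectors scaled by s/sqrt(n)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    r = min(q, s.size)
    W = np.zeros((p, q))
    W[:, :r] = U[:, :r] * (s[:r] / np.sqrt(n))
    if lam > 0:
        W = soft_threshold(W, lam)
    psi = np.ones(p)

    trace: list = []
    converged = False
    it = 0
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        EZ, VarZ = e_step(X, W, psi)
        W_new, psi_new = m_step(X, EZ, VarZ)
        if lam > 0:
            W_new = soft_threshold(W_new, lam)
            delta = float(np.max(np.abs(W_new - W)))
            trace.append(delta)
            W, psi = W_new, psi_new
            if delta < tol:
                converged = True
                break
        else:
            W, psi = W_new, psi_new
            ll = _log_likelihood(X, W, psi)
            trace.append(ll)
            if np.isfinite(prev_ll):
                rel = abs(ll - prev_ll) / (abs(prev_ll) + 1e-12)
                if rel < tol:
                    converged = True
                    break
            prev_ll = ll

    EZ, VarZ = e_step(X, W, psi)
    assignment = assign_clusters(EZ, K, seed=seed)

    sizes = [m.shape[0] for m in mats]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    W_views = [W[offsets[i]:offsets[i + 1]] for i in range(len(mats))]
    return IClusterFit(
        W=W_views, psi=psi, EZ=EZ, VarZ=VarZ,
        cluster_labels=assignment.labels,
        loglik_trace=trace, converged=converged, n_iter=it,
        lambda_value=float(lam), K=K, seed=seed,
        degenerate=assignment.degenerate,
        view_labels=view_labels, gene_ids=gene_ids,
    )


def _coerce_views(views):
    """Accept a ViewStack or a plain sequence of matrices."""
    if hasattr(views, "views"):
        return (
            [np.asarray(v, float) for v in views.views],
            list(getattr(views, "view_labels", [])),
            list(getattr(views, "gene_ids", [])),
        )
    mats = [np.asarray(v, float) for v in views]
    if not mats:
        raise ValueError("need at least one view")
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError("all views must share the same shape")
    return mats, [], []
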