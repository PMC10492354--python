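"""Fuzzy c-means clustering.

Implements the classic Bezdek alternating-optimization scheme for the
objective

    J(U, C) = sum_i sum_j u_ij^m * ||x_i - c_j||^2,

with row-stochastic membership matrix ``U`` (n x k), centroids ``C``
(k x p) and fuzziness exponent ``m > 1``.  ``m`` close to 1 drives the
memberships towards a crisp partition (the k-means limit); large ``m``
flattens them towards the uniform distribution 1/k.

The public surface is the scikit-learn style estimator
:class:`FuzzyCMeans` plus thin functional wrappers (:func:`fcm_cost`,
:func:`update_memberships`, :func:`update_centroids`, :func:`fit_fcm`,
:func:`fit_fcm_multistart`) that operate on plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "FcmFit",
    "FuzzyCMeans",
    "fcm_cost",
    "update_memberships",
    "update_centroids",
    "fit_fcm",
    "fit_fcm_multistart",
]

# Squared distances at or below this are treated as exact coincidence of a
# point with a centroid (the only case where 0/1 memberships are permitted).
_ZERO_DIST = 1e-12

# Memberships are floored at machine epsilon and renormalized so that every
# non-degenerate membership stays strictly inside (0, 1): mathematically the
# update never yields exact 0 or 1, but at small m the power-law weights can
# underflow past double precision.
_MEMBERSHIP_FLOOR = np.finfo(float).eps


def _check_m(m: float) -> float:
    m = float(m)
    if not m > 1.0:
        raise ValueError(f"fuzziness parameter m must be > 1, got {m} "
                         "(the m -> 1 limit is k-means; use sklearn.cluster.KMeans)")
    return m


def fcm_cost(X: np.ndarray, U: np.ndarray, C: np.ndarray, m: float) -> float:
    """Evaluate the fuzzy c-means objective J = sum u^m d^2.

    Parameters
    ----------
    X : (n, p) data matrix.
    U : (n, k) membership matrix.
    C : (k, p) centroid matrix.
    m : fuzziness exponent, > 1.
    """
    m = _check_m(m)
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    C = np.asarray(C, dtype=float)
    if X.shape[0] != U.shape[0] or U.shape[1] != C.shape[0] or X.shape[1] != C.shape[1]:
        raise ValueError(
            f"dimension mismatch: X {X.shape}, U {U.shape}, C {C.shape}")
    d2 = cdist(X, C, "sqeuclidean")
    return float(np.sum((U ** m) * d2))


def _memberships_from_sqdist(d2: np.ndarray, m: float) -> np.ndarray:
    """First-order-optimal memberships from an (n, k) squared-distance matrix.

    u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1)), with the degenerate convention
    that a point coinciding with one or more centroids splits its membership
    equally over the coincident centroids (exact 0/1 allowed there only).
    """
    expo = -1.0 / (m - 1.0)
    dmin = d2.min(axis=1, keepdims=True)
    safe_min = np.maximum(dmin, _ZERO_DIST)
    # normalizing by the row minimum keeps the largest weight at 1 and avoids
    # overflow for small m (where expo is a large negative power); rows with
    # a coincident centroid are overwritten below, so their infs are moot
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (d2 / safe_min) ** expo
        U = w / w.sum(axis=1, keepdims=True)
    U = np.maximum(U, _MEMBERSHIP_FLOOR)
    U /= U.sum(axis=1, keepdims=True)

    coincident = d2 <= _ZERO_DIST
    rows = coincident.any(axis=1)
    if rows.any():
        split = coincident[rows].astype(float)
        U[rows] = split / split.sum(axis=1, keepdims=True)
    return U


def update_memberships(X: np.ndarray, C: np.ndarray, m: float) -> np.ndarray:
    """Optimal membership matrix for fixed centroids."""
    m = _check_m(m)
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    return _memberships_from_sqdist(cdist(X, C, "sqeuclidean"), m)


def update_centroids(X: np.ndarray, U: np.ndarray, m: float) -> np.ndarray:
    """Optimal centroids for fixed memberships: u^m-weighted means."""
    m = _check_m(m)
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    W = U ** m
    weights = W.sum(axis=0)
    if np.any(weights <= 0):
        raise FloatingPointError(
            "a cluster received zero total membership weight; memberships "
            "must be strictly positive")
    return (W.T @ X) / weights[:, None]


@dataclass
class FcmFit:
    """Result of one fuzzy c-means optimization.

    ``cost`` always equals ``fcm_cost(X, membership, centers, m)`` for the
    data the fit was produced on.
    """

    membership: np.ndarray
    centers: np.ndarray
    cost: float
    n_iter: int
    converged: bool
    seed_used: int
    m: float
    cost_history: np.ndarray = field(repr=False, default=None)

    @property
    def labels(self) -> np.ndarray:
        """Hardened cluster labels (argmax membership, ties to lowest index)."""
        return np.argmax(self.membership, axis=1)


def _fit_single(X: np.ndarray, k: int, m: float, max_iter: int, tol: float,
                seed: int) -> FcmFit:
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(k), size=n)
    cost = np.inf
    history = []
    converged = False
    n_iter = 0
    C = update_centroids(X, U, m)
    for it in range(max_iter):
        C = update_centroids(X, U, m)
        d2 = cdist(X, C, "sqeuclidean")
        U_new = _memberships_from_sqdist(d2, m)
        cost = float(np.sum((U_new ** m) * d2))
        history.append(cost)
        delta = np.abs(U_new - U).max()
        U = U_new
        n_iter = it + 1
        if delta < tol:
            converged = True
            break
    return FcmFit(membership=U, centers=C, cost=cost, n_iter=n_iter,
                  converged=converged, seed_used=int(seed), m=m,
                  cost_history=np.asarray(history))


def _restart_seeds(master_seed, n_restarts: int) -> np.ndarray:
    """Deterministic per-restart integer seeds (< 2^31) from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_restarts)
    return np.array([int(c.generate_state(1)[0] % (2 ** 31)) for c in children])


def fit_fcm(X: np.ndarray, k: int, m: float, *, max_iter: int = 200,
            tol: float = 1e-6, init_seed: int | None = None) -> FcmFit:
    """Run one fuzzy c-means optimization from a random row-stochastic start.

    Alternates :func:`update_centroids` / :func:`update_memberships` until the
    maximum absolute membership change drops below ``tol`` or ``max_iter``
    iterations.  Deterministic given ``init_seed``.
    """
    m = _check_m(m)
    X = np.asarray(X, dtype=float)
    k = int(k)
    if k < 2:
        raise ValueError(f"need k >= 2 clusters, got {k}")
    if X.shape[0] < k:
        raise ValueError(f"n={X.shape[0]} observations cannot support k={k} clusters")
    if not tol > 0:
        raise ValueError("tol must be positive")
    if init_seed is None:
        init_seed = int(np.random.SeedSequence().generate_state(1)[0] % (2 ** 31))
    return _fit_single(X, k, m, max_iter, tol, int(init_seed))


def fit_fcm_multistart(X: np.ndarray, k: int, m: float, *, n_restarts: int = 100,
                       max_iter: int = 200, tol: float = 1e-6,
                       seed: int | None = None) -> FcmFit:
    """Best-of-``n_restarts`` fuzzy c-means fit (minimum objective value).

    Restart r runs with a seed derived deterministically from ``seed``; ties
    on the objective go to the lowest restart index.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    seeds = _restart_seeds(seed, n_restarts)
    best = None
    for s in seeds:
        fit = fit_fcm(X, k, m, max_iter=max_iter, tol=tol, init_seed=int(s))
        if best is None or fit.cost < best.cost:
            best = fit
    return best


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering with multi-restart optimization.

    Parameters
    ----------
    n_clusters : int, default=6
        Number of clusters k (>= 2).
    m : float, default=1.1
        Fuzziness exponent (> 1).
    n_init : int, default=100
        Number of independent random restarts; the run with the lowest
        objective value is kept.
    max_iter : int, default=200
        Iteration cap per restart.
    tol : float, default=1e-6
        Convergence threshold on the maximum absolute membership change.
    random_state : int or None
        Master seed; each restart derives its own seed from it.

    Attributes
    ----------
    membership_ : ndarray of shape (n_samples, n_clusters)
        Row-stochastic membership matrix of the best run.
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    labels_ : ndarray of shape (n_samples,)
        Hardened (argmax) labels.
    inertia_ : float
        Objective value J of the best run.
    n_iter_ : int
        Iterations used by the best run.
    converged_ : bool
    seed_used_ : int
        Derived seed of the winning restart.

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[0., 0.], [0., 0.1], [5., 5.], [5., 5.1]])
    >>> fcm = FuzzyCMeans(n_clusters=2, m=2.0, n_init=5, random_state=0).fit(X)
    >>> sorted(np.bincount(fcm.labels_))
    [2, 2]
    """

    def __init__(self, n_clusters: int = 6, *, m: float = 1.1, n_init: int = 100,
                 max_iter: int = 200, tol: float = 1e-6,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.m = m
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        fit = fit_fcm_multistart(
            X, self.n_clusters, self.m, n_restarts=self.n_init,
            max_iter=self.max_iter, tol=self.tol, seed=self.random_state)
        self.membership_ = fit.membership
        self.cluster_centers_ = fit.centers
        self.labels_ = fit.labels
        self.inertia_ = fit.cost
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.seed_used_ = fit.seed_used
        self.n_features_in_ = X.shape[1]
        return self

    def predict_membership(self, X) -> np.ndarray:
        """Membership matrix of new observations w.r.t. the fitted centroids."""
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X, dtype=float)
        return update_memberships(X, self.cluster_centers_, self.m)

    def predict(self, X) -> np.ndarray:
        """Hardened cluster labels for new observations."""
        return np.argmax(self.predict_membership(X), axis=1)

    def to_fit(self) -> FcmFit:
        """Bundle the fitted state as an :class:`FcmFit`."""
        check_is_fitted(self, "cluster_centers_")
        return FcmFit(membership=self.membership_, centers=self.cluster_centers_,
                      cost=self.inertia_, n_iter=self.n_iter_,
                      converged=self.converged_, seed_used=self.seed_used_,
                      m=self.m)
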