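"""Cluster validity indices and the two-stage (m, k) grid selection.

Four indices score each fitted membership matrix:

* Xie–Beni (XB): objective / (n * min squared centroid separation); lower
  is better.
* Partition coefficient (PC): mean squared membership, in [1/k, 1]; higher
  is better (crisper partition).
* Partition entropy (PE): mean Shannon entropy of the membership rows (in
  nats), in [0, ln k]; lower is better.
* Silhouette (SIL): classic crisp silhouette on the hardened labels, or a
  membership-weighted fuzzy variant; higher is better.

Selection is two-stage: first the fuzziness exponent m is chosen as the
mode of the four per-index optimal m values over the whole grid, then k is
chosen as the mode of the four per-index optimal k values restricted to
the selected m.  Ties go to the smallest value.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_samples, silhouette_score
from sklearn.utils.validation import check_array

from .fcm import FcmFit, fcm_cost, fit_fcm_multistart

__all__ = [
    "xie_beni",
    "partition_coefficient",
    "partition_entropy",
    "silhouette_index",
    "grid_search",
    "select_m",
    "select_k",
    "SelectionResult",
    "FcmGridSelector",
]

DEFAULT_M_GRID = (1.1, 1.2, 1.3, 1.4, 1.5)
DEFAULT_K_GRID = tuple(range(5, 16))

#: per-index optimization direction: True = lower is better
_MINIMIZE = {"XB": True, "PC": False, "PE": True, "SIL": False}


def xie_beni(X, U, C, m: float) -> float:
    """Xie–Beni compactness/separation index (lower is better)."""
    C = np.asarray(C, dtype=float)
    if C.shape[0] < 2:
        raise ValueError("Xie-Beni requires k >= 2 centroids")
    min_sep = float(pdist(C, "sqeuclidean").min())
    if min_sep <= 1e-12:
        raise ValueError("Xie-Beni undefined: two centroids coincide")
    n = np.asarray(X).shape[0]
    return fcm_cost(X, U, C, m) / (n * min_sep)


def partition_coefficient(U) -> float:
    """Bezdek partition coefficient, (1/n) sum u^2, in [1/k, 1]."""
    U = np.asarray(U, dtype=float)
    return float(np.mean(np.sum(U * U, axis=1)))


def partition_entropy(U) -> float:
    """Bezdek partition entropy in nats, -(1/n) sum u ln u, in [0, ln k]."""
    U = np.asarray(U, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(U > 0, U * np.log(U), 0.0)
    return float(-np.mean(np.sum(terms, axis=1)))


def silhouette_index(X, U, *, fuzzy: bool = False) -> float:
    """Silhouette index of a fuzzy partition.

    By default the classic crisp silhouette of the hardened (argmax)
    labels under Euclidean distance.  With ``fuzzy=True``, the per-sample
    silhouettes are averaged with weights equal to the margin between each
    row's two largest memberships (Campello–Hruschka style).
    """
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    labels = np.argmax(U, axis=1)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined: hardened labels form a single cluster")
    if not fuzzy:
        return float(silhouette_score(X, labels, metric="euclidean"))
    s = silhouette_samples(X, labels, metric="euclidean")
    top2 = np.sort(U, axis=1)[:, -2:]
    w = top2[:, 1] - top2[:, 0]
    if w.sum() <= 0:
        return float(np.mean(s))
    return float(np.average(s, weights=w))


@dataclass
class SelectionResult:
    """Outcome of the two-stage hyperparameter selection."""

    optimal_m: float
    optimal_k: int
    m_votes: dict = field(default_factory=dict)   # index -> m at its global optimum
    k_votes: dict = field(default_factory=dict)   # index -> k at its optimum given m


def _optimal_row(table: pd.DataFrame, col: str) -> pd.Series | None:
    """Grid row optimizing one index; ties to smallest (m, k); None if all-NaN."""
    sub = table.dropna(subset=[col]).sort_values(["m", "k"], kind="stable")
    if sub.empty:
        return None
    idx = sub[col].idxmin() if _MINIMIZE[col] else sub[col].idxmax()
    return sub.loc[idx]


def _mode_smallest(votes: dict):
    counts = Counter(votes.values())
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def select_m(table: pd.DataFrame) -> tuple[float, dict]:
    """Stage 1: per-index globally optimal m, then the mode (ties -> smallest).

    Returns ``(optimal_m, votes)`` where ``votes`` maps index name to the m
    of its optimal grid cell.  Indices with no finite value abstain.
    """
    votes = {}
    for col in _MINIMIZE:
        row = _optimal_row(table, col)
        if row is not None:
            votes[col] = float(row["m"])
    if not votes:
        raise ValueError("no index produced a finite value on the grid")
    return _mode_smallest(votes), votes


def select_k(table: pd.DataFrame, m_star: float) -> tuple[int, dict]:
    """Stage 2: per-index optimal k restricted to m = m_star, then the mode."""
    sub = table[np.isclose(table["m"].astype(float), m_star)]
    if sub.empty:
        raise ValueError(f"no grid rows at m={m_star}")
    votes = {}
    for col in _MINIMIZE:
        row = _optimal_row(sub, col)
        if row is not None:
            votes[col] = int(row["k"])
    if not votes:
        raise ValueError("no index produced a finite value at the selected m")
    return _mode_smallest(votes), votes


class FcmGridSelector(BaseEstimator):
    """Exhaustive (m, k) grid search with validity-index model selection.

    For every grid cell the best of ``n_init`` random restarts (lowest
    objective) is kept and scored with the four validity indices; the
    fuzziness exponent and cluster count are then selected by the two-stage
    mode rule (:func:`select_m`, :func:`select_k`).

    Attributes
    ----------
    index_table_ : DataFrame with columns m, k, XB, PC, PE, SIL, J.
    fits_ : dict mapping (m, k) -> :class:`~fuzzycohort.fcm.FcmFit`.
    best_m_, best_k_ : selected hyperparameters.
    best_fit_ : the fit at (best_m_, best_k_).
    m_votes_, k_votes_ : per-index votes behind each stage.
    """

    def __init__(self, *, m_grid=DEFAULT_M_GRID, k_grid=DEFAULT_K_GRID,
                 n_init: int = 100, max_iter: int = 200, tol: float = 1e-6,
                 fuzzy_silhouette: bool = False, keep_fits: bool = True,
                 random_state: int | None = None):
        self.m_grid = m_grid
        self.k_grid = k_grid
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.fuzzy_silhouette = fuzzy_silhouette
        self.keep_fits = keep_fits
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        m_grid = [float(m) for m in self.m_grid]
        k_grid = [int(k) for k in self.k_grid]
        if not m_grid or not k_grid:
            raise ValueError("m_grid and k_grid must be non-empty")
        if X.shape[0] < max(k_grid):
            raise ValueError("n must be >= the largest k in the grid")
        # one deterministic sub-seed per grid cell
        cell_seeds = np.random.SeedSequence(self.random_state).spawn(
            len(m_grid) * len(k_grid))
        rows = []
        fits = {}
        i = 0
        for m in m_grid:
            for k in k_grid:
                seed = int(cell_seeds[i].generate_state(1)[0] % (2 ** 31))
                i += 1
                fit = fit_fcm_multistart(X, k, m, n_restarts=self.n_init,
                                         max_iter=self.max_iter, tol=self.tol,
                                         seed=seed)
                try:
                    sil = silhouette_index(X, fit.membership,
                                           fuzzy=self.fuzzy_silhouette)
                except ValueError:
                    warnings.warn(
                        f"silhouette undefined at (m={m}, k={k}); recorded as "
                        "missing and excluded from that index's vote")
                    sil = np.nan
                try:
                    xb = xie_beni(X, fit.membership, fit.centers, m)
                except ValueError:
                    warnings.warn(
                        f"Xie-Beni undefined at (m={m}, k={k}): two centroids "
                        "coincide; recorded as missing")
                    xb = np.nan
                rows.append({
                    "m": m, "k": k,
                    "XB": xb,
                    "PC": partition_coefficient(fit.membership),
                    "PE": partition_entropy(fit.membership),
                    "SIL": sil,
                    "J": fit.cost,
                })
                fits[(m, k)] = fit
        self.index_table_ = pd.DataFrame(rows)
        self.best_m_, self.m_votes_ = select_m(self.index_table_)
        self.best_k_, self.k_votes_ = select_k(self.index_table_, self.best_m_)
        self.best_fit_ = fits[(self.best_m_, self.best_k_)]
        if self.keep_fits:
            self.fits_ = fits
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def selection_(self) -> SelectionResult:
        return SelectionResult(optimal_m=self.best_m_, optimal_k=self.best_k_,
                               m_votes=dict(self.m_votes_),
                               k_votes=dict(self.k_votes_))


def grid_search(X, m_grid=DEFAULT_M_GRID, k_grid=DEFAULT_K_GRID, *,
                n_init: int = 100, max_iter: int = 200, tol: float = 1e-6,
                fuzzy_silhouette: bool = False,
                seed: int | None = None) -> pd.DataFrame:
    """Index table (m, k, XB, PC, PE, SIL, J) over the full hyperparameter grid."""
    sel = FcmGridSelector(m_grid=m_grid, k_grid=k_grid, n_init=n_init,
                          max_iter=max_iter, tol=tol,
                          fuzzy_silhouette=fuzzy_silhouette, keep_fits=False,
                          random_state=seed).fit(X)
    return sel.index_table_
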