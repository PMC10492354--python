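"""Cluster characterization via observed/expected and exclusivity ratios.

For specialty x and cluster y:

* ``O_xy`` — observed prevalence of x in cluster y.  Under a fuzzy
  partition this is membership-weighted: sum_i u_iy X_ix / sum_i u_iy
  (a ``hardened=True`` variant counts over argmax labels instead).
* ``E_x`` — expected prevalence: the overall sample prevalence of x.
* ``(O/E)_xy = O_xy / E_x``.
* ``EX_xy`` — exclusivity: the membership mass of cluster y carried by the
  patients with x, divided by their count n_x.  Because memberships are
  row-stochastic, the exclusivities of one specialty sum to 1 over clusters.

A specialty characterizes a cluster when ``(O/E)_xy >= 2`` or
``EX_xy >= 0.25`` (thresholds inclusive, configurable); clusters are
labeled by their characterizing specialties in descending O/E order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "observed_expected",
    "exclusivity",
    "label_clusters",
    "characterize",
    "ClusterCharacterization",
]


def _as_aligned(U, X):
    U = np.asarray(U, dtype=float)
    X = np.asarray(X, dtype=float)
    if U.shape[0] != X.shape[0]:
        raise ValueError(f"U has {U.shape[0]} patients but X has {X.shape[0]}")
    return U, X


def observed_expected(U, X, *, hardened: bool = False):
    """O/E ratios per (specialty, cluster).

    Returns ``(oe, observed, expected)`` where ``oe`` and ``observed`` are
    p x k matrices and ``expected`` the length-p overall prevalence vector.
    Raises if any specialty has zero involvement (E_x = 0).
    """
    U, X = _as_aligned(U, X)
    if not X.any(axis=0).all():
        missing = np.flatnonzero(~X.any(axis=0)).tolist()
        raise ValueError(f"specialty column(s) {missing} have no involvement; "
                         "expected prevalence would be zero")
    if hardened:
        labels = np.argmax(U, axis=1)
        W = np.eye(U.shape[1])[labels]
    else:
        W = U
    cluster_mass = W.sum(axis=0)          # (k,)
    observed = (X.T @ W) / cluster_mass   # (p, k)
    expected = X.mean(axis=0)             # (p,)
    return observed / expected[:, None], observed, expected


def exclusivity(U, X):
    """Exclusivity ratios EX_xy = (sum of u_iy over patients with x) / n_x."""
    U, X = _as_aligned(U, X)
    n_x = X.sum(axis=0)
    if (n_x == 0).any():
        missing = np.flatnonzero(n_x == 0).tolist()
        raise ValueError(f"specialty column(s) {missing} have no involvement "
                         "(n_x = 0)")
    return (X.T @ U) / n_x[:, None]


def label_clusters(oe, ex, *, specialty_names=None, oe_threshold: float = 2.0,
                   ex_threshold: float = 0.25) -> dict:
    """Characterizing specialties per cluster (descending O/E order).

    A specialty characterizes a cluster when its O/E ratio or exclusivity
    reaches the (inclusive) threshold.  Returns ``{cluster: [specialty,...]}``;
    clusters no specialty characterizes get an empty list.
    """
    oe = np.asarray(oe, dtype=float)
    ex = np.asarray(ex, dtype=float)
    if oe.shape != ex.shape:
        raise ValueError("O/E and exclusivity matrices must share a shape")
    p, k = oe.shape
    if specialty_names is None:
        specialty_names = list(range(p))
    labels = {}
    for y in range(k):
        hits = np.flatnonzero((oe[:, y] >= oe_threshold)
                              | (ex[:, y] >= ex_threshold))
        order = hits[np.argsort(-oe[hits, y], kind="stable")]
        labels[y] = [specialty_names[x] for x in order]
    return labels


@dataclass
class ClusterCharacterization:
    """O/E and exclusivity matrices (p x k) plus derived cluster labels."""

    oe: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    exclusivity: np.ndarray
    n_x: np.ndarray
    labels: dict
    specialty_names: list


def characterize(U, X, *, specialty_names=None, hardened: bool = False,
                 oe_threshold: float = 2.0,
                 ex_threshold: float = 0.25) -> ClusterCharacterization:
    """Full characterization of a fitted partition over an involvement matrix."""
    U, X = _as_aligned(U, X)
    oe, observed, expected = observed_expected(U, X, hardened=hardened)
    ex = exclusivity(U, X)
    if specialty_names is None:
        specialty_names = list(range(X.shape[1]))
    labels = label_clusters(oe, ex, specialty_names=specialty_names,
                            oe_threshold=oe_threshold,
                            ex_threshold=ex_threshold)
    return ClusterCharacterization(oe=oe, observed=observed, expected=expected,
                                   exclusivity=ex, n_x=X.sum(axis=0),
                                   labels=labels,
                                   specialty_names=list(specialty_names))
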