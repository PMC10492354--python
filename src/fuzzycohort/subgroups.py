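"""Membership-band subgroup identification and profiling.

Each patient's membership vector is discretized into five equal bands —
[80, 100] full (FULL), [60, 80) dominant (DOM), [40, 60) mid (MID),
[20, 40) low (LOW), and below 20% insignificant — and patients are grouped
by the resulting band pattern with a sequential five-step rule:

1. any patient with a FULL band fully belongs to that single cluster
   (any other band is discarded);
2. of the remainder, patients with a DOM band form subgroups keyed by the
   dominant cluster plus any LOW secondaries;
3. then patients with at least one MID band, keyed by all MID and LOW
   entries;
4. then patients with only LOW bands, keyed by those;
5. everyone else is the rest group.

Subgroups smaller than a minimum size (default 100 patients, the scale at
which a hospital-level intervention is still practical) are dissolved into
the rest group.  Retained subgroups are named by their cluster indices
("4" for a full-membership subgroup, "1-5-a" / "1-5-b" ... for band
patterns over the same cluster combination, lettered by descending size)
and profiled descriptively.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "band_of",
    "assign_subgroups",
    "enforce_min_size",
    "name_subgroups",
    "profile_subgroups",
    "SubgroupAssignment",
]


class Band:
    FULL = "FULL"            # membership in [0.80, 1.00]
    DOM = "DOM"              # [0.60, 0.80)
    MID = "MID"              # [0.40, 0.60)
    LOW = "LOW"              # [0.20, 0.40)
    INSIGNIFICANT = "INSIGNIFICANT"   # below 0.20


_BAND_BY_LEVEL = {4: Band.FULL, 3: Band.DOM, 2: Band.MID, 1: Band.LOW,
                  0: Band.INSIGNIFICANT}
_EDGES = np.array([0.2, 0.4, 0.6, 0.8])


def band_of(membership: float) -> str:
    """Band of a single membership degree (closed-lower, open-upper bins).

    The membership must lie strictly inside (0, 1), as fuzzy c-means
    memberships do outside the coincident-centroid degeneracy.
    """
    u = float(membership)
    if not (0.0 < u < 1.0):
        raise ValueError(f"membership must lie strictly in (0, 1), got {u}")
    return _BAND_BY_LEVEL[int(np.searchsorted(_EDGES, u, side="right"))]


def _band_levels(U: np.ndarray) -> np.ndarray:
    """Vectorized band levels 0..4; tolerates the degenerate exact 0/1 rows."""
    return np.searchsorted(_EDGES, U, side="right")


@dataclass
class SubgroupAssignment:
    """Partition of the cohort into band-pattern subgroups plus a rest group.

    ``patterns[i]`` is patient i's canonical band pattern — a tuple of
    ``(cluster_index, band)`` pairs sorted by cluster index — or ``None``
    for the rest group.  Every patient belongs to exactly one subgroup or
    the rest group.
    """

    patient_ids: list
    patterns: list
    min_size: int = 1
    groups: dict = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.patient_ids) != len(self.patterns):
            raise ValueError("patient_ids and patterns length mismatch")
        groups: dict = {}
        for i, pat in enumerate(self.patterns):
            if pat is not None:
                groups.setdefault(pat, []).append(i)
        self.groups = {pat: np.asarray(idx) for pat, idx in groups.items()}

    @property
    def rest_indices(self) -> np.ndarray:
        return np.asarray([i for i, p in enumerate(self.patterns) if p is None],
                          dtype=int)

    @property
    def sizes(self) -> dict:
        return {pat: len(idx) for pat, idx in self.groups.items()}

    def to_frame(self, names: dict | None = None) -> pd.DataFrame:
        if names is None:
            names = name_subgroups(self)
        return pd.DataFrame({
            "patient_id": self.patient_ids,
            "subgroup": [names.get(p, "rest") for p in self.patterns],
            "band_pattern": [_pattern_str(p) for p in self.patterns],
        })


def _pattern_str(pattern) -> str:
    if pattern is None:
        return "rest"
    return "+".join(f"{j + 1}:{band}" for j, band in pattern)


def assign_subgroups(U, patient_ids=None) -> SubgroupAssignment:
    """Assign every patient a band-pattern subgroup via the five-step rule.

    ``U`` is a row-stochastic membership matrix.  Patterns are canonical
    (sorted by cluster index); a FULL band absorbs any secondary band
    (step 1), which can only arise at the exact 0.80/0.20 boundary.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise ValueError("U must be a 2-D membership matrix")
    if not np.allclose(U.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("membership rows must sum to 1")
    n, k = U.shape
    if patient_ids is None:
        patient_ids = list(range(n))
    levels = _band_levels(U)

    # feasibility: membership mass makes two FULLs, two DOMs, or FULL+DOM
    # impossible -- asserted, not assumed
    n_full = (levels == 4).sum(axis=1)
    n_dom = (levels == 3).sum(axis=1)
    assert n_full.max(initial=0) <= 1, "two FULL bands in one row"
    assert ((n_full + n_dom) <= 1).all(), "FULL+DOM or DOM+DOM in one row"

    patterns = []
    for i in range(n):
        lv = levels[i]
        if (lv == 4).any():                     # step 1: full membership
            j = int(np.flatnonzero(lv == 4)[0])
            patterns.append(((j, Band.FULL),))
            continue
        significant = np.flatnonzero(lv >= 1)
        if (lv == 3).any():                     # step 2: dominant (+ LOW secondaries)
            pat = tuple((int(j), _BAND_BY_LEVEL[int(lv[j])]) for j in significant)
        elif (lv == 2).any():                   # step 3: mid combinations
            pat = tuple((int(j), _BAND_BY_LEVEL[int(lv[j])]) for j in significant)
        elif (lv == 1).any():                   # step 4: low combinations
            pat = tuple((int(j), Band.LOW) for j in significant)
        else:                                   # step 5: rest group
            patterns.append(None)
            continue
        patterns.append(pat)
    return SubgroupAssignment(patient_ids=list(patient_ids), patterns=patterns)


def enforce_min_size(assignment: SubgroupAssignment,
                     min_size: int = 100) -> SubgroupAssignment:
    """Dissolve every subgroup smaller than ``min_size`` into the rest group."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    keep = {pat for pat, idx in assignment.groups.items() if len(idx) >= min_size}
    patterns = [p if (p is None or p in keep) else None
                for p in assignment.patterns]
    return SubgroupAssignment(patient_ids=list(assignment.patient_ids),
                              patterns=patterns, min_size=min_size)


def _letters():
    for c in string.ascii_lowercase:
        yield c
    i = 1
    while True:
        for c in string.ascii_lowercase:
            yield f"{c}{i}"
        i += 1


def name_subgroups(assignment: SubgroupAssignment) -> dict:
    """Map each band pattern to its display name.

    Full-membership subgroups are named by their (1-based) cluster index;
    every other pattern is named by its ascending cluster indices joined by
    hyphens plus a letter suffix distinguishing band patterns over the same
    cluster set, assigned in order of descending subgroup size (ties broken
    by the canonical pattern order).
    """
    names = {}
    by_set: dict = {}
    for pat, idx in assignment.groups.items():
        if len(pat) == 1 and pat[0][1] == Band.FULL:
            names[pat] = str(pat[0][0] + 1)
        else:
            clusters = tuple(sorted(j for j, _ in pat))
            by_set.setdefault(clusters, []).append((pat, len(idx)))
    for clusters, pats in by_set.items():
        base = "-".join(str(j + 1) for j in clusters)
        ranked = sorted(pats, key=lambda t: (-t[1], t[0]))
        for (pat, _size), letter in zip(ranked, _letters()):
            names[pat] = f"{base}-{letter}"
    return names


def _median_iqr(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return float("nan"), float("nan")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return float(q2), float(q3 - q1)


def profile_subgroups(assignment: SubgroupAssignment, encounters: pd.DataFrame,
                      matrix, U, *, names: dict | None = None,
                      top_specialties: int = 5,
                      top_diagnoses: int = 10) -> list[dict]:
    """Descriptive profile per subgroup (the rest group is profiled too).

    Reports n, per-cluster mean membership (%) with SD, female count and
    percentage, median (IQR, as the single value Q3 - Q1) of age, involved
    specialties, outpatient visits, ED visits, inpatient days and distinct
    diagnoses, plus the top specialties (% involved) and top diagnosis
    groups (%).  Top lists break ties alphabetically.
    """
    U = np.asarray(U, dtype=float)
    ids = [str(i) for i in assignment.patient_ids]
    if list(map(str, matrix.patient_ids)) != ids:
        raise ValueError("assignment and matrix patient order differ")
    known = set(encounters["patient_id"].astype(str))
    missing = [i for i in ids if i not in known]
    if missing:
        raise ValueError(f"subgroup references unknown patient(s): {missing[:5]}")
    if names is None:
        names = name_subgroups(assignment)

    enc = encounters.copy()
    enc["patient_id"] = enc["patient_id"].astype(str)
    per_patient = enc.groupby("patient_id").agg(
        age=("age_years", "first"), sex=("sex", "first"),
        outpatient_visits=("outpatient_visits", "sum"),
        ed_visits=("ed_visits", "sum"),
        inpatient_days=("inpatient_days", "sum"),
        n_diagnoses=("diagnosis_code", "nunique")).reindex(ids)
    n_specialties = matrix.values.sum(axis=1)

    groups = list(assignment.groups.items())
    groups.sort(key=lambda t: names.get(t[0], ""))
    rest = assignment.rest_indices
    if len(rest):
        groups.append((None, rest))

    profiles = []
    for pat, idx in groups:
        sub = per_patient.iloc[idx]
        stats = {}
        for colname, vals in (
                ("age_years", sub["age"]),
                ("specialties_involved", n_specialties[idx]),
                ("outpatient_visits", sub["outpatient_visits"]),
                ("ed_visits", sub["ed_visits"]),
                ("inpatient_days", sub["inpatient_days"]),
                ("diagnoses", sub["n_diagnoses"])):
            med, iqr = _median_iqr(vals)
            stats[colname] = {"median": med, "iqr": iqr}

        clusters = ([j for j, _ in pat] if pat is not None
                    else list(range(U.shape[1])))
        memberships = {
            f"cluster_{j + 1}": {
                "mean_pct": float(np.mean(U[idx, j]) * 100),
                "sd_pct": float(np.std(U[idx, j], ddof=0) * 100)}
            for j in clusters}

        spec_pct = matrix.values[idx].mean(axis=0) * 100
        spec_rank = sorted(zip(matrix.specialty_names, spec_pct),
                           key=lambda t: (-t[1], t[0]))[:top_specialties]

        member_ids = set(np.asarray(ids)[idx])
        sub_enc = enc[enc["patient_id"].isin(member_ids)]
        dx_pct = (sub_enc.groupby("diagnosis_group")["patient_id"].nunique()
                  / len(idx) * 100)
        dx_rank = sorted(dx_pct.items(), key=lambda t: (-t[1], t[0]))[:top_diagnoses]

        n_female = int((sub["sex"] == "female").sum())
        profiles.append({
            "name": names.get(pat, "rest"),
            "is_rest": pat is None,
            "band_pattern": _pattern_str(pat),
            "n": int(len(idx)),
            "membership": memberships,
            "sex_female": {"n": n_female,
                           "pct": float(n_female / len(idx) * 100)},
            **stats,
            "top_specialties": [{"specialty": s, "pct_involved": float(v)}
                                for s, v in spec_rank],
            "top_diagnoses": [{"diagnosis_group": g, "pct": float(v)}
                              for g, v in dx_rank],
        })
    return profiles
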