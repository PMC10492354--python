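"""Membership banding, subgroup assignment, naming and profiling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzycohort.io import build_involvement_matrix
from fuzzycohort.subgroups import (Band, SubgroupAssignment, assign_subgroups,
                                   band_of, enforce_min_size, name_subgroups,
                                   profile_subgroups)

from conftest import encounter_row, make_encounters


def direct_band_classifier(row):
    """Independent one-shot band-pattern oracle for a membership row.

    Bins every membership into its band, then applies the full-dominance
    exception: a FULL band discards all secondaries.  Returns the canonical
    pattern tuple or None for the rest group.
    """
    pattern = []
    for j, u in enumerate(row):
        if u >= 0.8:
            band = Band.FULL
        elif u >= 0.6:
            band = Band.DOM
        elif u >= 0.4:
            band = Band.MID
        elif u >= 0.2:
            band = Band.LOW
        else:
            continue
        pattern.append((j, band))
    fulls = [(j, b) for j, b in pattern if b == Band.FULL]
    if fulls:
        return (fulls[0],)
    return tuple(pattern) or None


class TestBandOf:
    @pytest.mark.parametrize("u,band", [
        (0.80, Band.FULL), (0.999, Band.FULL),
        (0.60, Band.DOM), (0.7999, Band.DOM),
        (0.40, Band.MID), (0.5999, Band.MID),
        (0.20, Band.LOW), (0.3999, Band.LOW),
        (0.1999, Band.INSIGNIFICANT), (0.001, Band.INSIGNIFICANT),
    ])
    def test_closed_lower_open_upper_bins(self, u, band):
        assert band_of(u) == band

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.1, 1.5])
    def test_values_outside_open_unit_interval_rejected(self, u):
        with pytest.raises(ValueError, match="strictly"):
            band_of(u)


class TestAssignment:
    def test_full_membership_absorbs_everything_else(self):
        U = np.array([[0.85, 0.10, 0.05]])
        a = assign_subgroups(U)
        assert a.patterns[0] == ((0, Band.FULL),)

    def test_dominant_with_low_secondary(self):
        # memberships like cluster 5 = 68%, cluster 1 = 29%
        U = np.array([[0.29, 0.02, 0.005, 0.005, 0.68]])
        a = assign_subgroups(U)
        assert a.patterns[0] == ((0, Band.LOW), (4, Band.DOM))

    def test_two_mid_combination(self):
        # memberships like cluster 1 = 51%, cluster 5 = 47%
        U = np.array([[0.51, 0.005, 0.005, 0.01, 0.47]])
        a = assign_subgroups(U)
        assert a.patterns[0] == ((0, Band.MID), (4, Band.MID))

    def test_uniform_row_goes_to_rest(self):
        U = np.full((1, 6), 1 / 6)
        a = assign_subgroups(U)
        assert a.patterns[0] is None
        assert len(a.rest_indices) == 1

    def test_exact_full_boundary_discards_low_secondary(self):
        # (0.80, 0.20) carries a FULL and a LOW band; FULL absorbs
        U = np.array([[0.80, 0.20]])
        a = assign_subgroups(U)
        assert a.patterns[0] == ((0, Band.FULL),)

    def test_sequential_agrees_with_direct_classifier(self, rng):
        # exhaustive cross-validation on 10^4 random row-stochastic rows
        U = rng.dirichlet(np.full(6, 0.4), size=10_000)
        U /= U.sum(axis=1, keepdims=True)
        a = assign_subgroups(U)
        for i in range(len(U)):
            assert a.patterns[i] == direct_band_classifier(U[i]), i

    @given(st.lists(st.floats(1e-3, 1.0), min_size=2, max_size=8))
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_sequential_equals_direct_for_any_membership_row(self, weights):
        row = np.asarray(weights)
        row /= row.sum()
        assignment = assign_subgroups(row[None, :])
        assert assignment.patterns[0] == direct_band_classifier(row)

    def test_partition_property(self, rng):
        U = rng.dirichlet(np.ones(4), size=500)
        a = assign_subgroups(U)
        sizes = sum(len(idx) for idx in a.groups.values())
        assert sizes + len(a.rest_indices) == 500
        seen = np.concatenate([idx for idx in a.groups.values()]
                              + [a.rest_indices])
        assert len(np.unique(seen)) == 500


class TestMinSize:
    def _assignment_with_sizes(self, big, small):
        patterns = ([((0, Band.FULL),)] * big
                    + [((1, Band.MID), (2, Band.MID))] * small)
        return SubgroupAssignment(patient_ids=list(range(big + small)),
                                  patterns=patterns)

    def test_group_of_99_dissolves_to_rest(self):
        out = enforce_min_size(self._assignment_with_sizes(100, 99),
                               min_size=100)
        assert len(out.groups) == 1
        assert len(out.rest_indices) == 99

    def test_group_of_100_is_retained(self):
        out = enforce_min_size(self._assignment_with_sizes(100, 100),
                               min_size=100)
        assert len(out.groups) == 2 and len(out.rest_indices) == 0

    def test_min_size_one_is_identity(self, rng):
        U = rng.dirichlet(np.ones(3), size=200)
        a = assign_subgroups(U)
        out = enforce_min_size(a, min_size=1)
        assert out.patterns == a.patterns

    def test_monotonicity_in_min_size(self, rng):
        U = rng.dirichlet(np.full(5, 0.5), size=400)
        U /= U.sum(axis=1, keepdims=True)
        a = assign_subgroups(U)
        previous = None
        for min_size in (1, 5, 20, 100):
            out = enforce_min_size(a, min_size=min_size)
            if previous is not None:
                assert len(out.groups) <= len(previous)
                # no patient moves between two non-rest subgroups
                for p_prev, p_now in zip(previous_patterns, out.patterns):
                    assert p_now == p_prev or p_now is None
            previous = out.groups
            previous_patterns = out.patterns


class TestNaming:
    def test_full_subgroups_named_by_cluster_index(self):
        patterns = [((3, Band.FULL),)] * 5
        names = name_subgroups(SubgroupAssignment(list(range(5)), patterns))
        assert names[((3, Band.FULL),)] == "4"

    def test_letter_suffixes_ordered_by_size(self):
        pat_mid = ((0, Band.MID), (4, Band.MID))
        pat_dom = ((0, Band.LOW), (4, Band.DOM))
        pat_mixed = ((0, Band.LOW), (4, Band.MID))
        patterns = [pat_mid] * 30 + [pat_dom] * 20 + [pat_mixed] * 10
        names = name_subgroups(
            SubgroupAssignment(list(range(60)), patterns))
        assert names[pat_mid] == "1-5-a"
        assert names[pat_dom] == "1-5-b"
        assert names[pat_mixed] == "1-5-c"

    def test_dominant_only_subgroup_gets_letter(self):
        pat = ((2, Band.DOM),)
        names = name_subgroups(SubgroupAssignment([0], [pat]))
        assert names[pat] == "3-a"


class TestProfiles:
    def _fixture(self):
        rows = []
        ages = [60.0, 64.0, 70.0, 75.0, 81.0]
        for i, age in enumerate(ages):
            pid = f"p{i}"
            rows.append(encounter_row(pid, "cardiology", age=age,
                                      sex="female" if i < 3 else "male",
                                      code=f"c{i}", visits=i + 1))
            rows.append(encounter_row(pid, "neurology", age=age,
                                      sex="female" if i < 3 else "male",
                                      code=f"n{i}", group="other nervous system disorders",
                                      visits=1, ed=1, days=2))
        enc = make_encounters(rows)
        matrix = build_involvement_matrix(enc)
        U = np.tile([0.95, 0.05], (5, 1))
        assignment = assign_subgroups(U, patient_ids=matrix.patient_ids)
        return assignment, enc, matrix, U

    def test_hand_computed_median_and_iqr(self):
        assignment, enc, matrix, U = self._fixture()
        (profile,) = profile_subgroups(assignment, enc, matrix, U)
        # ages 60,64,70,75,81: median 70; Q3-Q1 = 75 - 64 = 11 under linear
        # interpolation
        assert profile["age_years"] == {"median": 70.0, "iqr": 11.0}
        # outpatient visits per patient: 2,3,4,5,6 -> median 4, IQR 2
        assert profile["outpatient_visits"] == {"median": 4.0, "iqr": 2.0}
        assert profile["n"] == 5
        assert profile["sex_female"] == {"n": 3, "pct": 60.0}

    def test_constant_membership_column(self):
        assignment, enc, matrix, U = self._fixture()
        (profile,) = profile_subgroups(assignment, enc, matrix, U)
        memb = profile["membership"]["cluster_1"]
        assert memb["mean_pct"] == pytest.approx(95.0)
        assert memb["sd_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_universal_specialty_tops_the_list(self):
        assignment, enc, matrix, U = self._fixture()
        (profile,) = profile_subgroups(assignment, enc, matrix, U)
        top = profile["top_specialties"][0]
        assert top["pct_involved"] == 100.0
        assert top["specialty"] == "cardiology"  # alphabetical tie-break

    def test_unknown_patient_raises(self):
        assignment, enc, matrix, U = self._fixture()
        enc = enc[enc["patient_id"] != "p3"]
        with pytest.raises(ValueError, match="unknown patient"):
            profile_subgroups(assignment, enc, matrix, U)
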