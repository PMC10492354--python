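# Methods

## Feature space and cohort definition

The unit of analysis is the adult multimorbid patient; the feature vector
is binary involvement over the specialties observed in the filtered
cohort. A patient enters the cohort when aged ≥ 18 and carrying at least
two distinct chronic and/or oncological diagnoses for which outpatient
care was received. Counting the union ("≥ 2 chronic + oncological") is
equivalent to the three usual disjuncts (two chronic; two oncological; one
of each) because every diagnosis has exactly one type; the implementation
counts the two types separately and sums, so it stays correct even on
inconsistent inputs where one code appears under both types.

Two operationalizations are deliberate choices exposed as switches:

* *"received outpatient care for a diagnosis"* means the diagnosis row has
  ≥ 1 recorded outpatient visit (`require_outpatient_visit=True`). ED-only
  or inpatient-only diagnoses do not qualify a patient.
* diagnoses are counted as distinct `diagnosis_code`s by default;
  `count_level="diagnosis_group"` counts at the coarser group level. The
  appropriate level depends on how the source system assigns codes.

All rows of retained patients are kept (including acute/elective/other
care), and every specialty observed in the filtered cohort becomes a
matrix column (columns sorted lexicographically, rows by patient id, an
optional minimum-prevalence column filter defaulting to 0).

## Fuzzy c-means

Classic Bezdek alternating optimization of J = Σ u^m d² with squared
Euclidean distance on the raw 0/1 involvement matrix — no scaling, since
all features share the same unit. Numerical choices:

* **Initialization**: a random row-stochastic membership matrix (uniform
  Dirichlet per row) rather than random centroids; under the alternating
  scheme the two are interchangeable and the membership start cannot
  produce empty clusters.
* **Convergence**: maximum absolute membership change < 1e-6, capped at
  200 iterations. The recorded cost sequence is non-increasing (each half
  step is exactly optimal given the other block).
* **Restarts**: `n_init` independent runs (default 100), each seeded by a
  child of the master `numpy.random.SeedSequence`; the run with the lowest
  objective wins, ties to the lowest run index. Everything is reproducible
  from one integer seed.
* **Open-interval memberships**: mathematically `u ∈ (0, 1)` always, but
  at small m the weight `(d_ij/d_min)^(−2/(m−1))` can underflow double
  precision; memberships are floored at machine epsilon and renormalized
  so the open-interval contract survives in floating point. The one
  documented exception is a point coinciding with a centroid: membership
  is split equally over the coincident centroids and exact 0/1 is allowed.
* **Hardening** uses argmax with ties to the lowest cluster index.
* m = 1 is rejected (the limit is k-means; use a k-means implementation).

Two qualitative limits hold and are tested: at m = 1.05 on separable data
the hardened labels agree exactly with Lloyd's k-means, and memberships
flatten towards 1/k as m grows. The flattening is *not* uniform in the
data: FCM has a data-dependent collapse threshold in m, above which all
centroids merge at the global mean and memberships become exactly uniform.
For strongly separated binary prototypes (involvement probabilities
0.9/0.05) the two-cluster solution stays split even at m = 10 with
membership contrast up to ~0.1, whereas at moderate signal (0.85/0.1) the
m = 10 optimum is already collapsed; the flattening test fixture therefore
uses the moderate-signal cohort. The same collapse explains why, on the
default 6-prototype cohort, fits at m = 1.5 return exactly uniform
memberships (partition coefficient 1/k): selection then correctly prefers
m = 1.1.

## Validity indices and hyperparameter selection

Xie–Beni `J/(n · min separation²)` (min), partition coefficient (max),
partition entropy in natural log (min — the base only rescales, never
reorders) and the classic crisp silhouette on hardened labels under
Euclidean distance (max; `fuzzy_silhouette=True` switches to a
membership-margin-weighted variant). The grid is m ∈ {1.1, …, 1.5} ×
k ∈ 5..15 by default.

Selection is two-stage: each index votes with the m of its globally
optimal grid cell and the mode wins (ties to smaller m — the same
tie-break the k-stage uses); then, restricted to the selected m, each
index votes with its optimal k and the mode wins again. Within one index,
ties across cells go to the smallest (m, k). Degenerate cells are recorded
as missing and abstain from that index's vote with a warning: silhouette
when the hardened labels form fewer than two clusters, Xie–Beni when two
centroids coincide (the collapsed large-m fits). The scalar functions
raise instead, as the caller can see the degenerate input.

## Characterization

Under a fuzzy partition, "prevalence of specialty x in cluster y" is
membership-weighted: `O_xy = Σᵢ u_iy X_ix / Σᵢ u_iy`; with crisp
memberships this reduces exactly to the contingency-table prevalence
(tested), and a `hardened=True` variant counts over argmax labels instead.
Two exact identities follow from row-stochastic U and are enforced to
1e-9: `Σ_y EX_xy = 1` per specialty, and `Σ_y O_xy·w_y = n_x` with `w_y`
the cluster membership mass. Thresholds (O/E ≥ 2, EX ≥ 0.25) are
inclusive and configurable; cluster display labels list characterizing
specialties in descending O/E order.

## Subgroup banding

Memberships are binned into [0, 20), [20, 40), [40, 60), [60, 80),
[80, 100] (closed-lower, open-upper; 0.80 is full membership). The
five-step sequential rule is equivalent to classifying each patient by
their canonical band pattern with one exception: a full band absorbs any
secondary band. That exception only matters on the boundary — a patient at
exactly (0.80, 0.20) holds a FULL and a LOW band and is treated as fully
belonging, since membership mass makes two FULLs or FULL + DOM infeasible
(asserted at runtime, not assumed). A dominant patient keys its subgroup
by the dominant cluster plus any low secondaries; mid/low patients by all
their significant bands. Subgroups below `min_size` (default 100, the
scale at which a targeted hospital intervention is practical) dissolve
into the rest group; raising `min_size` can only shrink the set of
retained subgroups, never move a patient between two retained ones.

Naming: full-membership subgroups carry their 1-based cluster index
("4"); every other pattern gets the ascending cluster indices joined by
hyphens plus a letter ("1-5-a", "1-5-b", …) assigned per cluster set in
descending subgroup size, ties broken by the canonical pattern order. The
letter order is a display convention, not a quantity.

Profiles report, per subgroup: n; per-cluster mean membership (%) and SD;
female count and %; median and IQR (reported as the single value Q3 − Q1,
linear interpolation between order statistics) of age, involved
specialties, outpatient visits, ED visits, inpatient days and distinct
diagnoses; the top-5 specialties by % involved and top-10 diagnosis groups
by % of members, with alphabetical tie-breaks. The rest group is profiled
too, flagged `is_rest`.

## Synthetic cohort generator

The generator emulates the *structure* of a one-year hospital billing
extract, not any real hospital's margins. K prototypes (default 6) each
carry `high_prob` = 0.9 on a disjoint signature block of 3 specialties in
a 22-specialty catalog and `low_prob` = 0.05 elsewhere; a
`blend_fraction` = 0.2 of patients draws involvement from the elementwise
mean of two prototype rows (chosen because combination subgroups imply
patients genuinely shared between two specialty patterns). Each involved
specialty receives at least one chronic/oncological diagnosis row with at
least one outpatient visit from a 32-group catalog with
specialty-affinity, plus Poisson extra diagnoses and Poisson utilization
counts (outpatient mean 2, ED 0.3, inpatient 1 with 30% admission
probability); ages are normal (67, 15) clipped to [18, 98] and 56% of
patients are female — values typical of a multimorbid hospital population.
Every generated patient passes the inclusion filter by construction;
`inject_subthreshold_patients` appends filter-violating patients (minors,
acute-only, no outpatient care) for stress tests.

What passing tests on this generator do **not** show about real data: real
involvement is not conditionally independent Bernoulli (comorbidity
induces correlated involvement beyond the planted patterns), real cluster
prevalences are unbalanced, specialties can belong to several patterns,
and real blended patients are not exact 50/50 mixtures. One measured
consequence: under Bernoulli blending, a blended patient lands in a
two-cluster combination subgroup essentially only when its draw hits
exactly as many signature specialties of each parent (probability ≈ 0.31
for 3-specialty signatures), because any asymmetry is amplified by the
membership exponent 2/(m−1) into a near-crisp membership; only ~22% of
blended patients reach their pair-combination subgroup at any m in the
grid. Recovery of the planted *cluster structure* is nevertheless sharp
(k = 6 selected, ARI ≈ 0.97 on pure patients, ~98% of pure patients in
their planted full-membership subgroup).

## Problem sizes

The test bench and the acceptance script run the full pipeline at n =
5,000 patients with a 3 × 6 (m, k) grid and 20 restarts per cell — enough
for the selection rule and the recovery statistics to be stable across
seeds — and the brute-force optimality check compares multistart fits
against 10⁵ random membership matrices on instances with n ≤ 8. These
sizes are the package's own test design; the library itself has no
such limits.
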