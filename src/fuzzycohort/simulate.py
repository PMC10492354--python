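"""Synthetic multimorbidity cohort generator with planted specialty-pattern
structure.

The generator emulates a one-year hospital extract: each synthetic patient
is assigned either a single "prototype" involvement pattern (a set of
signature specialties that tend to be involved together) or a blend of two
prototypes, and their binary specialty-involvement vector is drawn
Bernoulli-wise from the prototype probabilities (``high_prob`` on signature
specialties, ``low_prob`` background elsewhere; blends use the elementwise
mean of the two prototype rows).  Each involved specialty then receives
diagnosis rows from a catalog of diagnosis groups with specialty
affinities, with Poisson care-activity counts; every generated patient is
guaranteed to satisfy the adult-multimorbidity inclusion criteria unless
sub-threshold patients are injected explicitly for stress testing.

The planted pure/blend assignment is returned alongside the table so that
downstream cluster and subgroup recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_SPECIALTIES",
    "DEFAULT_DIAGNOSIS_CATALOG",
    "GeneratorConfig",
    "make_prototypes",
    "simulate_cohort",
    "inject_subthreshold_patients",
]

#: 22 medical specialties of a middle-large Dutch general hospital.
TABLE_SPECIALTIES = (
    "internal medicine", "cardiology", "general surgery", "neurology",
    "pulmonology", "dermatology", "ophthalmology", "otorhinolaryngology",
    "orthopedic surgery", "urology", "gastroenterology", "rheumatology",
    "gynecology", "geriatrics", "plastic surgery", "anesthesiology",
    "dental surgery", "physiatry", "psychiatry", "neurosurgery",
    "pediatrics", "radiology",
)

#: (diagnosis_group, diagnosis_type, affinity specialties); an empty
#: affinity tuple means the group can appear under any specialty.  Groups
#: follow the CCS-style naming of hospital diagnosis classifications.
DEFAULT_DIAGNOSIS_CATALOG = (
    ("diabetes mellitus with complications", "chronic", ("internal medicine", "geriatrics")),
    ("chronic kidney disease", "chronic", ("internal medicine",)),
    ("thyroid disorders", "chronic", ("internal medicine",)),
    ("osteoporosis", "chronic", ("internal medicine", "rheumatology")),
    ("congestive heart failure; non-hypertensive", "chronic", ("cardiology",)),
    ("cardiac dysrhythmias", "chronic", ("cardiology",)),
    ("other circulatory disease", "chronic", ("cardiology", "internal medicine")),
    ("asthma", "chronic", ("pulmonology",)),
    ("chronic obstructive pulmonary disease and bronchiectasis", "chronic", ("pulmonology",)),
    ("other lower respiratory disease", "chronic", ("pulmonology",)),
    ("other upper respiratory disease", "acute", ("otorhinolaryngology", "pulmonology")),
    ("other nervous system disorders", "chronic", ("neurology", "neurosurgery")),
    ("headache; including migraine", "chronic", ("neurology",)),
    ("parkinson's disease", "chronic", ("neurology", "geriatrics")),
    ("spondylosis; intervertebral disc disorders; other back problems", "chronic",
     ("orthopedic surgery", "neurosurgery", "physiatry", "anesthesiology")),
    ("osteoarthritis", "chronic", ("orthopedic surgery", "rheumatology")),
    ("other connective tissue disease", "chronic", ("rheumatology", "physiatry")),
    ("other non-traumatic joint disorders", "chronic", ("orthopedic surgery", "rheumatology")),
    ("other skin disorders", "chronic", ("dermatology",)),
    ("other inflammatory condition of skin", "chronic", ("dermatology",)),
    ("other non-epithelial cancer of skin", "oncological", ("dermatology", "plastic surgery")),
    ("melanomas of skin", "oncological", ("dermatology", "general surgery")),
    ("cancer of breast", "oncological", ("general surgery", "internal medicine")),
    ("cancer of prostate", "oncological", ("urology",)),
    ("cancer of colon", "oncological", ("gastroenterology", "general surgery")),
    ("other gastrointestinal disorders", "chronic", ("gastroenterology",)),
    ("cataract", "elective", ("ophthalmology",)),
    ("other eye disorders", "chronic", ("ophthalmology",)),
    ("other female genital disorders", "elective", ("gynecology",)),
    ("other ear and sense organ disorders", "chronic", ("otorhinolaryngology", "dental surgery")),
    ("delirium dementia and amnestic and other cognitive disorders", "chronic",
     ("geriatrics", "psychiatry")),
    ("residual codes; unclassified", "other", ()),
)


class ConfigError(ValueError):
    """Inconsistent generator configuration."""


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the planted-structure regime used throughout the
    test-bench: 6 prototypes over 22 specialties with 3 signature
    specialties each, strong signal (high_prob 0.9 vs low_prob 0.05) and a
    20% blended fraction.
    """

    n_patients: int = 5000
    specialty_catalog: tuple = TABLE_SPECIALTIES
    n_prototypes: int = 6
    signature_size: int = 3
    high_prob: float = 0.9
    low_prob: float = 0.05
    blend_fraction: float = 0.2
    diagnosis_catalog: tuple = DEFAULT_DIAGNOSIS_CATALOG
    outpatient_mean: float = 2.0
    ed_mean: float = 0.3
    inpatient_mean: float = 1.0
    extra_dx_mean: float = 0.5
    age_mean: float = 67.0
    age_sd: float = 15.0
    age_min: float = 18.0
    age_max: float = 98.0
    female_fraction: float = 0.56
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if not (0 <= self.low_prob < self.high_prob <= 1):
            raise ConfigError("need 0 <= low_prob < high_prob <= 1")
        if not (0 <= self.blend_fraction <= 1):
            raise ConfigError("blend_fraction must be in [0, 1]")
        if self.n_prototypes < 1:
            raise ConfigError("n_prototypes must be >= 1")
        if self.signature_size < 1:
            raise ConfigError("signature_size must be >= 1")
        if self.signature_size * self.n_prototypes > len(self.specialty_catalog):
            raise ConfigError(
                "disjoint signatures impossible: signature_size * n_prototypes "
                f"= {self.signature_size * self.n_prototypes} exceeds the "
                f"{len(self.specialty_catalog)} available specialties")
        return self


def make_prototypes(config: GeneratorConfig) -> np.ndarray:
    """K x p matrix of involvement probabilities.

    Prototype j carries ``high_prob`` on its ``signature_size`` signature
    specialties (consecutive disjoint blocks of the catalog) and
    ``low_prob`` elsewhere.
    """
    config.validate()
    p = len(config.specialty_catalog)
    protos = np.full((config.n_prototypes, p), config.low_prob)
    for j in range(config.n_prototypes):
        block = slice(j * config.signature_size, (j + 1) * config.signature_size)
        protos[j, block] = config.high_prob
    return protos


def _draw_assignments(config: GeneratorConfig, rng) -> list:
    """Planted label per patient: (j,) for pure, (j, l) with j < l for blends."""
    K = config.n_prototypes
    pairs = [(a, b) for a in range(K) for b in range(a + 1, K)]
    out = []
    for _ in range(config.n_patients):
        if K >= 2 and pairs and rng.random() < config.blend_fraction:
            out.append(pairs[rng.integers(len(pairs))])
        else:
            out.append((int(rng.integers(K)),))
    return out


def _qualifying_pools(config: GeneratorConfig):
    """Per-specialty pools of chronic/oncological catalog indices."""
    catalog = config.diagnosis_catalog
    qualifying = [i for i, (_, t, _a) in enumerate(catalog)
                  if t in ("chronic", "oncological")]
    if not qualifying:
        raise ConfigError("diagnosis catalog has no chronic/oncological group")
    pools = {}
    for s in config.specialty_catalog:
        pool = [i for i in qualifying
                if not catalog[i][2] or s in catalog[i][2]]
        pools[s] = pool or qualifying
    any_pools = {}
    for s in config.specialty_catalog:
        pool = [i for i, (_, _t, aff) in enumerate(catalog)
                if not aff or s in aff]
        any_pools[s] = pool or list(range(len(catalog)))
    return qualifying, pools, any_pools


def simulate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``(encounters, ground_truth)``; fully reproducible from the seed.

    Every involved specialty receives at least one chronic or oncological
    diagnosis row with at least one outpatient visit, and every patient
    carries at least two distinct qualifying diagnoses, so the generated
    cohort passes the inclusion filter by construction.  ``ground_truth``
    has columns patient_id, prototype_1, prototype_2 (empty for pure
    patients; prototype indices are 0-based).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    protos = make_prototypes(config)
    assignments = _draw_assignments(config, rng)
    qualifying, qual_pools, any_pools = _qualifying_pools(config)
    catalog = config.diagnosis_catalog
    specialties = list(config.specialty_catalog)
    p = len(specialties)

    rows = []
    truth = []
    id_width = max(5, len(str(max(config.n_patients - 1, 0))))
    for i, assigned in enumerate(assignments):
        pid = f"P{i:0{id_width}d}"
        probs = protos[list(assigned)].mean(axis=0)
        involved = rng.random(p) < probs
        if not involved.any():
            # force one signature specialty of the (first) planted prototype
            involved[assigned[0] * config.signature_size] = True
        age = float(np.clip(np.round(rng.normal(config.age_mean, config.age_sd)),
                            config.age_min, config.age_max))
        sex = "female" if rng.random() < config.female_fraction else "male"

        # (specialty, catalog index) -> ensure one qualifying dx per specialty
        dx_rows = {}
        for s_idx in np.flatnonzero(involved):
            s = specialties[s_idx]
            ci = qual_pools[s][rng.integers(len(qual_pools[s]))]
            dx_rows[(s, ci)] = 1 + rng.poisson(max(config.outpatient_mean - 1, 0.0))
            for _ in range(rng.poisson(config.extra_dx_mean)):
                cj = any_pools[s][rng.integers(len(any_pools[s]))]
                dx_rows.setdefault((s, cj), rng.poisson(config.outpatient_mean))
        # guarantee >= 2 distinct qualifying diagnosis codes with a visit
        have = {ci for (s, ci), v in dx_rows.items()
                if ci in qualifying and v >= 1}
        while len(have) < 2:
            s = specialties[int(np.flatnonzero(involved)[0])]
            remaining = [c for c in qualifying if c not in have]
            ci = remaining[rng.integers(len(remaining))]
            dx_rows[(s, ci)] = 1 + rng.poisson(max(config.outpatient_mean - 1, 0.0))
            have.add(ci)

        for (s, ci), visits in sorted(dx_rows.items()):
            group, dtype, _aff = catalog[ci]
            rows.append((pid, age, sex, s, f"D{ci:03d}", group, dtype,
                         int(visits), int(rng.poisson(config.ed_mean)),
                         int(rng.poisson(config.inpatient_mean)
                             if rng.random() < 0.3 else 0)))
        truth.append((pid, assigned[0],
                      assigned[1] if len(assigned) == 2 else pd.NA))

    encounters = pd.DataFrame(rows, columns=[
        "patient_id", "age_years", "sex", "specialty", "diagnosis_code",
        "diagnosis_group", "diagnosis_type", "outpatient_visits", "ed_visits",
        "inpatient_days"])
    ground_truth = pd.DataFrame(truth, columns=["patient_id", "prototype_1",
                                                "prototype_2"])
    ground_truth["prototype_2"] = ground_truth["prototype_2"].astype("Int64")
    return encounters, ground_truth


def inject_subthreshold_patients(table: pd.DataFrame, count: int,
                                 seed: int = 0) -> pd.DataFrame:
    """Append ``count`` patients that violate the inclusion criteria.

    Cycles through three violation modes: a minor with several chronic
    diagnoses; an adult with only acute/elective diagnoses; an adult whose
    chronic diagnoses have zero outpatient visits.  Used to stress-test the
    inclusion filter.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(count):
        pid = f"X{i:05d}"
        mode = i % 3
        if mode == 0:   # minor, otherwise fully qualifying
            for ci in (0, 1, 2):
                rows.append((pid, 17.0, "female", "internal medicine",
                             f"D{ci:03d}", f"synthetic minor group {ci}",
                             "chronic", 2, 0, 0))
        elif mode == 1:  # acute/elective only
            rows.append((pid, 70.0, "male", "general surgery", "D900",
                         "appendicitis and other appendiceal conditions",
                         "acute", int(rng.integers(1, 4)), 1, 2))
            rows.append((pid, 70.0, "male", "ophthalmology", "D901",
                         "cataract", "elective", 1, 0, 0))
        else:            # chronic but never seen in the outpatient clinic
            for ci in (10, 11):
                rows.append((pid, 70.0, "female", "cardiology",
                             f"D9{ci}", "other circulatory disease",
                             "chronic", 0, 1, 3))
    extra = pd.DataFrame(rows, columns=list(table.columns))
    return pd.concat([table, extra], ignore_index=True)
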