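"""End-to-end pipeline: cohort -> grid-selected FCM fit -> characterization
-> banded subgroups -> profiles.

Used by the ``run-all`` CLI command and by programmatic callers that want
the whole analysis from one configuration and one master seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .characterization import ClusterCharacterization, characterize
from .io import CohortMatrix, apply_inclusion_filter, build_involvement_matrix
from .model_selection import FcmGridSelector
from .simulate import GeneratorConfig, simulate_cohort
from .subgroups import (SubgroupAssignment, assign_subgroups, enforce_min_size,
                        name_subgroups, profile_subgroups)

logger = logging.getLogger("fuzzycohort")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    encounters: pd.DataFrame
    ground_truth: pd.DataFrame | None
    matrix: CohortMatrix
    selector: FcmGridSelector
    characterization: ClusterCharacterization
    raw_assignment: SubgroupAssignment
    assignment: SubgroupAssignment
    names: dict
    profiles: list = field(repr=False, default=None)

    @property
    def membership(self) -> np.ndarray:
        return self.selector.best_fit_.membership


def run_pipeline(*, encounters: pd.DataFrame | None = None,
                 generator: GeneratorConfig | None = None,
                 m_grid=(1.1, 1.2, 1.3, 1.4, 1.5),
                 k_grid=tuple(range(5, 16)),
                 n_init: int = 100,
                 min_size: int = 100,
                 min_age: float = 18,
                 require_outpatient_visit: bool = True,
                 seed: int | None = None,
                 profile: bool = True) -> PipelineResult:
    """Run the full analysis and return every intermediate product.

    Either pass a validated encounter table or a :class:`GeneratorConfig`
    (its own seed is overridden by ``seed`` when given).
    """
    truth = None
    if encounters is None:
        if generator is None:
            raise ValueError("pass either encounters or a generator config")
        if seed is not None:
            from dataclasses import replace
            generator = replace(generator, seed=int(seed))
        logger.info("simulating cohort: %s", asdict(generator))
        encounters, truth = simulate_cohort(generator)

    filtered = apply_inclusion_filter(
        encounters, min_age=min_age,
        require_outpatient_visit=require_outpatient_visit)
    matrix = build_involvement_matrix(filtered)
    logger.info("cohort matrix: %d patients x %d specialties", *matrix.shape)

    selector = FcmGridSelector(m_grid=m_grid, k_grid=k_grid, n_init=n_init,
                               random_state=seed).fit(matrix.values)
    logger.info("selected m=%s (votes %s), k=%s (votes %s)",
                selector.best_m_, selector.m_votes_,
                selector.best_k_, selector.k_votes_)

    fit = selector.best_fit_
    char = characterize(fit.membership, matrix.values,
                        specialty_names=matrix.specialty_names)
    raw = assign_subgroups(fit.membership, patient_ids=matrix.patient_ids)
    final = enforce_min_size(raw, min_size=min_size)
    names = name_subgroups(final)
    profiles = None
    if profile:
        profiles = profile_subgroups(final, filtered, matrix, fit.membership,
                                     names=names)
    return PipelineResult(encounters=filtered, ground_truth=truth,
                          matrix=matrix, selector=selector,
                          characterization=char, raw_assignment=raw,
                          assignment=final, names=names, profiles=profiles)
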