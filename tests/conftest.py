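"""Shared fixtures: compact synthetic cohorts generated at test time."""

import numpy as np
import pytest

import oncopanel as op


def small_composition() -> op.CascadeComposition:
    """A scaled-down cascade composition with every subset populated."""
    return op.CascadeComposition(
        n_total=150, n_absent_cosmic=25, n_of_those_in_icgc=3,
        n_confirmed_somatic=70, n_pathogenic=50,
        n_pathogenic_with_prior_large_intestine_report=35,
        n_sift_deleterious=12, n_sift_tolerated=10,
        n_polyphen_damaging=25, n_polyphen_benign=12,
        n_germline_band=6, n_germline_maf_supported=4,
        consequence_counts={"synonymous": 25, "missense": 35, "other": 10},
    )


def small_config(seed: int = 5, n_patients: int = 60) -> op.CohortConfig:
    return op.CohortConfig(
        n_patients=n_patients, variants_per_patient=15,
        composition=small_composition(),
        panel_genes=[f"G{i:03d}" for i in range(1, 26)], seed=seed,
    )


@pytest.fixture(scope="session")
def demo_cohort() -> op.Cohort:
    return op.generate_cohort(small_config())


@pytest.fixture(scope="session")
def demo_classified(demo_cohort):
    return op.classify(demo_cohort.calls, demo_cohort.annotations)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
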