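"""Shared fixtures: one moderately sized planted cohort reused across tests."""

import warnings

import pytest

import episignkit as ek


@pytest.fixture(scope="session")
def planted_cohort():
    """A 16-case / 64-control cohort with 150 planted probes at delta 0.15."""
    cfg = ek.SimulationConfig(
        n_probes=5000, n_signature=150, n_database=60, seed=42
    )
    return ek.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_stats(planted_cohort):
    return ek.differential_analysis(planted_cohort.beta, planted_cohort.samples)


@pytest.fixture(scope="session")
def planted_signature(planted_cohort, planted_stats):
    sheet = planted_cohort.samples
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ek.select_probes(
            planted_stats,
            planted_cohort.beta,
            sheet.ids_in_group("case"),
            sheet.ids_in_group("control"),
        )


@pytest.fixture(scope="session")
def trained_model(planted_cohort, planted_signature):
    sheet = planted_cohort.samples
    pool = ek.TrainingPool(
        sheet.ids_in_group("case"),
        sheet.ids_in_group("control"),
        sheet.ids_in_group("database"),
    )
    return ek.train_mvp(planted_signature, planted_cohort.beta, pool, seed=7)
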