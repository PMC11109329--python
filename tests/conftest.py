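import numpy as np
import pandas as pd
import pytest

from famseg import SimConfig, build_paper_fixture, simulate_cohort


@pytest.fixture(scope="session")
def fx():
    """The curated multiplex-family reference cohort."""
    return build_paper_fixture()


@pytest.fixture(scope="session")
def cohort(fx):
    return fx.cohort


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated cohort (small families, few background variants)."""
    cfg = SimConfig(
        n_families=5,
        sibship_min=2,
        sibship_max=4,
        n_background=200,
        seed=11,
    )
    return simulate_cohort(cfg)


def clone_with_genotypes(cohort, G):
    """Rebuild a cohort around a modified genotype matrix."""
    from famseg import CohortModel

    return CohortModel(
        pedigrees=cohort.pedigrees,
        variants=cohort.variants,
        G=G,
        samples=cohort.samples,
        annotations=cohort.annotations,
        D=cohort.D,
    )
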