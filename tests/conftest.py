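import numpy as np
import pandas as pd
import pytest

from sumtwas import LDPanel
from sumtwas.studies import (
    multitissue_exclusivity_study,
    null_calibration_study,
    summary_vs_individual_study,
)

SEED = 1


@pytest.fixture(scope="session")
def null_study():
    """Global-null study: models exist, every gene-trait effect is zero."""
    return null_calibration_study(SEED)


@pytest.fixture(scope="session")
def oracle_study():
    """Summary-statistic vs individual-level z-score comparison study."""
    return summary_vs_individual_study(SEED)


@pytest.fixture(scope="session")
def multitissue_study():
    """Five-tissue study with focal-only truth genes and two phenotypes."""
    return multitissue_exclusivity_study(SEED)


def make_panel(dosages, positions=None, variant_ids=None, freqs=None) -> LDPanel:
    """Hand-build a small LDPanel from a dosage matrix (individuals x variants)."""
    dosages = np.asarray(dosages)
    m = dosages.shape[1]
    ids = variant_ids or [f"v{i + 1}" for i in range(m)]
    pos = positions if positions is not None else (np.arange(m) + 1) * 1000
    freq = freqs if freqs is not None else dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": pos,
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
            "freq": freq,
        }
    )
    return LDPanel(variants=variants, genotypes=dosages)


@pytest.fixture
def small_panel():
    rng = np.random.default_rng(42)
    return make_panel(rng.integers(0, 3, size=(200, 6)))
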