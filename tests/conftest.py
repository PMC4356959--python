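import numpy as np
import pytest

from otochron.io import IndexSeries


def make_index_set(rng, n=20, years=40, share=0.5, first_year=1970,
                   scale=0.1):
    """Index-series set with a white common signal of known variance share.

    Each series is exp(scale * (sqrt(share)*common + sqrt(1-share)*noise)),
    positive with mean near 1, so pairwise correlations equal ``share`` in
    expectation.
    """
    common = rng.standard_normal(years)
    a, b = np.sqrt(share), np.sqrt(1 - share)
    return [
        IndexSeries(
            owner_id=f"S{i:02d}", level="ims", first_year=first_year,
            indices=np.exp(scale * (a * common + b * rng.standard_normal(years))),
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def weak_dataset():
    """Default study-condition dataset: 44 fish, common share 0.035."""
    from otochron.simulate import SimulationConfig, generate_dataset

    return generate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def strong_dataset():
    """Strong-signal dataset for recovery/QC tests."""
    from otochron.simulate import SimulationConfig, generate_dataset

    return generate_dataset(SimulationConfig(seed=11, common_share=0.5))
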