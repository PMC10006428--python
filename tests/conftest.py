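import pytest

from gymnome import synthetic_data as sd
from gymnome.io_formats import Interval


@pytest.fixture(scope="session")
def methylome_dataset():
    """Medium methylome simulation with two planted valleys (session-cached)."""
    params = sd.MethylomeSimParams(
        seed=7,
        planted_dmvs=(
            Interval("chr1", 100_000, 110_000),
            Interval("chr1", 400_000, 412_000),
        ),
    )
    records, lambda_records, truth = sd.simulate_methylome(params)
    return params, records, lambda_records, truth


@pytest.fixture(scope="session")
def hgt_dataset():
    params = sd.HgtSimParams(seed=11)
    tables, species_map, truth = sd.simulate_hgt_tables(params)
    return params, tables, species_map, truth
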