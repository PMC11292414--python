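import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_omics():
    """Default-condition synthetic omics data with ground truth."""
    from karyoamp.simulate import OmicsSimConfig, gen_omics

    return gen_omics(OmicsSimConfig(seed=5))


@pytest.fixture(scope="session")
def informative_feature_table():
    """Feature table from the karyotype generator at its informative defaults
    (n=800, seed=7), labelled with the underlying truth."""
    from karyoamp.features import engineer_features, impute_by_ploidy
    from karyoamp.karyotype import parse_karyotype
    from karyoamp.simulate import KaryotypeSimConfig, gen_karyotype_records

    records, truth, _ = gen_karyotype_records(KaryotypeSimConfig(n_samples=800, seed=7))
    profiles = [parse_karyotype(r.raw_text) for r in records]
    ids = [r.cell_line_id for r in records]
    table = engineer_features(
        profiles,
        ids,
        ecdna=truth["ecdna_true"].tolist(),
        hsr=truth["hsr_true"].tolist(),
    )
    return impute_by_ploidy(table)
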