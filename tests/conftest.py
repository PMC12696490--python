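import pytest
from hypothesis import HealthCheck, settings

import moscovery as m

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_study():
    """A light synthetic study: 20 chrY exons, k=10, 80 samples at 40x."""
    cfg = m.SimConfig(n_samples=80, prevalence=0.15, mean_depth=40.0, seed=11)
    return m.simulate_study(cfg, k=10, n_genes=4, exons_per_gene=5, n_candidates=1500)


@pytest.fixture(scope="session")
def full_study():
    """Full-size study conditions: ~170-exon panel, k=100, 500 samples,
    10% carrier prevalence, carrier cell fractions uniform on [0.1, 0.8],
    50x mean depth."""
    return m.simulate_study(m.SimConfig(seed=2026))


@pytest.fixture(scope="session")
def full_estimates(full_study):
    norm = m.CoverageNormalizer(match_table=full_study.matches)
    norm.fit(full_study.coverage.depth)
    return norm.transform(full_study.coverage.depth)
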