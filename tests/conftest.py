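import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rvth.experiment import GridSpec, estimate_size, summarize
from rvth.simulate import SimulationConfig, build_gene, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: study-scale null replication: 5000 cohorts at the design defaults
#: (2000 subjects, CDS = median human gene, covariate explaining 15% of
#: trait variance), shared by the size-control and p-value-uniformity tests
NULL_RUN_SEED = 42
NULL_RUN_CELL = (0.0, 0.5, 0.15, 1209.0)


@pytest.fixture(scope="session")
def null_size_run():
    spec = GridSpec(
        deltas=(0.0,), zetas=(0.5,), rsqs=(0.15,), cds_lengths=(1209.0,),
        n_sims_size=5000, alpha=0.01,
        methods=("TH", "RCS-C", "CA", "CA-P", "SK-R"),
    )
    results, pvalues = estimate_size(
        spec, SimulationConfig(), master_seed=NULL_RUN_SEED, return_pvalues=True
    )
    return summarize(results), pvalues[NULL_RUN_CELL]


@pytest.fixture(scope="session")
def small_cohort():
    rng = np.random.default_rng(7)
    config = SimulationConfig(n_cases=120, n_controls=120, rsq=0.15, delta=0.5,
                              zeta=0.8, cds_length=4057.0)
    gene = build_gene(config.cds_length, config.class_probs, config.zeta,
                      config.wright, rng)
    return simulate_cohort(config, gene, rng)
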