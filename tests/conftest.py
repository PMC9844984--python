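import numpy as np
import pytest

import meioscan as ms


@pytest.fixture(scope="session")
def moderate_run():
    """A mid-sized simulated dataset with a full pipeline run.

    200 gametes x 3000 underlying hetSNPs at 0.1x coverage: small enough to
    run in a fraction of a second, large enough that phasing, imputation and
    crossover discovery all operate in their intended regime.
    """
    params = ms.SimParams(
        n_gametes=200, n_hetsnps=3000, coverage=0.1, recomb_rate=1.0,
        error_rate=0.005, seed=17,
    )
    gm, truth = ms.simulate_dataset(params)
    result = ms.run_pipeline(gm, ms.RunConfig(window_length=1000))
    return params, gm, truth, result


@pytest.fixture(scope="session")
def noiseless_run():
    """Full-coverage, error-free dataset: the exact-recovery limit."""
    params = ms.SimParams(
        n_gametes=60, n_hetsnps=500, coverage=50.0, recomb_rate=1.0,
        error_rate=0.0, seed=5,
    )
    gm, truth = ms.simulate_dataset(params)
    result = ms.run_pipeline(gm, ms.RunConfig(window_length=200))
    return params, gm, truth, result


def make_matrix(genotypes, positions=None, gamete_ids=None, **kwargs):
    geno = np.asarray(genotypes, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, geno.shape[0] + 1)
    if gamete_ids is None:
        gamete_ids = [f"g{j}" for j in range(geno.shape[1])]
    return ms.GameteMatrix(positions=positions, gamete_ids=gamete_ids, genotypes=geno, **kwargs)
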