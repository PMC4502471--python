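import numpy as np
import pytest

import spliceonet as sn

BENCH_SEEDS = (1, 2, 3)


def run_pipeline(seed: int):
    """Full synthetic study: generate data, fit the model, score all pairs."""
    spec = sn.BenchmarkSpec(seed=seed)
    bench = sn.generate_benchmark(spec)
    model = sn.fit_conditional_models(bench.observed_net, bench.expr, seed=seed)
    pnet = sn.build_ps_network(bench.catalog, bench.observed_net, bench.expr, model)
    return spec, bench, model, pnet


@pytest.fixture(scope="session")
def pipelines():
    """One fitted pipeline per benchmark seed, shared across tests."""
    return {seed: run_pipeline(seed) for seed in BENCH_SEEDS}


@pytest.fixture()
def toy_pnet():
    """4 proteins, hand-set probabilities."""
    pin = np.array([
        [0.0, 0.9, 0.2, 0.05],
        [0.9, 0.0, 0.1, 0.4],
        [0.2, 0.1, 0.0, 0.7],
        [0.05, 0.4, 0.7, 0.0],
    ])
    return sn.ProbabilisticNetwork(["a", "b", "c", "d"], pin)


def random_pnet(rng: np.random.Generator, n: int, density: float = 0.4,
                low: float = 0.05, high: float = 1.0) -> sn.ProbabilisticNetwork:
    """Random sparse symmetric probability matrix."""
    pin = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                pin[i, j] = pin[j, i] = rng.uniform(low, high)
    return sn.ProbabilisticNetwork([f"N{k}" for k in range(n)], pin)
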