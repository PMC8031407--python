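import numpy as np
import pandas as pd
import pytest

from stressdeg.de_consensus import de_analysis
from stressdeg.io_model import CountMatrix, SampleMeta
from stressdeg.synthetic_data import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """One modest leaf-only simulated experiment shared across tests."""
    cfg = SimConfig(n_genes=300, tissues=("leaf",), seed=7)
    cm, truth = simulate_experiment(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def small_de(small_experiment):
    _, cm, _ = small_experiment
    results, calls = de_analysis(cm)
    return results, calls


def make_count_matrix(counts, genotype="Ba12", tissue="leaf",
                      ewcs=(35, 15), n_reps=None):
    """Wrap a raw gene x sample array as a CountMatrix with a two-group
    (ref EWC, test EWC) design; columns split evenly between the groups."""
    arr = np.asarray(counts, dtype=np.int64)
    n = arr.shape[1]
    if n_reps is None:
        n_reps = n // 2
    samples = []
    for j in range(n):
        ewc = ewcs[0] if j < n_reps else ewcs[1]
        rep = j + 1 if j < n_reps else j - n_reps + 1
        samples.append(SampleMeta(f"s{j}", genotype, tissue, ewc, rep))
    genes = [f"g{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=genes, columns=[s.sample_id for s in samples])
    return CountMatrix(genes, samples, df)
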