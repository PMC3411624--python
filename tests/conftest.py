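import numpy as np
import pandas as pd
import pytest

from jedkit import GeneratorConfig, gen_probe_data
from jedkit.containers import ProbeLevelMatrix


@pytest.fixture
def small_probe_data() -> ProbeLevelMatrix:
    """10 genes x 4 probes x 4 arrays with noise, seeded."""
    return gen_probe_data(
        GeneratorConfig(genes=10, probes_per_gene=4, arrays=4, noise_sd=0.25, seed=11)
    )


@pytest.fixture
def tiny_gene_data() -> ProbeLevelMatrix:
    """One gene, probe matrix [[1, 2], [3, 4]] on two arrays."""
    intens = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0]],
        index=pd.Index(["g1_p1", "g1_p2"], name="probe_id"),
        columns=["A1", "A2"],
    )
    return ProbeLevelMatrix(intens, pd.Series(["g1", "g1"], index=intens.index))


def make_probe_data(values: np.ndarray, genes_of_probes, arrays) -> ProbeLevelMatrix:
    """Build a ProbeLevelMatrix from an array and explicit probe->gene labels."""
    values = np.asarray(values, dtype=float)
    idx = pd.Index([f"p{k + 1}" for k in range(values.shape[0])], name="probe_id")
    intens = pd.DataFrame(values, index=idx, columns=list(arrays))
    return ProbeLevelMatrix(intens, pd.Series(list(genes_of_probes), index=idx))
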