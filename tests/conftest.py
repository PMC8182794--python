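import numpy as np
import pandas as pd
import pytest

from dimoshift import (
    CountMatrix,
    QLDifferentialExpression,
    SimulationConfig,
    TMMNormalizer,
    filter_low_expression,
    simulate_counts,
)


def make_count_matrix(counts: np.ndarray, n_reps: int = 3) -> CountMatrix:
    """Wrap a (genes x 4*n_reps) array in a CountMatrix with the 2x2 design."""
    groups = [("F", "control"), ("F", "cold"), ("M", "control"), ("M", "cold")]
    cols, rows = [], []
    for sex, temp in groups:
        for r in range(1, n_reps + 1):
            cols.append(f"{sex}_{temp}_{r}")
            rows.append({"library_id": f"{sex}_{temp}_{r}", "sex": sex,
                         "temperature": temp, "replicate": r})
    counts = np.asarray(counts)
    frame = pd.DataFrame(
        counts, columns=cols,
        index=pd.Index([f"g{i}" for i in range(counts.shape[0])], name="gene_id"),
    )
    return CountMatrix(frame, pd.DataFrame(rows).set_index("library_id"))


@pytest.fixture(scope="session")
def sim_default():
    """Moderate-size simulation at the default (study-like) conditions."""
    cm, truth = simulate_counts(SimulationConfig(n_genes=1200, seed=42))
    return cm, truth


@pytest.fixture(scope="session")
def de_chain(sim_default):
    """Filter -> TMM -> QL GLM chain on the default simulation."""
    cm, truth = sim_default
    filtered = filter_low_expression(cm)
    norm = TMMNormalizer().fit(filtered).transform(filtered)
    de = QLDifferentialExpression().fit(filtered, norm=norm)
    return filtered, norm, de, truth
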