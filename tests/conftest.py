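import numpy as np
import pandas as pd
import pytest

from stressflux import DETable, SimCountSpec, ToyNetworkSpec, generate_toy_model, simulate_counts


@pytest.fixture(scope="session")
def chain_model():
    return generate_toy_model(ToyNetworkSpec(variant="chain"))


@pytest.fixture(scope="session")
def branched_model():
    return generate_toy_model(ToyNetworkSpec(variant="branched"))


@pytest.fixture(scope="session")
def reversible_model():
    return generate_toy_model(ToyNetworkSpec(variant="reversible"))


@pytest.fixture(scope="session")
def small_counts():
    """300-gene 4v4 matrix with the study-like planted signal, desk scale."""
    spec = SimCountSpec(n_genes=300, library_size_mean=1e5, seed=1)
    return simulate_counts(spec)


def make_detable(log2fcs: dict[str, float], ns_genes: tuple[str, ...] = ()) -> DETable:
    """DE table with the given significant log2 fold changes (p = 1e-4)."""
    genes = list(log2fcs) + list(ns_genes)
    lfc = np.array([log2fcs.get(g, 0.0) for g in genes])
    status = np.array(
        ["up" if v > 0 else "down" for v in lfc[: len(log2fcs)]]
        + ["ns"] * len(ns_genes)
    )
    frame = pd.DataFrame(
        {
            "log2fc": lfc,
            "fold_change_signed": np.where(lfc == 0, 1.0, np.sign(lfc) * 2.0 ** np.abs(lfc)),
            "p_value": [1e-4] * len(log2fcs) + [0.5] * len(ns_genes),
            "status": status,
        },
        index=pd.Index(genes, name="gene"),
    )
    return DETable(frame)
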