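import numpy as np
import pytest

from tgx_hdaci import (
    CompoundProfile,
    SimConfig,
    asset_to_model,
    load_builtin_biomarker,
    make_oracle_instance,
)


@pytest.fixture(scope="session")
def asset():
    return load_builtin_biomarker()


@pytest.fixture(scope="session")
def panel_model(asset):
    return asset_to_model(asset)


@pytest.fixture(scope="session")
def table2_cfg():
    return SimConfig.table2(seed=1)


def profiles_from_arrays(X, y, genes, prefix="c"):
    return [
        CompoundProfile(
            compound=f"{prefix}{j:02d}",
            class_label=lab,
            genes=genes,
            values=row,
        )
        for j, (row, lab) in enumerate(zip(X, y))
    ]


@pytest.fixture
def tiny_instance():
    X, y, genes = make_oracle_instance(n_genes=5, n_samples=6, seed=7)
    return X, y, genes
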