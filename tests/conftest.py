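import numpy as np
import pandas as pd
import pytest

from headful import GenomeLayout, InductionConfig
from headful.induction_sim import MoleculePool


@pytest.fixture
def p22() -> GenomeLayout:
    return GenomeLayout.p22_default()


@pytest.fixture
def small_layout() -> GenomeLayout:
    """Toy layout small enough for deep read sampling in unit tests."""
    return GenomeLayout(
        chromosome_length=200_000,
        prophage_start=50_000,
        prophage_length=20_000,
        attB_pos=50_000,
        pac_offset=10_000,
        packaging_direction=1,
        ori_offset=10_000,
    )


def make_pool(layout: GenomeLayout, n_integrated: int, n_attB: int = 0,
              n_episomal: float = 0.0, n_cells: int | None = None,
              flank_added: float = 0.0, timepoint: int = 0) -> MoleculePool:
    """Hand-built molecule census for estimator and packaging tests."""
    if n_cells is None:
        n_cells = max(n_integrated + n_attB, 1)
    counts = pd.DataFrame(
        {
            "n_integrated": [n_integrated],
            "n_attB": [n_attB],
            "n_circles": [0],
            "n_episomal_units": [float(n_episomal)],
            "flank_added": [float(flank_added)],
            "exc_pre_repl": [0],
            "exc_total": [n_attB],
            "reintegrations": [0],
        },
        index=pd.Index([timepoint], name="timepoint"),
    )
    return MoleculePool(counts=counts, layout=layout,
                        config=InductionConfig(n_cells=n_cells), n_cells=n_cells)


@pytest.fixture
def make_pool_fn():
    return make_pool
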