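import numpy as np
import pandas as pd
import pytest

from cropscreen.counting import UmiCountTable
from cropscreen.synthetic import (
    GuideLibrary,
    GuideRecord,
    ScreenDesign,
    make_library,
)


@pytest.fixture(scope="session")
def small_library() -> GuideLibrary:
    return make_library(5, 4, 4, 4, 2, seed=11)


@pytest.fixture(scope="session")
def tiny_library() -> GuideLibrary:
    return GuideLibrary(
        [
            GuideRecord("g1", "GENE1", "ACGTACGTACGTACGTACGA", "target"),
            GuideRecord("g2", "GENE1", "CCGTACGTACGTACGTACGA", "target"),
            GuideRecord("g3", "GENE2", "GCGTACGTACGTACGTACGA", "target"),
        ]
    )


@pytest.fixture()
def fast_design(small_library) -> ScreenDesign:
    return ScreenDesign(
        n_clones_founding=400,
        bottleneck_fraction=0.5,
        n_generations=4,
        depth=4000,
        error_rate=0.0,
        seed=3,
    )


def make_umi_table(entries, sample="s1") -> UmiCountTable:
    """entries: list of (guide_id, umi, count)."""
    return UmiCountTable(
        sample, pd.DataFrame(entries, columns=["guide_id", "umi", "count"])
    )


@pytest.fixture()
def umi_table_factory():
    return make_umi_table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
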