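import numpy as np
import pandas as pd
import pytest

import sedanet as sn


@pytest.fixture(scope="session")
def small_community():
    """Default-condition synthetic community shared by read-only tests."""
    return sn.generate_community(n_samples=25, n_families=60, seed=11)


@pytest.fixture()
def toy_cm():
    counts = pd.DataFrame(
        [[5, 0, 2, 1], [0, 3, 2, 0], [4, 1, 0, 7]],
        index=["s0", "s1", "s2"],
        columns=["famA", "famB", "famC", "famD"])
    return sn.CountMatrix(counts, pd.Series([1.0, 2.0, 3.0], index=counts.index))


@pytest.fixture()
def toy_annotation():
    tbl = pd.DataFrame({
        "habitat": ["pelagic", "pelagic", "benthic", "excluded"],
        "functional_group": ["centric diatoms", "fish", "bivalves", "parasites"],
        "trophic": ["phototrophic", "heterotrophic", "heterotrophic", "na"],
    }, index=pd.Index(["famA", "famB", "famC", "famD"], name="family"))
    return sn.TaxonAnnotation(tbl)
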