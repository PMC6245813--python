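import numpy as np
import pandas as pd
import pytest

import mirtisect as mt


@pytest.fixture(scope="session")
def table4_means() -> mt.GroupMeanMatrix:
    """Published liver-vs-brain-tissues TMM mean table shipped with the package."""
    from importlib import resources

    with resources.files("mirtisect.data").joinpath("liver_brain_tmm_means.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return mt.GroupMeanMatrix(df, group_kind="tissue")


@pytest.fixture(scope="session")
def toy_counts() -> mt.CountMatrix:
    """Seeded 20-gene x 4-sample toy matrix used for normalization oracles."""
    rng = np.random.default_rng(42)
    x = rng.negative_binomial(5, 5 / 55, size=(4, 20)).T.astype(float)
    return mt.CountMatrix(
        pd.DataFrame(x, index=[f"g{i}" for i in range(20)],
                     columns=["s1", "s2", "s3", "s4"])
    )


@pytest.fixture(scope="session")
def small_atlas():
    """Default-layout synthetic atlas with three planted tissue-specific miRNAs."""
    design = mt.AtlasDesign(
        n_mirnas=60,
        planted=mt.plant_ts_effects(3, 1000, ["liver", "heart", "pancreas"]),
        seed=1,
    )
    return mt.generate_atlas(design)
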