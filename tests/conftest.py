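import numpy as np
import pandas as pd
import pytest

from rootkin.types import GeneticMap, VelocityProfileParams


@pytest.fixture
def base_params() -> VelocityProfileParams:
    """Typical Arabidopsis-like profile: peak REGR 45 %/h at 0.4 mm."""
    return VelocityProfileParams(vf=0.2, x0=0.4, k=9.0, n=1.0)


@pytest.fixture
def small_map() -> GeneticMap:
    """Two short chromosomes, 3 + 2 markers."""
    return GeneticMap(
        chromosomes=["chr1", "chr2"],
        lengths={"chr1": 20.0, "chr2": 10.0},
        positions={"chr1": np.array([0.0, 10.0, 20.0]), "chr2": np.array([0.0, 10.0])},
        marker_names={"chr1": ["m1", "m2", "m3"], "chr2": ["m4", "m5"]},
    )


def random_valid_params(rng: np.random.Generator) -> VelocityProfileParams:
    """Draw profile parameters over the plausible biological ranges."""
    return VelocityProfileParams(
        vf=rng.uniform(0.05, 0.5),
        x0=rng.uniform(0.2, 0.8),
        k=rng.uniform(3.0, 30.0),
        n=rng.uniform(0.3, 3.0),
    )


@pytest.fixture
def genotype_frame() -> pd.DataFrame:
    """8 RILs x 5 markers, hand-written, with one missing call."""
    data = {
        "m1": ["AA", "AA", "BB", "BB", "AA", "BB", "AA", "BB"],
        "m2": ["AA", "AA", "BB", "BB", "AA", "BB", "BB", "BB"],
        "m3": ["AA", "BB", "BB", "AA", "AA", "BB", "BB", "AA"],
        "m4": ["BB", "AA", "AA", "BB", "BB", "AA", "AA", "BB"],
        "m5": ["BB", "AA", "AA", "BB", np.nan, "AA", "AA", "BB"],
    }
    return pd.DataFrame(
        data, index=pd.Index([f"RIL{i:03d}" for i in range(1, 9)], name="ril")
    )
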