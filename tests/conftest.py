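import numpy as np
import pytest

from sedadrivers.io_formats import (
    AbioticSeries,
    FeatureTable,
    SedimentCore,
)


@pytest.fixture
def small_core():
    """Three layers whose half-open spans are [1957,1960), [1960,1963), [1963,1966)."""
    return SedimentCore(
        layer_ids=("L1", "L2", "L3"),
        depth_top_cm=(1.0, 0.5, 0.0),
        depth_bottom_cm=(1.5, 1.0, 0.5),
        year_mid=(1958.5, 1961.5, 1964.5),
        phase=("E", "E", "E"),
    )


@pytest.fixture
def counts_2x2():
    return FeatureTable(["f1", "f2"], ["L1", "L2"], np.array([[1, 2], [3, 4]]))


@pytest.fixture
def yearly_series():
    def make(name, years, values, clazz="climate", biocide_type=None):
        return AbioticSeries(
            name=name,
            clazz=clazz,
            biocide_type=biocide_type,
            years=tuple(years),
            values=tuple(float(v) for v in values),
        )

    return make
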