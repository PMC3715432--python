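import numpy as np
import pytest

from fishloc.synthetic import (ChainModel, NucleusGeometry, PlacedNucleus,
                               RadialModel, place_probe_pair)


@pytest.fixture(scope="session")
def placed_nucleus():
    """One deterministic placed nucleus for rendering-based tests."""
    geom = NucleusGeometry(centre=(1.6, 2.6, 2.6), semi_axes=(1.2, 1.8, 1.5),
                           orientation=0.4)
    pair = place_probe_pair(geom, ChainModel(c=0.0015, g=65.0),
                            RadialModel("beta", 2.0, 2.0), seed=5)
    return PlacedNucleus("nuc1", "e1", "region", "ctrl", geom, pair)
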