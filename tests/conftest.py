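import numpy as np
import pandas as pd
import pytest

import perivar as pv


def long_table(wide: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Build a long community table from {slide: {taxon: abundance}}."""
    rows = [
        {"slide_id": s, "taxon_id": t, "abundance": float(a)}
        for s, taxa in wide.items()
        for t, a in taxa.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def design108():
    return pv.build_design(108, seed=11)


@pytest.fixture(scope="session")
def diatom_dataset(design108):
    """Study-shaped diatom simulation: 8 taxa x 108 slides."""
    params = pv.diatom_params()
    targets = pv.simulate_taxon_targets(params, seed=21)
    community = pv.simulate_diatom_counts(design108, targets, params, seed=22)
    return {"params": params, "targets": targets, "community": community, "design": design108}


@pytest.fixture(scope="session")
def bacteria_dataset(design108):
    """ARISA-shaped closed profiles: 150 OTUs x 108 slides."""
    params = pv.bacteria_params()
    community = pv.simulate_bacterial_profiles(design108, params, seed=31)
    return {"params": params, "community": community, "design": design108}
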