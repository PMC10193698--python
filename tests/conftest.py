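import numpy as np
import pandas as pd
import pytest

from cpfetoscan.synthetic import ImagingConfig


@pytest.fixture
def noise_free_imaging():
    """Small, noise-free imaging config for exact-construction tests."""
    return ImagingConfig(
        tile_pixels=256,
        shot_noise="off",
        read_noise_sd=0.0,
        granule_density_per_kpx=0.0,
        n_collagen_fibres=0,
    )


@pytest.fixture
def litter_table():
    """Hand-built litter-level table: 3 control + 3 exposed dams, 2 organs."""
    rows = []
    loads = {
        ("C", "placenta"): [100.0, 110.0, 90.0],
        ("DE", "placenta"): [400.0, 420.0, 410.0],
        ("C", "gonad"): [50.0, 55.0, 45.0],
        ("DE", "gonad"): [60.0, 62.0, 58.0],
    }
    for (group, organ), vals in loads.items():
        for i, v in enumerate(vals):
            rows.append(dict(dam_id=f"{group}{i + 1}", group=group, organ=organ, cp_load=v))
    return pd.DataFrame(rows)


def planted_tile(imaging, centroids, tissue_fraction=1.0, seed=0):
    """Render a tile with known planted particles."""
    from cpfetoscan.synthetic import render_tile

    rng = np.random.default_rng(seed)
    return render_tile(np.asarray(centroids, float), imaging, tissue_fraction, rng)
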