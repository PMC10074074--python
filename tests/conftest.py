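import numpy as np
import pandas as pd
import pytest

from seepcore.core import Core, SedimentLayer
from seepcore.synthetic import dating_scenario, simulate_core


def make_core(
    totals,
    thickness=2.0,
    density=1.0,
    cs137=None,
    supported=None,
    site_id="T1",
):
    """Hand-built core from a list of total ²¹⁰Pb activities."""
    layers = []
    for i, tot in enumerate(totals):
        layers.append(
            SedimentLayer(
                layer_index=i,
                top_depth=i * thickness,
                bottom_depth=(i + 1) * thickness,
                dry_bulk_density=density,
                pb210_total=float(tot),
                pb210_supported=supported,
                cs137=None if cs137 is None else float(cs137[i]),
            )
        )
    return Core(site_id=site_id, layers=layers)


@pytest.fixture(scope="session")
def noisefree_dating():
    """Noise-free 40 × 1 cm constant-MAR core with truth."""
    params = dating_scenario()
    core, inventory, truth = simulate_core(params)
    return params, core, inventory, truth


@pytest.fixture()
def tiny_inventory():
    return pd.DataFrame(
        dict(
            site_id=["S"] * 4,
            layer_index=[0, 0, 1, 1],
            polymer=["PE", "PP", "PE", "PVC"],
            number_items_kg=[100.0, 50.0, 80.0, 20.0],
            mass_mg_kg=[50.0, 25.0, 40.0, 10.0],
        )
    )
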