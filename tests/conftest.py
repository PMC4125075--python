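import numpy as np
import pytest

from phenosig.growth_io import GrowthCurve
from phenosig.synth_data import StrainPanelSpec, make_strain_panel


@pytest.fixture(scope="session")
def default_panel():
    """The default 4-strain x 3-replicate control panel (seed 0)."""
    return make_strain_panel(StrainPanelSpec(seed=0))


@pytest.fixture()
def simple_curve():
    t = np.arange(0, 4, 1 / 6)
    od = 0.05 * np.exp(0.5 * t)
    return GrowthCurve(times=t, od=od, strain="mg", condition="ctrl", well="A1")


@pytest.fixture()
def plate_files(tmp_path):
    """A tiny 3-column plate CSV plus layout JSON on disk."""
    import json

    csv = tmp_path / "plate.csv"
    csv.write_text(
        "time,A1,A2\n" + "\n".join(
            f"{i/6!r},{0.05*np.exp(0.3*i/6):.6f},{0.05*np.exp(0.4*i/6):.6f}"
            for i in range(30)
        )
    )
    layout = tmp_path / "layout.json"
    layout.write_text(json.dumps({"A1": ["mg", "ctrl"], "A2": ["bpro", "ctrl"]}))
    return csv, layout
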