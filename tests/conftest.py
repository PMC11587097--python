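import pytest

from uvdose import FourPLParams, MediumOptics
from uvdose.io import load_fitted_d_half, load_plate_registry


@pytest.fixture(scope="session")
def registry():
    """Bundled four-vessel registry (96-, 24-, 12-well, 3.5 cm dish)."""
    return load_plate_registry()


@pytest.fixture(scope="session")
def medium():
    """Keratinocyte growth medium at 302 nm (measured absorptivity)."""
    return MediumOptics(absorptivity=0.1695)


@pytest.fixture(scope="session")
def il6_fits() -> dict[str, FourPLParams]:
    """Bundled worked-example 4PL fits of IL-6 release per vessel."""
    return load_fitted_d_half()


@pytest.fixture(scope="session")
def published_panel():
    """(S, r, D_1/2) calibration panel: published per-vessel values,
    ordered 3.5 cm dish, 12-well, 24-well, 96-well."""
    return {
        "S": (8.87, 3.63, 1.90, 0.31),
        "r": (0.351, 0.791, 1.155, 1.770),
        "D_half": (18.5, 23.7, 51.4, 166.2),
    }
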