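from __future__ import annotations

import pytest

from ascoflux.core_model import (
    CELLOPENTAOSE,
    GLUCOSE,
    InterventionConfig,
    build_core_model,
    build_reduced_energy_model,
)
from ascoflux.products import build_default_registry
from ascoflux.toys import make_toy_networks


@pytest.fixture(scope="session")
def toys():
    return make_toy_networks()


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def products_by_name(registry):
    return {p.name: p for p in registry.products}


@pytest.fixture(scope="session")
def products_by_group(registry):
    out: dict[str, list] = {}
    for p in registry.products:
        out.setdefault(p.functional_group, []).append(p)
    return out


@pytest.fixture(scope="session")
def wt_model():
    return build_core_model()


@pytest.fixture(scope="session")
def cp_model():
    return build_core_model(interventions=InterventionConfig(True, False))


@pytest.fixture(scope="session")
def pdhcyt_model():
    return build_core_model(interventions=InterventionConfig(False, True))


@pytest.fixture(scope="session")
def both_model():
    return build_core_model(interventions=InterventionConfig(True, True))


@pytest.fixture(scope="session")
def glucose_model():
    return build_core_model(substrate=GLUCOSE)


@pytest.fixture(scope="session")
def reduced_energy_model():
    return build_reduced_energy_model()
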