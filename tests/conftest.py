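import numpy as np
import pytest

from pkacycles import AcidBasePair, SpeciesEnergy, ThermoContext


@pytest.fixture
def ctx():
    return ThermoContext()


@pytest.fixture
def pair_factory():
    """Factory for random acid/base pairs with controllable tags/charges."""

    def make(
        rng: np.random.Generator,
        acid_charge: int = 1,
        method_tag: str = "m",
        solvent_tag: str = "water",
        ident: str = "x",
        scale: float = 50.0,
    ) -> AcidBasePair:
        g = rng.uniform(-scale, scale, size=4)
        acid = SpeciesEnergy(
            f"{ident}_acid", acid_charge, g[0], g[1], method_tag, solvent_tag
        )
        base = SpeciesEnergy(
            f"{ident}_base", acid_charge - 1, g[2], g[3], method_tag, solvent_tag
        )
        return AcidBasePair(acid=acid, base=base)

    return make
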