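import numpy as np
import pytest

from kcrtools import ChannelDesign, MotifSpec, ProteinRecord
from kcrtools import generate_proteome, plant_sites_and_motifs


@pytest.fixture(scope="session")
def design() -> ChannelDesign:
    return ChannelDesign.default()


@pytest.fixture(scope="session")
def small_proteome() -> list[ProteinRecord]:
    return generate_proteome(30, (100, 300), seed=101)


@pytest.fixture(scope="session")
def proteome_with_sites():
    """A proteome with Kcr sites and a planted FKcrE-style motif."""
    proteome = generate_proteome(60, (150, 400), seed=202)
    proteome, sites, truth = plant_sites_and_motifs(
        proteome, 0.12, [MotifSpec(((-1, "F"), (1, "E")), 0.3)], seed=203
    )
    return proteome, sites, truth


def binom_99_interval(n: int, p: float) -> tuple[float, float]:
    """Central 99% normal interval for a binomial proportion."""
    se = np.sqrt(p * (1 - p) / n)
    return p - 2.576 * se, p + 2.576 * se
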