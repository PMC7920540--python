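import numpy as np
import pytest

from vmtc import build_cell
from vmtc.membrane import default_distribution_table, DistributionTable
from vmtc.morphology import Morphology, Section
from vmtc.simulator import assemble


@pytest.fixture(scope="session")
def cell():
    """The calibrated default model cell (shared across tests)."""
    return build_cell()


def zero_distribution() -> DistributionTable:
    return DistributionTable(
        {
            ch: {r: 0.0 for r in row}
            for ch, row in default_distribution_table().density.items()
        }
    )


def soma_only_morphology() -> Morphology:
    side = np.sqrt(293.0 / np.pi)
    return Morphology(
        sections=(
            Section(
                id=0,
                region="soma",
                parent_id=None,
                length=side,
                diameter=side,
                branch_order=0,
                path_distance_to_soma=0.0,
            ),
        )
    )


@pytest.fixture(scope="session")
def passive_soma():
    """A single passive compartment (fixed soma area, no channels)."""
    return assemble(soma_only_morphology(), dist=zero_distribution())
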