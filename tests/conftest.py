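import numpy as np
import pytest

from pbmotif import (
    IntensityTable,
    PromoterRecord,
    SimulationConfig,
    simulate,
)


@pytest.fixture(scope="session")
def sim_small():
    """One deterministic small simulated experiment shared across tests."""
    return simulate(SimulationConfig(n_genes=400, seed=11))


@pytest.fixture(scope="session")
def sim_default():
    """One run at the default study conditions (2,000 genes)."""
    return simulate(SimulationConfig(seed=101))


@pytest.fixture()
def toy_promoters():
    return [
        PromoterRecord("geneA", "AAATTGATTGTT"),
        PromoterRecord("geneB", "ACGT" * 10),
    ]


def make_table(seqs: dict[str, str], intens: dict[str, float], background=None):
    """Build an IntensityTable carrying core sequences, in insertion order."""
    ids = list(intens)
    return IntensityTable(
        probe_ids=np.array(ids, dtype=object),
        intensities=np.array([intens[i] for i in ids], dtype=float),
        background=background,
        core_seqs=seqs,
    )
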