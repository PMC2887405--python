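import numpy as np
import pytest

from srnapop.panel import AlignedLocus, PanelEntry, PopulationPanel, extract_core_alignment

BASES = np.array(list("ACGT"))


def random_locus(rng, n=None, L=None, locus_id="rand", gap_frac=0.0):
    """A random alignment; optionally sprinkle gaps/Ns."""
    n = n or int(rng.integers(2, 11))
    L = L or int(rng.integers(1, 51))
    mat = rng.choice(BASES, size=(n, L))
    if gap_frac:
        mask = rng.random((n, L)) < gap_frac
        mat[mask] = rng.choice(np.array(list("-N")), size=int(mask.sum()))
    return AlignedLocus(locus_id, tuple(
        (f"s{i}", "".join(row)) for i, row in enumerate(mat)
    ))


def core_of(locus, subset=None):
    return extract_core_alignment(locus, subset)


@pytest.fixture
def small_panel():
    return PopulationPanel({
        "I1": PanelEntry("cultivated", "indica"),
        "I2": PanelEntry("cultivated", "indica"),
        "J1": PanelEntry("cultivated", "japonica"),
        "J2": PanelEntry("cultivated", "japonica"),
        "W1": PanelEntry("wild", "none"),
        "W2": PanelEntry("wild", "none"),
        "O1": PanelEntry("outgroup", "none"),
    })
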