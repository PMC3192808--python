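import pytest
from hypothesis import settings

from multibind import load_packaged_model

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

MOTIFS = ["P1", "P2", "P3", "P4", "RP"]

#: The five reference-scaffold motif peptides (N-domain panel) and their
#: orientation classes.
TABLE_SEQUENCES = {
    "P1": ("PPPVPPRRR", "II"),
    "P2": ("PPAIPPRQP", "II"),
    "P3": ("PPLLPPREP", "II"),
    "P4": ("GPPVPPRQS", "II"),
    "RP": ("TRRHLPSPP", "I"),
}


@pytest.fixture(scope="session")
def model():
    """Packaged affinity model with effective Kds matching the published table."""
    return load_packaged_model(use_measured_kd_eff=True)


@pytest.fixture(scope="session")
def model_from_ceff():
    """Packaged affinity model deriving effective Kds from the printed C_eff."""
    return load_packaged_model(use_measured_kd_eff=False)
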