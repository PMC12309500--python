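import pytest

from chromdyn import EffectSpec, make_design, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One mid-sized synthetic study shared by read-only tests."""
    return simulate_dataset(5, n_genes=150, n_peaks=900, n_motifs=12)


@pytest.fixture(scope="session")
def null_spec():
    """Effect specification with nothing planted."""
    return EffectSpec(
        frac_loss_0h_untrained=0.0,
        frac_gain_6h_untrained=0.0,
        amplification_trained=1.0,
        reversal_frac=0.0,
    )


@pytest.fixture()
def design():
    return make_design(3)
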