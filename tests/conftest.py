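import pytest

from netcover import synthetic_data as sd


@pytest.fixture(scope="session")
def aml_fixture():
    return sd.load_aml_fixture()


@pytest.fixture
def small_config():
    """Desk-scale synthetic config matching the documented test conditions."""
    def _make(seed: int = 11, **overrides) -> sd.SyntheticConfig:
        base = dict(
            n_genes=1000,
            n_samples_tumor=20,
            n_samples_normal=20,
            frac_up=0.05,
            frac_down=0.05,
            planted_lfc=2.0,
            nb_dispersion=0.2,
            ppi_n_nodes=500,
            ppi_attach_m=2,
            n_drugs=50,
            seed=seed,
        )
        base.update(overrides)
        return sd.SyntheticConfig(**base)

    return _make
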