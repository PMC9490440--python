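import numpy as np
import pytest

from bioapatite import default_config, empa, pipeline, synthetic


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def small_design():
    """A reduced study: one fresh and one 91-day group per state."""
    groups = tuple(
        (state, pmi, 3) for state in ("unburnt", "burnt") for pmi in (0, 91)
    )
    return synthetic.StudyDesign(groups=groups, points_per_zone=4, seed=11)


@pytest.fixture(scope="session")
def ref_study(cfg):
    """One seeded publication-shaped study reused across expensive tests."""
    return pipeline.simulate_stage(cfg, seed=20240901)


@pytest.fixture(scope="session")
def ref_ftir(cfg, ref_study):
    return pipeline.ftir_stage(ref_study.spectra, cfg)


@pytest.fixture(scope="session")
def ref_cleaned(cfg, ref_study):
    cleaned, _ = pipeline.empa_stage(empa.EmpaTable(points=ref_study.empa), cfg)
    return cleaned


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
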