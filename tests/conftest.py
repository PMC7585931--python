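import numpy as np
import pytest

import oispec as o


@pytest.fixture(scope="session")
def ext_table():
    return o.load_extinction_table()


@pytest.fixture(scope="session")
def oxygen_baseline():
    return o.BaselineState(100.0, 0.70, "oxygen")


@pytest.fixture(scope="session")
def paths_fast(ext_table, oxygen_baseline):
    """Shared path-length table at moderate photon count."""
    return o.pathlength_table(oxygen_baseline, o.IMAGING_WAVELENGTHS_NM,
                              ext_table, n_photons=5000, seed=7)


@pytest.fixture(scope="session")
def phantom48():
    return o.make_phantom(shape=(48, 48), seed=2)


@pytest.fixture(scope="session")
def reduced_proto():
    return o.reduced_protocol()


@pytest.fixture(scope="session")
def chronic_recording(phantom48, reduced_proto, ext_table, paths_fast):
    cond = o.ConditionSpec.default("WT-like", "chronic")
    return o.simulate_session(phantom48, reduced_proto, cond, ext_table,
                              paths_fast, seed=3)


@pytest.fixture(scope="session")
def analysis_config(ext_table, paths_fast):
    return o.AnalysisConfig(table=ext_table, paths=paths_fast)


@pytest.fixture(scope="session")
def chronic_result(chronic_recording, analysis_config):
    return o.run_session(chronic_recording, analysis_config)


@pytest.fixture(scope="session")
def noisefree_phantom():
    from oispec.phantom import NoiseModel

    return o.make_phantom(shape=(48, 48), seed=2,
                          noise=NoiseModel(enabled=False, dark_offset=0.0))


@pytest.fixture(scope="session")
def noisefree_recording(noisefree_phantom, reduced_proto, ext_table,
                        paths_fast):
    cond = o.ConditionSpec.default("WT-like", "chronic")
    return o.simulate_session(noisefree_phantom, reduced_proto, cond,
                              ext_table, paths_fast, seed=5,
                              experiments=("exp1", "exp3", "exp7"))


def roi_mean(movie, mask):
    return np.nanmean(movie[:, mask], axis=1)
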