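import pytest

from retmod.calibrate import DesignSpec, assemble_cube
from retmod.synthetic import NoiseModel, sample_truth, simulate_corner_table
from retmod.system import ColumnSpec, InstrumentSpec


@pytest.fixture(scope="session")
def column():
    return ColumnSpec()  # 250 x 4.6 mm, 10 µm, porosity 0.68


@pytest.fixture(scope="session")
def instrument():
    return InstrumentSpec(dwell_volume_ml=1.0)


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def truth9(design, column, instrument):
    return sample_truth(9, seed=1, design=design, column=column, instrument=instrument)


@pytest.fixture(scope="session")
def noiseless_table(truth9, design, column, instrument):
    return simulate_corner_table(
        truth9, design, NoiseModel(rt_sd_min=0.0, area_cv=0.0, seed=0), column, instrument
    )


@pytest.fixture(scope="session")
def models9(noiseless_table, column, instrument, design):
    return assemble_cube(noiseless_table, column, instrument, design)
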