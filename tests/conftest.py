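import numpy as np
import pytest

from hcymr import fixture
from hcymr.data_model import HarmonizedInstrument, InstrumentSet, VariantAssociation


@pytest.fixture(scope="session")
def instrument_table():
    return fixture.load_instrument_table()


@pytest.fixture(scope="session")
def finngen_set():
    return fixture.study_instrument_set("finngen")


@pytest.fixture(scope="session")
def day_set():
    return fixture.study_instrument_set("day")


@pytest.fixture(scope="session")
def tyrmi_set():
    return fixture.study_instrument_set("tyrmi")


@pytest.fixture(scope="session")
def study_sets(finngen_set, day_set, tyrmi_set):
    return {"finngen": finngen_set, "day": day_set, "tyrmi": tyrmi_set}


def make_set(bx, by, sy, sx=None, label="test", **sizes) -> InstrumentSet:
    """Build an InstrumentSet from plain arrays (ids v001, v002, ...)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    instruments = tuple(
        HarmonizedInstrument(f"v{j + 1:03d}", bx[j], sx[j], by[j], sy[j])
        for j in range(len(bx)))
    return InstrumentSet(label=label, instruments=instruments, **sizes)


@pytest.fixture(scope="session")
def selection_scenario():
    """18 genome-wide-significant candidates: the 14 retained homocysteine
    instruments plus three LD-redundant variants and one with a BMI
    pleiotropy annotation.  Summary statistics for the four dropped
    variants are synthetic (their published tables are not packaged); only
    the drop logic matters."""
    candidates = list(fixture.exposure_associations())
    extras = [
        VariantAssociation("rs12134663", "A", 0.14, 0.008, p_value=1e-60,
                           chromosome="1"),
        VariantAssociation("rs957140", "G", 0.040, 0.007, p_value=2e-8,
                           chromosome="6"),
        VariantAssociation("rs12921383", "T", 0.085, 0.008, p_value=1e-30,
                           chromosome="16"),
        VariantAssociation("rs548987", "C", 0.044, 0.007, p_value=3e-9,
                           chromosome="16"),
    ]
    ld = [
        ("rs12134663", "rs1801133", 0.62),
        ("rs957140", "rs9369898", 0.31),
        ("rs12921383", "rs154657", 0.47),
        ("rs42648", "rs838133", 0.01),  # below threshold, must not prune
    ]
    flags = {"rs548987": "body mass index"}
    return candidates + extras, ld, flags
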