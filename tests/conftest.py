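import pytest

from siderokit.fragments import PeakList
from siderokit.marfey import MarfeyRecord
from siderokit.presets import (
    MARFEY_HYDROLYSATE_C3,
    MARFEY_HYDROLYSATE_COUNTS,
    MARFEY_STANDARDS_C3,
    potashchelin,
)

# Published assay values for the potashchelin worked example.
POTASHCHELIN_CALCD_MH = {
    "A": ("C43H73N10O23", 1097.4850),
    "B": ("C43H71N10O22", 1079.4744),
    "C": ("C43H73N10O22", 1081.4901),
    "D": ("C45H75N10O22", 1107.5057),
}
POTASHCHELIN_A_Y_SERIES = (218, 319, 450, 537, 624, 681, 768)
POTASHCHELIN_A_B_SERIES = (330, 417, 474, 561, 648, 779, 880, 967)


@pytest.fixture
def pota():
    return {w: potashchelin(w) for w in "ABCD"}


@pytest.fixture
def observed_y_peaks():
    return PeakList.from_mz(POTASHCHELIN_A_Y_SERIES, tolerance=0.5)


@pytest.fixture
def marfey_standards():
    return [
        MarfeyRecord(rt=rt, reagent=rg, analyte=a, configuration=c, source="standard")
        for a, c, rg, rt in MARFEY_STANDARDS_C3
    ]


@pytest.fixture
def marfey_hydrolysate():
    return [
        MarfeyRecord(rt=rt, reagent="L-FDAA",
                     count=MARFEY_HYDROLYSATE_COUNTS.get(rt, 1))
        for rt in MARFEY_HYDROLYSATE_C3
    ]
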