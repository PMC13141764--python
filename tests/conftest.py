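import numpy as np
import pytest

from glioshape import MaskSlice
from glioshape.simulate import CohortSpec, make_cohort, make_reference_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    """Deterministic cohort reproducing every published marginal 2x2 table."""
    return make_reference_cohort()


@pytest.fixture(scope="session")
def riskl_cohort():
    """Complete-case cohort generated from the Risk_L coefficients."""
    return make_cohort(CohortSpec(n=1000, include_missing=False, seed=42))


@pytest.fixture()
def disk_mask():
    rr, cc = np.mgrid[0:128, 0:128]
    return MaskSlice((rr - 64) ** 2 + (cc - 64) ** 2 <= 40 ** 2,
                     medial_hint=(1.0, 0.0))


@pytest.fixture()
def rect_mask():
    pix = np.zeros((100, 100), dtype=bool)
    pix[20:80, 20:60] = True
    return MaskSlice(pix, medial_hint=(1.0, 0.0))
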