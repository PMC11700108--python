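import numpy as np
import pandas as pd
import pytest

from fruitmass.synthetic import (
    DEFAULT_COHORTS,
    CohortSpec,
    FruitGroundTruth,
    ImagingSpec,
    generate_tabular_cohort,
    render_fruit_image,
)


def make_records(L, D, FW=None) -> pd.DataFrame:
    data = {"length_mm": np.asarray(L, float), "diameter_mm": np.asarray(D, float)}
    if FW is not None:
        data["weight_g"] = np.asarray(FW, float)
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def cohort_2019() -> pd.DataFrame:
    """Development-cohort emulation (n=1028, LD generating law, 0.5 g noise)."""
    return generate_tabular_cohort(DEFAULT_COHORTS["plum-2019"], seed=1)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A quick 60-record noisy LD-law cohort for model unit tests."""
    spec = CohortSpec(
        name="small",
        n=60,
        L_mean=25.0, L_sd=2.0, L_min=18.0, L_max=32.0,
        D_mean=24.0, D_sd=2.0, D_min=17.0, D_max=31.0,
        rho_LD=0.8, gen_form="LD", gen_a=-4.494, gen_b=0.0225, noise_sd=0.3,
    )
    return generate_tabular_cohort(spec, seed=11)


@pytest.fixture(scope="session")
def imaging() -> ImagingSpec:
    return ImagingSpec()


@pytest.fixture(scope="session")
def rendered_green(imaging):
    truth = FruitGroundTruth(L_mm=25.0, D_mm=20.0, orientation_deg=0.0, hue_class="green")
    return render_fruit_image(truth, imaging, seed=7)
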