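import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from petctdose.synthetic import (
    ActivityProtocol,
    CohortSpec,
    DlpModel,
    HeightModel,
    StratumSpec,
    default_mct_spec,
    default_quadra_spec,
    generate_cohort,
)

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


def small_spec(name: str = "mini", seed: int = 7, height_missing_rate: float = 0.2) -> CohortSpec:
    """A ~50-patient cohort spec for fast structural tests."""
    return CohortSpec(
        cohort_name=name,
        strata=(
            StratumSpec("<50", 4, 46.0, 3.0),
            StratumSpec("50–59", 8, 56.0, 3.0),
            StratumSpec("60–69", 10, 65.0, 3.0),
            StratumSpec("70–79", 12, 74.0, 3.0),
            StratumSpec("80–89", 8, 84.0, 3.0),
            StratumSpec("90–99", 5, 93.0, 3.0),
            StratumSpec(">100", 5, 108.0, 6.0),
        ),
        activity_protocol=ActivityProtocol(
            name="weight_tiered",
            standard_mbq=250.0,
            heavy_mbq=300.0,
            heavy_threshold_kg=90.0,
            jitter_median=1.17,
            jitter_sigma=0.2,
        ),
        dlp_model=DlpModel(intercept=4.798, slope=0.01649, noise_sd=0.18),
        height_model=HeightModel(mean_bmi=26.0, bmi_sd=4.0),
        height_missing_rate=height_missing_rate,
        gender_ratio_male=0.55,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mct_table() -> pd.DataFrame:
    return generate_cohort(default_mct_spec())


@pytest.fixture(scope="session")
def quadra_table() -> pd.DataFrame:
    return generate_cohort(default_quadra_spec())


@pytest.fixture()
def small_cohort_files(tmp_path):
    """Two small cohort CSVs on disk, returned as (path_a, path_b)."""
    a = generate_cohort(small_spec("alpha", seed=11))
    b = generate_cohort(small_spec("beta", seed=22))
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    a.to_csv(pa, index=False)
    b.to_csv(pb, index=False)
    return pa, pb
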