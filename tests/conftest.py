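import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_db_csv(tmp_path):
    """A 3-row well-formed concentration table."""
    path = tmp_path / "db.csv"
    path.write_text(
        "food_category,substance,site,detection_time,concentration_ug_per_kg,"
        "national_limit_ug_per_kg,source\n"
        "olive oil,BaP,Sichuan,2018,12.5,10.0,demo\n"
        "rice,BaP,Hunan,2019,0.4,5.0,demo\n"
        "fried meat products,BaP,Chongqing,2020,7.0,5.0,demo\n"
    )
    return path


@pytest.fixture
def toy_cohort_files(tmp_path):
    """Two participants with fully linked diary rows."""
    cohort = tmp_path / "cohort.csv"
    cohort.write_text(
        "id,sex,body_weight_kg,height_cm,age_years,education,region,dining_places\n"
        "P1,male,70.0,175.0,21,bachelor,core,canteen\n"
        "P2,female,55.0,160.0,20,postgraduate,peripheral,canteen;restaurant\n"
    )
    diary = tmp_path / "diary.csv"
    rows = ["participant_id,day_index,food_category,mass_consumed_kg"]
    for day in range(1, 8):
        rows.append(f"P1,{day},rice,0.1")
        rows.append(f"P2,{day},fried meat products,0.05")
    diary.write_text("\n".join(rows) + "\n")
    return cohort, diary
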