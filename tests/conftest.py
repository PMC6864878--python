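import pytest

from tricase.case_model import CaseBase, CaseRecord
from tricase.synthetic_cases import GenerationConfig, generate_case_base


@pytest.fixture
def new_case_1() -> CaseRecord:
    """First printed test query of the study (rice planthopper on rice)."""
    return CaseRecord.from_dict(
        {
            "case_id": 1,
            "pest_type": "RP",
            "crop_name": "Rice",
            "pest_quantity": 335,
            "pest_stage": "Pupae",
            "infected_area": 77,
            "growth_stage": "Repro",
            "planting_density": 473,
            "temperature": [21, 30],
            "humidity": "57.49%",
            "rainfall": "72.15%",
            "sunlight": 4830,
            "wind_speed": 2,
        }
    )


@pytest.fixture
def small_base(new_case_1) -> CaseBase:
    """Four hand-built cases: two RP/rice, one CS/rice, one RP/wheat."""
    c1 = CaseRecord.from_dict(
        {**new_case_1.to_dict(), "case_id": 1, "solution": "Apply Buprofezin at 250 mL/ha"}
    )
    c2 = CaseRecord(
        case_id=2, pest_type="RP", crop_name="Rice", pest_quantity=400,
        pest_stage="Adult", infected_area=120, growth_stage="Vege",
        planting_density=300, temperature=(16.0, 28.0), humidity=0.40,
        rainfall=0.20, sunlight=2000, wind_speed=5,
        solution="Apply Imidacloprid at 150 mL/ha",
    )
    c3 = CaseRecord(
        case_id=3, pest_type="CS", crop_name="Rice", pest_quantity=350,
        pest_stage="Egg", infected_area=90, growth_stage="Ripen",
        planting_density=250, temperature=(18.0, 26.0), humidity=0.55,
        rainfall=0.60, sunlight=3500, wind_speed=3,
        solution="Apply VIRTAKO at 200 mL/ha",
    )
    c4 = CaseRecord(
        case_id=4, pest_type="RP", crop_name="Wheat", pest_quantity=330,
        pest_stage="Larvae", infected_area=60, growth_stage="Vege",
        planting_density=200, temperature=(15.0, 25.0), humidity=0.30,
        rainfall=0.15, sunlight=1500, wind_speed=2,
        solution="Apply Pymetrozine at 100 mL/ha",
    )
    return CaseBase(cases=[c1, c2, c3, c4])


@pytest.fixture(scope="session")
def synthetic_base() -> CaseBase:
    return generate_case_base(GenerationConfig(n_past=100, n_new=0, seed=11))
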