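"""Parameter tables: base-case values, lookups, validation, serialization."""

import numpy as np
import pytest
from pydantic import ValidationError

from flscea import (
    AgeBandTable,
    AgeRangeError,
    default_parameters,
    load_parameters,
    lookup,
    save_parameters,
)
from flscea.scenarios import perturbed_parameters

# every published table cell: (table accessor, age, gender, expected value)
_TABLE_CELLS = [
    ("osteoporosis_prevalence", 65, "F", 37.1),
    ("osteoporosis_prevalence", 75, "F", 51.3),
    ("osteoporosis_prevalence", 80, "F", 67.5),
    ("osteoporosis_prevalence", 65, "M", 5.4),
    ("osteoporosis_prevalence", 75, "M", 12.3),
    ("osteoporosis_prevalence", 90, "M", 21.9),
    ("risk.incidence.hip", 67, "F", 0.96),
    ("risk.incidence.hip", 72, "F", 2.34),
    ("risk.incidence.hip", 77, "F", 4.08),
    ("risk.incidence.hip", 82, "F", 6.44),
    ("risk.incidence.hip", 87, "F", 6.59),
    ("risk.incidence.hip", 95, "F", 8.67),
    ("risk.incidence.hip", 67, "M", 0.65),
    ("risk.incidence.hip", 72, "M", 1.26),
    ("risk.incidence.hip", 77, "M", 2.37),
    ("risk.incidence.hip", 82, "M", 5.19),
    ("risk.incidence.hip", 87, "M", 5.71),
    ("risk.incidence.hip", 95, "M", 8.35),
    ("risk.incidence.vertebral", 67, "F", 5.64),
    ("risk.incidence.vertebral", 72, "F", 8.74),
    ("risk.incidence.vertebral", 77, "F", 12.05),
    ("risk.incidence.vertebral", 82, "F", 21.19),
    ("risk.incidence.vertebral", 90, "F", 26.89),
    ("risk.incidence.vertebral", 67, "M", 0.95),
    ("risk.incidence.vertebral", 72, "M", 2.26),
    ("risk.incidence.vertebral", 77, "M", 4.50),
    ("risk.incidence.vertebral", 82, "M", 5.94),
    ("risk.incidence.vertebral", 90, "M", 9.54),
    ("risk.incidence.wrist", 67, "F", 12.95),
    ("risk.incidence.wrist", 72, "F", 13.17),
    ("risk.incidence.wrist", 77, "F", 13.87),
    ("risk.incidence.wrist", 82, "F", 15.01),
    ("risk.incidence.wrist", 87, "F", 15.10),
    ("risk.incidence.wrist", 95, "F", 13.97),
    ("risk.incidence.wrist", 67, "M", 3.27),
    ("risk.incidence.wrist", 72, "M", 2.79),
    ("risk.incidence.wrist", 77, "M", 3.13),
    ("risk.incidence.wrist", 82, "M", 4.75),
    ("risk.incidence.wrist", 87, "M", 4.78),
    ("risk.incidence.wrist", 95, "M", 3.23),
    ("risk.rr_osteoporosis.hip", 67, "F", 3.91),
    ("risk.rr_osteoporosis.hip", 72, "F", 3.31),
    ("risk.rr_osteoporosis.hip", 77, "F", 2.6),
    ("risk.rr_osteoporosis.hip", 82, "F", 2.04),
    ("risk.rr_osteoporosis.hip", 90, "F", 1.92),
    ("risk.rr_osteoporosis.vertebral", 67, "M", 2.59),
    ("risk.rr_osteoporosis.vertebral", 75, "M", 2.15),
    ("risk.rr_osteoporosis.vertebral", 85, "M", 1.82),
    ("risk.rr_osteoporosis.wrist", 67, "F", 1.78),
    ("risk.rr_osteoporosis.wrist", 75, "F", 1.60),
    ("risk.rr_osteoporosis.wrist", 85, "F", 1.45),
    ("mortality.life_table", 67, "F", 13.06),
    ("mortality.life_table", 72, "F", 24.36),
    ("mortality.life_table", 77, "F", 40.89),
    ("mortality.life_table", 82, "F", 73.98),
    ("mortality.life_table", 87, "F", 115.29),
    ("mortality.life_table", 92, "F", 180.24),
    ("mortality.life_table", 97, "F", 219.46),
    ("mortality.life_table", 101, "F", 436.34),
    ("mortality.life_table", 67, "M", 21.26),
    ("mortality.life_table", 72, "M", 37.02),
    ("mortality.life_table", 77, "M", 59.13),
    ("mortality.life_table", 82, "M", 98.56),
    ("mortality.life_table", 87, "M", 146.53),
    ("mortality.life_table", 92, "M", 211.66),
    ("mortality.life_table", 97, "M", 212.07),
    ("mortality.life_table", 101, "M", 507.28),
]

# scalar base-case values
_SCALARS = [
    ("demographics.proportion_female", 0.577),
    ("demographics.start_age", 65.0),
    ("risk.rr_subsequent_female", 1.95),
    ("risk.rr_subsequent_male", 3.47),
    ("mortality.excess_rr_female", 1.91),
    ("mortality.excess_rr_male", 2.99),
    ("mortality.excess_attribution", 0.25),
    ("costs.fracture_first_year.hip", 11166.0),
    ("costs.fracture_first_year.vertebral", 6328.0),
    ("costs.fracture_first_year.wrist", 2162.0),
    ("costs.hip_longterm_annual", 4799.0),
    ("costs.nursing_home_probability", 0.05),
    ("costs.drug_per_cycle", 392.31),
    ("costs.dxa_cost", 87.57),
    ("costs.gp_visit_cost", 10.3),
    ("costs.side_effect_gp_visits_first_cycle", 0.041),
    ("costs.side_effect_gp_visits_later_cycle", 0.021),
    ("costs.fls_fee", 200.0),
    ("utilities.baseline", 0.70),
    ("utilities.multipliers.hip.first_year", 0.55),
    ("utilities.multipliers.hip.subsequent_years", 0.86),
    ("utilities.multipliers.vertebral.first_year", 0.68),
    ("utilities.multipliers.vertebral.subsequent_years", 0.85),
    ("utilities.multipliers.wrist.first_year", 0.83),
    ("utilities.multipliers.wrist.subsequent_years", 0.99),
    ("treatment.efficacy_rr.hip", 0.67),
    ("treatment.efficacy_rr.vertebral", 0.45),
    ("treatment.efficacy_rr.wrist", 0.81),
    ("treatment.max_duration", 5.0),
    ("fls.attendance", 0.66),
    ("fls.initiation_fls", 0.38),
    ("fls.initiation_no_fls", 0.172),
    ("fls.adherence_fls", 0.57),
    ("fls.adherence_no_fls", 0.341),
    ("econ.discount_rate_costs", 0.05),
    ("econ.discount_rate_qalys", 0.05),
    ("econ.wtp", 10500.0),
    ("econ.cycle_length", 0.5),
    ("econ.n_patients", 1_000_000),
]


def _get(obj, path):
    for token in path.split("."):
        obj = obj[token] if isinstance(obj, dict) else getattr(obj, token)
    return obj


@pytest.mark.parametrize("path,age,gender,expected", _TABLE_CELLS)
def test_base_case_table_cells(base_params, path, age, gender, expected):
    assert lookup(_get(base_params, path), age, gender) == expected


@pytest.mark.parametrize("path,expected", _SCALARS)
def test_base_case_scalars(base_params, path, expected):
    assert _get(base_params, path) == expected


def test_persistence_schedule_as_published(base_params):
    assert base_params.treatment.persistence_schedule == [
        (0.5, 0.56),
        (1.0, 0.50),
        (2.0, 0.33),
        (3.0, 0.21),
        (4.0, 0.12),
        (5.0, 0.06),
    ]


def test_base_case_hooks_default_to_no_adjustment(base_params):
    # attribution and the wrist adjustment are configurable hooks, inert by default
    assert base_params.risk.wrist_asian_adjustment == 1.0
    assert base_params.mortality.fls_mortality_or is None
    for site in ("hip", "vertebral", "wrist"):
        table = base_params.risk.attribution[site]
        assert set(table.values_female) == {1.0}


def test_lookup_is_piecewise_constant(base_params):
    table = base_params.risk.incidence["hip"]
    assert table.lookup(70, "F") == table.lookup(74.5, "F") == table.lookup(74.99, "F")
    assert table.lookup(74.99, "F") != table.lookup(75.0, "F")


def test_lookup_outside_range_names_the_table(base_params):
    with pytest.raises(AgeRangeError, match="hip incidence"):
        lookup(base_params.risk.incidence["hip"], 40, "F")


def test_gender_invariant_table_serves_both_genders(base_params):
    table = base_params.risk.rr_osteoporosis["hip"]
    assert table.lookup(67, "F") == table.lookup(67, "M") == 3.91


def test_band_validation_rejects_gaps_and_overlaps():
    with pytest.raises(ValidationError, match="contiguous"):
        AgeBandTable(bands=[(60, 69), (71, None)], values_female=[1.0, 2.0])
    with pytest.raises(ValidationError):
        AgeBandTable(bands=[(60, 69), (68, None)], values_female=[1.0, 2.0])
    with pytest.raises(ValidationError, match="nonnegative"):
        AgeBandTable(bands=[(60, None)], values_female=[-1.0])


def test_save_load_round_trip(base_params, tmp_path):
    path = tmp_path / "params.yaml"
    save_parameters(base_params, path)
    assert load_parameters(path) == base_params


def test_round_trip_of_perturbed_parameters():
    rng = np.random.default_rng(42)
    for _ in range(5):
        p = perturbed_parameters(rng, spread=0.3)
        assert load_parameters(save_parameters(p)) == p


def test_partial_document_merges_over_defaults():
    p = load_parameters({"costs": {"fls_fee": 400.0}})
    base = default_parameters()
    assert p.costs.fls_fee == 400.0
    p.costs.fls_fee = 200.0
    assert p == base


def test_validation_enumerates_all_violations():
    with pytest.raises(ValidationError) as err:
        load_parameters(
            {
                "fls": {"adherence_fls": 1.3},
                "mortality": {"excess_attribution": -0.5},
            }
        )
    paths = {tuple(e["loc"]) for e in err.value.errors()}
    assert ("fls", "adherence_fls") in paths
    assert ("mortality", "excess_attribution") in paths


def test_table_csv_export(base_params):
    frame = base_params.mortality.life_table.to_frame()
    assert list(frame.columns) == ["age_lower", "age_upper", "female", "male"]
    assert len(frame) == 8
    assert frame["female"].iloc[0] == 13.06
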