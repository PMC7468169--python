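"""Input-term computations against the published budget sheets and
structural properties of the input ledgers."""

import dataclasses
import math

import pytest

from farmbudget import (
    Approach,
    CoefficientMissingError,
    CropPlot,
    FarmRecord,
    FluxTable,
    NotApplicableError,
    Nutrient,
    Phase,
    UnresolvableTermError,
    annual_manure_production,
    assemble_input_ledger,
    bnf_input,
    compost_input,
    deposition_input,
    fertilizer_input,
    manure_input,
    seed_input,
    total_compost_input,
)
from farmbudget.synthetic import GeneratorConfig, generate_farms

from conftest import approx_printed

N, P = Nutrient.N, Nutrient.P


class TestManureProduction:
    @pytest.mark.parametrize(
        "farm_id, expected",
        [("farm1", 1_303_050.0), ("farm2", 3_350_700.0), ("farm3", 2_792_250.0)],
    )
    def test_published_farm_values(self, farms, farm_id, expected):
        assert annual_manure_production(farms[farm_id]) == pytest.approx(expected)

    def test_zero_heads(self, farms):
        empty = dataclasses.replace(farms["farm1"], head_count=0)
        assert annual_manure_production(empty) == 0.0


class TestSeedInput:
    @pytest.mark.parametrize(
        "farm_id, nutrient, expected",
        [
            ("farm1", N, 0.264),
            ("farm2", N, 7.92),  # 1.65 ha corn @4.4 + 1.65 ha sesame @0.4
            ("farm3", N, 4.648),
            ("farm1", P, 0.462),
            ("farm2", P, 2.97),
        ],
    )
    def test_per_crop_flux_times_area(self, farms, fluxes, farm_id, nutrient, expected):
        assert seed_input(farms[farm_id], fluxes, nutrient) == pytest.approx(expected)

    def test_unknown_crop_raises_named_error(self, farms, fluxes):
        farm = dataclasses.replace(
            farms["farm1"], plots=(CropPlot(crop_name="barley", area=1.0),)
        )
        with pytest.raises(CoefficientMissingError, match="barley"):
            seed_input(farm, fluxes, N)


class TestFertilizerInput:
    def test_resolved_values_win(self, farms, fluxes):
        assert fertilizer_input(farms["farm1"], fluxes, N) == 8.0
        assert fertilizer_input(farms["farm3"], fluxes, P) == 16.0

    def test_organic_farm_is_zero(self, farms, fluxes):
        assert fertilizer_input(farms["farm2"], fluxes, N) == 0.0

    def test_rate_times_content_times_area(self, farms, fluxes):
        farm = dataclasses.replace(
            farms["farm1"],
            plots=(CropPlot(crop_name="sesame", area=1.0, fertilizer_rate=100.0),),
            resolved_fertilizer_n=None,
        )
        fx = dataclasses.replace(fluxes, fertilizer_content={N: 0.10, P: 0.05})
        assert fertilizer_input(farm, fx, N) == pytest.approx(10.0)

    def test_unresolvable_without_content(self, farms, fluxes):
        farm = dataclasses.replace(farms["farm1"], resolved_fertilizer_n=None)
        with pytest.raises(UnresolvableTermError):
            fertilizer_input(farm, fluxes, N)


class TestManureInput:
    @pytest.mark.parametrize(
        "farm_id, nutrient, printed",
        [
            ("farm1", N, 11075.9), ("farm2", N, 28480.9), ("farm3", N, 23734.1),
            ("farm1", P, 1954.6), ("farm2", P, 5026.1), ("farm3", P, 4188.4),
        ],
    )
    def test_back_derived_content_reproduces_all_published_rows(
        self, farms, fluxes, farm_id, nutrient, printed
    ):
        assert manure_input(farms[farm_id], fluxes, nutrient) == pytest.approx(
            printed, abs=0.051
        )

    def test_bulking_agent_with_zero_content_adds_nothing(self, farms, fluxes):
        farm = farms["farm2"]  # 16.7 t/yr rice hull, content 0
        without = dataclasses.replace(farm, bulking_agent_mass=0.0)
        assert manure_input(farm, fluxes, N) == manure_input(without, fluxes, N)


class TestCompostInput:
    @pytest.mark.parametrize(
        "farm_id, phase, nutrient, printed",
        [
            ("farm1", Phase.LIQUID, N, 5031.1),
            ("farm2", Phase.LIQUID, N, 12832.6),
            ("farm3", Phase.LIQUID, N, 5551.2),
            ("farm2", Phase.SOLID, N, 1363.8),
            ("farm3", Phase.SOLID, N, 1810.9),
            ("farm1", Phase.LIQUID, P, 72.6),
            ("farm3", Phase.LIQUID, P, 85.4),
            ("farm2", Phase.SOLID, P, 1022.9),
            ("farm3", Phase.SOLID, P, 925.2),
        ],
    )
    def test_production_times_content_times_loading(
        self, farms, fluxes, farm_id, phase, nutrient, printed
    ):
        value = compost_input(farms[farm_id], fluxes, nutrient, phase)
        assert approx_printed(value, printed)

    def test_no_solid_facility_gives_zero(self, farms, fluxes):
        assert compost_input(farms["farm1"], fluxes, N, Phase.SOLID) == 0.0

    def test_missing_loading_raises(self, farms, fluxes):
        gappy = dataclasses.replace(
            fluxes, loading={"liquid": {}, "solid": fluxes.loading["solid"]}
        )
        with pytest.raises(CoefficientMissingError):
            compost_input(farms["farm1"], gappy, N, Phase.LIQUID)

    @pytest.mark.parametrize(
        "farm_id, printed",
        [("farm3", 7362.1), ("farm1", 5031.1), ("farm2", 14196.4)],
    )
    def test_total_is_liquid_plus_solid(self, farms, fluxes, farm_id, printed):
        assert approx_printed(total_compost_input(farms[farm_id], fluxes, N), printed)


class TestAreaBasedInputs:
    @pytest.mark.parametrize(
        "farm_id, nutrient, printed",
        [("farm2", N, 79.5), ("farm3", P, 1.4), ("farm1", N, 15.9)],
    )
    def test_deposition(self, farms, fluxes, farm_id, nutrient, printed):
        assert approx_printed(deposition_input(farms[farm_id], fluxes, nutrient), printed)

    @pytest.mark.parametrize(
        "farm_id, printed", [("farm1", 9.9), ("farm2", 49.5), ("farm3", 34.8)]
    )
    def test_biological_fixation(self, farms, fluxes, farm_id, printed):
        assert bnf_input(farms[farm_id], fluxes) == pytest.approx(printed, abs=0.051)

    def test_fixation_not_defined_for_p(self, farms, fluxes):
        with pytest.raises(NotApplicableError):
            bnf_input(farms["farm1"], fluxes, P)


class TestInputLedger:
    @pytest.mark.parametrize(
        "farm_id, nutrient, approach, printed_total",
        [
            ("farm1", N, Approach.SSB, 5065.2),
            ("farm2", N, Approach.CURRENT_GNB, 28617.9),
            ("farm3", P, Approach.SSB, 1030.0),
            ("farm2", N, Approach.SSB, 14333.4),
            ("farm3", N, Approach.SSB, 7473.4),
        ],
    )
    def test_published_totals(self, farms, fluxes, farm_id, nutrient, approach, printed_total):
        ledger = assemble_input_ledger(farms[farm_id], fluxes, nutrient, approach)
        assert approx_printed(ledger.total, printed_total)

    def test_gnb_approaches_share_input_totals(self, farms, fluxes):
        for farm in farms.values():
            for nutrient in Nutrient:
                cur = assemble_input_ledger(farm, fluxes, nutrient, Approach.CURRENT_GNB)
                ideal = assemble_input_ledger(farm, fluxes, nutrient, Approach.IDEAL_GNB)
                assert cur.total == ideal.total

    def test_optional_components_present_as_zero_terms(self, farms, fluxes):
        ledger = assemble_input_ledger(farms["farm1"], fluxes, N, Approach.SSB)
        assert ledger["organic_fertilizer"] == 0.0
        assert ledger["mineralization"] == 0.0


class TestStructuralProperties:
    def test_manure_and_compost_inputs_scale_linearly_with_herd(self, farms, fluxes):
        farm = farms["farm2"]
        k = 3.0
        scaled = dataclasses.replace(
            farm,
            head_count=farm.head_count * k,
            liquid_compost_production=farm.liquid_compost_production * k,
            solid_compost_production=farm.solid_compost_production * k,
            bulking_agent_mass=farm.bulking_agent_mass * k,
        )
        assert manure_input(scaled, fluxes, N) == pytest.approx(
            k * manure_input(farm, fluxes, N)
        )
        assert total_compost_input(scaled, fluxes, P) == pytest.approx(
            k * total_compost_input(farm, fluxes, P)
        )

    def test_liquid_loading_ordering(self, fluxes):
        liquid = fluxes.loading["liquid"]
        for nutrient in Nutrient:
            assert (
                liquid["storage_only"][nutrient]
                > liquid["intermittent_aeration"][nutrient]
                > liquid["continuous_aeration"][nutrient]
            )
        assert liquid["continuous_aeration"][N] == liquid["intermittent_aeration"][N] / 2

    def test_ledger_totals_match_independent_term_sums_on_random_farms(self):
        cohort = generate_farms(GeneratorConfig(seed=7, n_farms=50))
        for synthetic in cohort:
            for nutrient in Nutrient:
                for approach in Approach:
                    ledger = assemble_input_ledger(
                        synthetic.farm, synthetic.fluxes, nutrient, approach
                    )
                    assert ledger.total == math.fsum(v for _, v in ledger.terms)
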