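"""Competitive occupancy calculators, presets, what-if overrides, reports."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metalation.calculator import (
    AvailabilityPreset,
    MetalationResult,
    ProteinAffinitySet,
    available_presets,
    compute_occupancy,
    load_affinity_set,
    load_preset,
    occupancy_from_free_energies,
    occupancy_from_ratios,
    packaged_affinity_set,
    render_report,
    whatif_availability,
)
from metalation.chem import DEFAULT_CONSTANTS, Metal, kd_to_free_energy


class TestPresets:
    def test_three_conditions_shipped(self):
        assert available_presets() == ["aerobic", "anaerobic", "h2o2"]

    def test_anaerobic_values_as_published(self):
        p = load_preset("anaerobic")
        assert p.concentrations[Metal.NI] == 9e-14
        assert p.concentrations[Metal.ZN] == 1.4e-12  # midpoint default
        assert p.sd[Metal.MN] == 3e-6

    def test_zinc_variants_selectable(self):
        assert load_preset("aerobic", zinc="zur").concentrations[Metal.ZN] == 7e-12
        assert load_preset("aerobic", zinc="zntr").concentrations[Metal.ZN] == 4e-13

    def test_boundary_entries_carry_no_sd(self):
        p = load_preset("h2o2")
        assert Metal.FE in p.boundary and Metal.FE not in p.sd
        assert Metal.CU in p.boundary

    def test_unknown_preset_reports_choices(self):
        with pytest.raises(KeyError, match="aerobic"):
            load_preset("microaerophilic")

    def test_availabilities_follow_irving_williams_ordering(self):
        """Tighter-binding metals are buffered at lower free energies."""
        for name in available_presets():
            p = load_preset(name)
            g = {m: p.free_energy(m) for m in Metal}
            assert g[Metal.MN] > g[Metal.CO] > g[Metal.NI] > g[Metal.CU]
            assert g[Metal.FE] > g[Metal.CO]


class TestComputeOccupancy:
    def test_nickel_chaperone_predominantly_nickel_when_anaerobic(self):
        result = compute_occupancy(load_preset("anaerobic"), packaged_affinity_set("hypb"))
        assert result.percent(Metal.NI) == pytest.approx(57.4, abs=2.0)
        assert result.percent(Metal.ZN) == pytest.approx(2.6, abs=2.0)
        assert result.total_occupancy < 1.0

    def test_manganese_sod_correctly_metalated_after_peroxide(self):
        soda = packaged_affinity_set("soda")
        assert compute_occupancy(load_preset("h2o2"), soda).percent(Metal.MN) == pytest.approx(99.5, abs=2.0)
        assert compute_occupancy(load_preset("aerobic"), soda).percent(Metal.MN) == pytest.approx(96.6, abs=2.0)

    def test_single_metal_at_matching_kd_is_half_occupied(self):
        preset = load_preset("aerobic")
        aff = ProteinAffinitySet("toy", {Metal.NI: preset.concentrations[Metal.NI]})
        assert compute_occupancy(preset, aff).occupancy(Metal.NI) == pytest.approx(0.5)

    def test_all_metals_disabled_gives_zero_total(self):
        aff = ProteinAffinitySet("toy", {Metal.NI: 1e-12}, enabled=frozenset())
        result = compute_occupancy(load_preset("aerobic"), aff)
        assert result.total_occupancy == 0.0 and result.rows == ()

    def test_two_metal_hand_enumerated_partition_function(self):
        # site states: empty (1), Ni (r=2), Zn (r=1/4) -> occupancies 2/3.25, 0.25/3.25
        preset = AvailabilityPreset("toy", {Metal.NI: 2e-12, Metal.ZN: 1e-12})
        aff = ProteinAffinitySet("toy", {Metal.NI: 1e-12, Metal.ZN: 4e-12})
        result = compute_occupancy(preset, aff)
        assert result.occupancy(Metal.NI) == pytest.approx(2 / 3.25, rel=1e-12)
        assert result.occupancy(Metal.ZN) == pytest.approx(0.25 / 3.25, rel=1e-12)

    def test_occupancy_ordering_follows_free_energy_gradient(self):
        result = compute_occupancy(load_preset("aerobic"), packaged_affinity_set("soda"))
        rows = sorted(result.rows, key=lambda r: r.ddg)
        occs = [r.occupancy for r in rows]
        assert occs == sorted(occs, reverse=True)

    def test_enabled_metal_without_preset_concentration_named(self):
        preset = AvailabilityPreset("toy", {Metal.NI: 1e-13})
        aff = ProteinAffinitySet("toy", {Metal.ZN: 1e-12})
        with pytest.raises(ValueError, match="Zn2"):
            compute_occupancy(preset, aff)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-20, max_value=-3),  # log10 availability
                st.floats(min_value=-20, max_value=-3),  # log10 K_D
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_concentration_and_free_energy_forms_agree(self, draws):
        metals = list(Metal)[: len(draws)]
        ratios = {}
        ddg = {}
        for metal, (log_c, log_kd) in zip(metals, draws):
            c, kd = 10.0 ** log_c, 10.0 ** log_kd
            ratios[metal] = c / kd
            ddg[metal] = kd_to_free_energy(kd) - kd_to_free_energy(c)
        a = occupancy_from_ratios(ratios)
        b = occupancy_from_free_energies(ddg)
        for metal in metals:
            assert a[metal] == pytest.approx(b[metal], rel=1e-10)
        # strictly below 1 mathematically; equality only at float rounding
        assert sum(a.values()) <= 1.0

    def test_occupancy_monotone_in_affinity_and_availability(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            kd_ni = 10.0 ** rng.uniform(-15, -10)
            kd_zn = 10.0 ** rng.uniform(-13, -9)
            preset = load_preset("aerobic")
            aff = ProteinAffinitySet("toy", {Metal.NI: kd_ni, Metal.ZN: kd_zn})
            base = compute_occupancy(preset, aff)
            weaker = compute_occupancy(
                preset, ProteinAffinitySet("toy", {Metal.NI: kd_ni * 5, Metal.ZN: kd_zn})
            )
            assert weaker.occupancy(Metal.NI) < base.occupancy(Metal.NI)
            richer = compute_occupancy(
                whatif_availability(preset, {Metal.NI: preset.concentrations[Metal.NI] * 5}), aff
            )
            assert richer.occupancy(Metal.NI) > base.occupancy(Metal.NI)
            # raising a competitor's availability depresses the other metal
            assert richer.occupancy(Metal.ZN) < base.occupancy(Metal.ZN)

    def test_excluding_a_competitor_never_lowers_remaining_occupancy(self):
        preset = load_preset("aerobic")
        aff = packaged_affinity_set("soda")
        both = compute_occupancy(preset, aff)
        mn_only = compute_occupancy(preset, aff.exclude(Metal.FE))
        assert mn_only.occupancy(Metal.MN) >= both.occupancy(Metal.MN)


class TestWhatIf:
    def test_empty_overrides_return_same_preset(self):
        p = load_preset("aerobic")
        assert whatif_availability(p, {}) is p

    def test_override_rederives_free_energy_and_marks_custom(self):
        p = whatif_availability(load_preset("aerobic"), {Metal.MN: 1e-4})
        assert p.name == "custom"
        assert p.free_energy(Metal.MN) == pytest.approx(
            DEFAULT_CONSTANTS.RT * math.log(1e-4), rel=1e-12
        )
        assert Metal.MN not in p.sd

    def test_overriding_aerobic_to_peroxide_values_reproduces_preset(self):
        aerobic, h2o2 = load_preset("aerobic"), load_preset("h2o2")
        custom = whatif_availability(aerobic, dict(h2o2.concentrations))
        soda = packaged_affinity_set("soda")
        a = compute_occupancy(custom, soda)
        b = compute_occupancy(h2o2, soda)
        for metal in (Metal.MN, Metal.FE):
            assert a.occupancy(metal) == pytest.approx(b.occupancy(metal), rel=1e-12)

    def test_non_positive_override_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            whatif_availability(load_preset("aerobic"), {Metal.MN: 0.0})


class TestReportsAndIO:
    def test_tsv_and_json_carry_identical_numbers(self):
        result = compute_occupancy(load_preset("anaerobic"), packaged_affinity_set("hypb"))
        doc = json.loads(render_report(result, "json"))
        tsv_lines = render_report(result, "tsv").strip().splitlines()
        header = tsv_lines[0].split("\t")
        for rec, line in zip(doc["metals"], tsv_lines[1:]):
            cells = dict(zip(header, line.split("\t")))
            assert float(cells["occupancy_percent"]) == rec["occupancy_percent"]
            assert float(cells["kd_molar"]) == rec["kd_molar"]

    def test_percentages_sum_to_reported_total(self):
        result = compute_occupancy(load_preset("anaerobic"), packaged_affinity_set("hypb"))
        doc = json.loads(render_report(result, "json"))
        assert sum(m["occupancy_percent"] for m in doc["metals"]) == pytest.approx(
            doc["total_occupancy_percent"], abs=0.11
        )

    def test_empty_result_renders_header_only(self):
        empty = MetalationResult("toy", "aerobic", ())
        assert render_report(empty, "tsv").splitlines()[0].startswith("metal\t")

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            render_report(MetalationResult("toy", "aerobic", ()), "xml")

    def test_affinity_table_round_trip(self, tmp_path):
        path = tmp_path / "prot.tsv"
        path.write_text("metal\tkd_molar\tenabled\nNi2+\t1e-13\ttrue\nZn2+\t1e-11\tfalse\n")
        aff = load_affinity_set(path)
        assert aff.enabled == frozenset({Metal.NI})
        assert aff.kd[Metal.ZN] == 1e-11

    def test_enabled_metal_without_kd_is_an_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("metal\tkd_molar\tenabled\nNi2+\t\ttrue\n")
        with pytest.raises(ValueError, match="missing kd_molar"):
            load_affinity_set(path)

    def test_malformed_header_is_an_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("element\tkd\nNi\t1e-13\n")
        with pytest.raises(ValueError, match="expected columns"):
            load_affinity_set(path)
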