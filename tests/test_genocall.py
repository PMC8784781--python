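"""End-point parsing, NTC normalization, genotype calling, curve reduction."""

from __future__ import annotations

import numpy as np
import pytest

from asq.genocall import (
    CurveSet,
    EndpointPlate,
    PlateLayout,
    call_genotypes,
    endpoint_from_curves,
    normalize,
    read_endpoint,
    simulate_curves,
    simulate_plate,
    write_endpoint,
)

LONG_CSV = "Well,Dye,RFU\nA1,FAM,900\nA1,HEX,120\nB1,FAM,100\nB1,HEX,110\n"
WIDE_CSV = "Well,FAM,HEX\nA1,900,120\nB1,100,110\n"


def accuracy(calls, truth) -> float:
    by_well = {c.well: c.call for c in calls}
    return float(np.mean([by_well[w] == cls for w, cls in truth.items()]))


class TestReadEndpoint:
    def test_long_and_wide_dialects_agree(self):
        assert read_endpoint(LONG_CSV).wells == read_endpoint(WIDE_CSV).wells

    def test_duplicate_row_is_an_error(self):
        bad = LONG_CSV + "A1,FAM,1\n"
        with pytest.raises(ValueError, match="row 6.*duplicate|duplicate.*row 6"):
            read_endpoint(bad)

    def test_negative_rfu_is_an_error(self):
        with pytest.raises(ValueError, match="negative RFU"):
            read_endpoint("Well,Dye,RFU\nA1,FAM,-5\n")

    def test_round_trip_on_simulated_plate(self):
        plate, _, _ = simulate_plate(n_wells=96, seed=1)
        for dialect in ("long", "wide"):
            again = read_endpoint(write_endpoint(plate, dialect))
            assert set(again.wells) == set(plate.wells)
            for well in plate.wells:
                for dye in plate.dyes:
                    assert again.wells[well][dye] == pytest.approx(plate.wells[well][dye])

    def test_mismatched_dye_sets_rejected(self):
        with pytest.raises(ValueError, match="dye set"):
            EndpointPlate(wells={"A1": {"FAM": 1.0}, "B1": {"FAM": 1.0, "HEX": 2.0}})


class TestNormalize:
    def test_samples_at_ntc_mean_go_to_zero(self):
        plate = EndpointPlate(
            wells={
                "A1": {"FAM": 200.0, "HEX": 300.0},
                "H1": {"FAM": 200.0, "HEX": 300.0},
            }
        )
        layout = PlateLayout.from_samples({"A1": "s1", "H1": "NTC"})
        normalized = normalize(plate, layout)
        assert normalized.wells["A1"] == {"FAM": 0.0, "HEX": 0.0}

    def test_invariant_to_well_order(self):
        plate, layout, _ = simulate_plate(n_wells=48, seed=3)
        shuffled = EndpointPlate(wells=dict(reversed(list(plate.wells.items()))))
        a = normalize(plate, layout)
        b = normalize(shuffled, layout)
        assert a.wells == b.wells
        assert a.ntc_sd == b.ntc_sd

    def test_simulated_ntc_mean_near_zero(self):
        plate, layout, truth = simulate_plate(n_wells=96, seed=11)
        normalized = normalize(plate, layout)
        ntc_wells = [w for w, cls in truth.items() if cls == "ntc"]
        for dye in plate.dyes:
            values = [plate.wells[w][dye] for w in ntc_wells]
            se = np.std(values) / np.sqrt(len(values))
            norm_mean = np.mean([normalized.wells[w][dye] - 0.0 for w in ntc_wells])
            # clamping at zero biases the mean upward by less than ~1 SE
            assert norm_mean <= 2 * se + 1e-9

    def test_requires_ntc_wells(self):
        plate = EndpointPlate(wells={"A1": {"FAM": 1.0, "HEX": 2.0}})
        with pytest.raises(ValueError, match="NTC"):
            normalize(plate, PlateLayout.from_samples({"A1": "s1"}))


class TestCallGenotypes:
    def make_normalized(self, wells, ntc_sd=50.0):
        plate = EndpointPlate(wells=wells)
        plate.ntc_sd = {"FAM": ntc_sd, "HEX": ntc_sd}
        return plate

    def test_ntc_well_is_always_ntc(self):
        plate = self.make_normalized({"A1": {"FAM": 9000.0, "HEX": 9000.0}})
        layout = PlateLayout.from_samples({"A1": "NTC"})
        (call,) = call_genotypes(plate, layout)
        assert call.call == "ntc"

    def test_clear_single_dye_signal(self):
        plate = self.make_normalized({"A1": {"FAM": 9000.0, "HEX": 300.0}})
        layout = PlateLayout.from_samples({"A1": "s"})
        (call,) = call_genotypes(plate, layout)
        assert call.call == "allele1"
        assert call.theta == pytest.approx(9000 / 9300, abs=1e-9)

    def test_weak_signal_is_no_call(self):
        plate = self.make_normalized({"A1": {"FAM": 120.0, "HEX": 100.0}})
        layout = PlateLayout.from_samples({"A1": "s"})
        (call,) = call_genotypes(plate, layout)
        assert call.call == "no_call"

    @pytest.mark.parametrize("mode", ["threshold", "cluster"])
    def test_three_class_plate_recovery(self, mode):
        plate, layout, truth = simulate_plate(
            n_wells=90,
            proportions={"allele1": 1 / 3, "allele2": 1 / 3, "heterozygous": 1 / 3},
            centroids={
                "allele1": (9000.0, 500.0),
                "allele2": (500.0, 9000.0),
                "heterozygous": (4500.0, 4500.0),
            },
            noise_sd=400.0,
            seed=7,
        )
        # no NTC class simulated: supply separate reference NTC statistics
        normalized = EndpointPlate(
            wells={w: {d: max(v - 300.0, 0.0) for d, v in ch.items()}
                   for w, ch in plate.wells.items()}
        )
        normalized.ntc_sd = {"FAM": 50.0, "HEX": 50.0}
        calls = call_genotypes(normalized, layout, mode=mode, seed=0)
        assert accuracy(calls, truth) >= 0.99

    def test_calling_invariant_to_well_order(self):
        plate, layout, _ = simulate_plate(n_wells=48, seed=5)
        normalized = normalize(plate, layout)
        flipped = EndpointPlate(
            wells=dict(reversed(list(normalized.wells.items()))), ntc_sd=normalized.ntc_sd
        )
        a = call_genotypes(normalized, layout)
        b = call_genotypes(flipped, layout)
        assert a == b

    def test_more_than_two_dyes_unsupported(self):
        plate = EndpointPlate(wells={"A1": {"FAM": 1.0, "HEX": 2.0, "Cy5": 3.0}})
        with pytest.raises(ValueError, match="2 dyes"):
            call_genotypes(plate, PlateLayout.from_samples({"A1": "s"}))


class TestEndpointFromCurves:
    def test_flat_curve_gives_zero(self):
        curves = CurveSet(
            curves={"A1": {"FAM": np.full(40, 500.0), "HEX": np.full(40, 750.0)}}
        )
        plate = endpoint_from_curves(curves)
        assert plate.wells["A1"]["FAM"] == pytest.approx(0.0, abs=1e-9)
        assert plate.wells["A1"]["HEX"] == pytest.approx(0.0, abs=1e-9)

    def test_sigmoid_timing_controls_endpoint(self):
        cycles = np.arange(1, 41, dtype=float)

        def sigmoid(cq):
            return 300.0 + 9000.0 / (1 + np.exp(-(cycles - cq) / 1.5))

        def endpoint(cq):
            curves = CurveSet(
                curves={"A1": {"FAM": sigmoid(cq), "HEX": np.full(40, 300.0)}}
            )
            return endpoint_from_curves(curves).wells["A1"]["FAM"]

        early, late, unamplified = endpoint(24), endpoint(38), endpoint(48)
        assert early > 8000
        assert late < 0.75 * early  # rise only partially registered by cycle 40
        assert unamplified < 0.05 * early  # inflection beyond the run: no signal

    def test_window_overlap_rejected(self):
        curves, _, _ = simulate_curves(n_wells=4, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            endpoint_from_curves(curves, baseline_window=(3, 39))

    def test_feeds_the_caller(self):
        curves, layout, truth = simulate_curves(n_wells=24, seed=9)
        plate = endpoint_from_curves(curves)
        normalized = normalize(plate, layout)
        calls = call_genotypes(normalized, layout)
        assert accuracy(calls, truth) >= 0.95

    def test_read_at_any_cycle(self):
        curves, layout, truth = simulate_curves(n_wells=24, seed=9)
        plate = endpoint_from_curves(curves, summary_end=32)
        calls = call_genotypes(normalize(plate, layout), layout)
        assert accuracy(calls, truth) >= 0.95


class TestSimulators:
    def test_same_seed_reproduces(self):
        a, _, ta = simulate_plate(n_wells=96, seed=4)
        b, _, tb = simulate_plate(n_wells=96, seed=4)
        assert a.wells == b.wells and ta == tb

    def test_zero_separation_defeats_calling(self):
        plate, layout, truth = simulate_plate(
            n_wells=60,
            proportions={"allele1": 0.45, "allele2": 0.45, "ntc": 0.1},
            centroids={"allele1": (4000.0, 4000.0), "allele2": (4000.0, 4000.0)},
            seed=13,
        )
        calls = call_genotypes(normalize(plate, layout), layout)
        non_ntc = {w: c for w, c in truth.items() if c != "ntc"}
        assert accuracy([c for c in calls if c.well in non_ntc], non_ntc) < 0.6

    def test_curves_cross_detection_threshold_in_expected_window(self):
        curves, _, truth = simulate_curves(n_wells=24, seed=2)
        for well, cls in truth.items():
            if cls != "allele1":
                continue
            trace = curves.curves[well]["FAM"]
            baseline = np.mean(trace[2:15])
            noise = np.std(trace[2:15])
            crossing = np.argmax(trace > baseline + 10 * noise) + 1
            assert 20 <= crossing <= 27

    def test_invalid_parameters(self):
        with pytest.raises(ValueError, match="SD"):
            simulate_plate(noise_sd=0)
        with pytest.raises(ValueError, match="cycles"):
            simulate_curves(n_cycles=20)
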