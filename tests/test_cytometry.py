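"""Gating, bead calibration and flow-cytometry trait derivation."""

import numpy as np
import pytest

from qpa.core_io import EventTable
from qpa.cytometry import (
    PAPER_CALIBRATION,
    BeadCalibration,
    GateSpec,
    bead_normalize,
    cell_concentration,
    chla_per_size,
    estimate_size,
    fit_bead_calibration,
    gate_events,
    lipid_content,
    median_channel,
    silicification,
)
from qpa.errors import (
    DegenerateCalibrationError,
    InsufficientCellsError,
    InvalidInputError,
    MissingMetadataError,
    QualityWarning,
)
from qpa.simulate import (
    DEFAULT_SIM_CALIBRATION,
    StrainGroundTruth,
    default_gate,
    simulate_bead_events,
    simulate_events,
    simulate_stain_shift,
)


def make_events(n=100, fsc=1000.0, fl_red=500.0, fl_green=200.0, fl_uv=100.0,
                ssc=300.0, volume=100.0):
    return EventTable(
        fsc=np.full(n, fsc), ssc=np.full(n, ssc), fl_red=np.full(n, fl_red),
        fl_green=np.full(n, fl_green), fl_uv=np.full(n, fl_uv),
        acquired_volume_ul=volume,
    )


class TestGate:
    def test_zero_thresholds_keep_everything(self, rng):
        ev = make_events(50)
        out = gate_events(ev, GateSpec(0.0, 0.0))
        assert out.n_events == 50
        assert out.acquired_volume_ul == ev.acquired_volume_ul

    def test_thresholds_above_max_empty_table(self):
        out = gate_events(make_events(50), GateSpec(min_fl_red=1e9, min_fsc=1e9))
        assert out.n_events == 0

    def test_gate_idempotent_and_subset(self, rng):
        ev = simulate_events(StrainGroundTruth(mu_true=0.5), seed=3, n_events=2000)
        gate = default_gate()
        once = gate_events(ev, gate)
        twice = gate_events(once, gate)
        assert once.n_events == twice.n_events <= ev.n_events
        np.testing.assert_array_equal(once.fsc, twice.fsc)

    def test_debris_fraction_removed(self):
        ev = simulate_events(
            StrainGroundTruth(mu_true=0.5, size_true=6.0),
            n_events=10000, debris_fraction=0.2, seed=11,
        )
        kept = gate_events(ev, default_gate()).n_events / ev.n_events
        assert kept == pytest.approx(0.8, abs=0.02)


class TestBeadCalibration:
    def test_exact_line_recovered(self):
        cal = fit_bead_calibration([(d, 1000.0 * d) for d in (2, 4, 6, 10, 15)])
        assert cal.slope == pytest.approx(1000.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.r_squared == pytest.approx(1.0)

    def test_published_instrument_constants_invert_to_10um(self):
        # size = (FSC + 275549)/83539 at FSC = 559841 gives exactly 10 um
        ev = make_events(n=300, fsc=559841.0)
        assert estimate_size(PAPER_CALIBRATION, ev) == pytest.approx(10.0, rel=1e-12)

    def test_noiseless_bead_fixture_recovers_calibration(self):
        events, labels = simulate_bead_events(
            DEFAULT_SIM_CALIBRATION, noise_sigma=0.0, seed=0
        )
        medians = [
            (d, median_channel(events.subset(labels == d), "FSC"))
            for d in sorted(set(labels))
        ]
        cal = fit_bead_calibration(medians)
        assert cal.slope == pytest.approx(DEFAULT_SIM_CALIBRATION.slope, rel=1e-9)
        assert cal.intercept == pytest.approx(DEFAULT_SIM_CALIBRATION.intercept, rel=1e-9)

    def test_noisy_beads_match_normal_equations_oracle(self, rng):
        d = np.array([2.0, 4.0, 6.0, 10.0, 15.0])
        f = 20000.0 * d + 1000.0 + rng.normal(0, 500, 5)
        cal = fit_bead_calibration(list(zip(d, f)))
        # oracle: explicit normal equations
        x = np.column_stack([d, np.ones(5)])
        slope, intercept = np.linalg.solve(x.T @ x, x.T @ f)
        assert cal.slope == pytest.approx(slope, rel=1e-9)
        assert cal.intercept == pytest.approx(intercept, rel=1e-9)

    def test_single_diameter_rejected(self):
        with pytest.raises(DegenerateCalibrationError):
            fit_bead_calibration([(6.0, 5000.0), (6.0, 5100.0)])


class TestMedianAndSize:
    def test_single_event(self):
        assert median_channel(make_events(1, fl_red=42.0), "FL_RED") == 42.0

    def test_lower_median_convention_for_even_counts(self):
        ev = EventTable(
            fsc=np.array([1.0, 2.0, 3.0, 4.0]), ssc=np.zeros(4),
            fl_red=np.zeros(4), fl_green=np.zeros(4), fl_uv=np.zeros(4),
        )
        assert median_channel(ev, "FSC") == 2.0

    def test_large_lognormal_sample_near_analytic_median(self, rng):
        n = 100_000
        ev = EventTable(
            fsc=rng.lognormal(8.0, 0.4, n), ssc=np.zeros(n), fl_red=np.zeros(n),
            fl_green=np.zeros(n), fl_uv=np.zeros(n),
        )
        assert median_channel(ev, "FSC") == pytest.approx(np.exp(8.0), rel=0.01)

    def test_empty_table_rejected(self):
        with pytest.raises(InsufficientCellsError):
            median_channel(make_events(0), "FSC")

    def test_insufficient_cells_boundary(self):
        cal = BeadCalibration(slope=1000.0, intercept=0.0)
        with pytest.raises(InsufficientCellsError):
            estimate_size(cal, make_events(199, fsc=6000.0))
        assert estimate_size(cal, make_events(200, fsc=6000.0)) == pytest.approx(6.0)

    def test_size_monotone_in_fsc(self):
        cal = BeadCalibration(slope=1000.0, intercept=500.0)
        sizes = [
            estimate_size(cal, make_events(300, fsc=f)) for f in (4000.0, 8000.0, 16000.0)
        ]
        assert sizes == sorted(sizes)

    def test_simulated_population_size_within_2pct(self):
        truth = StrainGroundTruth(mu_true=0.5, size_true=4.0)
        ev = simulate_events(truth, n_events=10000, debris_fraction=0.2, seed=5)
        gated = gate_events(ev, default_gate())
        size = estimate_size(DEFAULT_SIM_CALIBRATION, gated)
        assert size == pytest.approx(4.0, rel=0.02)

    def test_fsc_ordering_preserved_between_sizes(self):
        small = simulate_events(StrainGroundTruth(0.5, size_true=4.0), seed=1, n_events=3000)
        large = simulate_events(StrainGroundTruth(0.5, size_true=12.0), seed=1, n_events=3000)
        assert median_channel(small, "FSC") < median_channel(large, "FSC")


class TestStainTraits:
    def test_chla_per_size_hand_value_and_linearity(self):
        ev = make_events(101, fl_red=600.0)
        assert chla_per_size(ev, 6.0) == pytest.approx(100.0)
        doubled = ev.with_channel("FL_RED", ev.fl_red * 2)
        assert chla_per_size(doubled, 6.0) == pytest.approx(200.0)
        with pytest.raises(InvalidInputError):
            chla_per_size(ev, 0.0)

    def test_identical_tables_zero_lipid(self):
        ev = make_events(300)
        assert lipid_content(ev, ev) == 0.0

    def test_negative_delta_warns_but_returns(self):
        pre = make_events(300, fl_green=250.0)
        post = make_events(300, fl_green=200.0)
        with pytest.warns(QualityWarning):
            assert lipid_content(pre, post) == pytest.approx(-50.0)

    def test_simulated_bodipy_delta_recovered(self):
        truth = StrainGroundTruth(mu_true=0.5)
        pre = simulate_events(truth, n_events=10000, seed=21)
        post = simulate_stain_shift(pre, "FL_GREEN", 250.0, seed=22)
        gate = default_gate()
        delta = lipid_content(gate_events(pre, gate), gate_events(post, gate))
        assert delta == pytest.approx(250.0, rel=0.05)
        np.testing.assert_array_equal(post.fl_red, pre.fl_red)  # other channels untouched

    def test_silicification_hand_value(self):
        stained = make_events(300, fl_uv=600.0)
        unstained = make_events(300, fl_uv=100.0)
        assert silicification(stained, unstained, 0.5) == pytest.approx(1000.0)
        assert silicification(stained, stained, 0.5) == 0.0

    def test_silicification_requires_positive_growth(self):
        ev = make_events(300)
        with pytest.raises(InvalidInputError):
            silicification(ev, ev, 0.0)


class TestConcentrationAndNormalisation:
    def test_cell_concentration_hand_value(self):
        assert cell_concentration(make_events(1000, volume=100.0)) == pytest.approx(10000.0)
        assert cell_concentration(make_events(0, volume=100.0)) == 0.0

    def test_missing_volume_rejected(self):
        ev = make_events(10, volume=float("nan"))
        with pytest.raises(MissingMetadataError):
            cell_concentration(ev)

    def test_bead_normalize_identity_and_linearity(self):
        assert bead_normalize(5000.0, 5000.0) == pytest.approx(1.0)
        assert bead_normalize(2500.0, 5000.0) == pytest.approx(0.5)
        with pytest.raises(InvalidInputError):
            bead_normalize(100.0, 0.0)

    def test_gain_change_cancels_across_experiments(self):
        # same sample on a detector with 2x gain: bead-normalised trait equal
        ev = make_events(500, fl_red=600.0)
        bead_median = 5000.0
        t1 = bead_normalize(median_channel(ev, "FL_RED"), bead_median)
        ev2 = ev.with_channel("FL_RED", ev.fl_red * 2.0)
        t2 = bead_normalize(median_channel(ev2, "FL_RED"), bead_median * 2.0)
        assert t1 == pytest.approx(t2, rel=1e-12)
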