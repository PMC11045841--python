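"""Quantum-efficiency and velocity-phase statistics."""

import numpy as np
import pytest

from rotordyn.ensemble_stats import (
    condition_table,
    decay_window,
    ensemble_average,
    velocity_histogram,
    wilson_interval,
)
from rotordyn.errors import EmptyPopulationError
from rotordyn.hop_analysis import HopRecord


def _record(dtau, label, hop_time=50.0, tid="t"):
    return HopRecord(
        traj_id=tid, hop_time=hop_time, alpha_decay=-90.0, tau_decay=-90.0,
        delta_op_decay=0.0, dtau_decay=dtau, dalpha_decay=dtau,
        ddelta_op_decay=0.0, drho_decay=float("nan"),
        end_alpha=-180.0 if label == "reactive" else 0.0, label=label,
    )


class TestConditionTable:
    def test_hand_enumerated_example(self):
        # 4 records: velocities [-2, -0.5, +0.5, -1.5], outcomes [R, U, U, R]
        recs = [
            _record(-2.0, "reactive"),
            _record(-0.5, "unreactive"),
            _record(+0.5, "unreactive"),
            _record(-1.5, "reactive"),
        ]
        ct = condition_table(recs)
        assert ct.phi_iso == pytest.approx(0.5)
        assert ct.frac_dtau_neg == pytest.approx(0.75)
        assert ct.p_neg_given_reactive == pytest.approx(1.0)
        assert ct.p_reactive_given_neg == pytest.approx(2 / 3)
        assert ct.frac_in_band_of_neg == pytest.approx(1 / 3)
        assert ct.p_reactive_given_band == pytest.approx(0.0)

    def test_all_reactive_all_negative(self):
        recs = [_record(-2.0 - i, "reactive", tid=f"t{i}") for i in range(5)]
        ct = condition_table(recs)
        assert ct.phi_iso == 1.0
        assert ct.frac_dtau_neg == 1.0
        assert ct.p_neg_given_reactive == 1.0
        assert ct.p_reactive_given_neg == 1.0

    def test_law_of_total_probability_exact(self, small_rh_records):
        records, _, _ = small_rh_records
        ct = condition_table(records)
        lhs = ct.phi_iso
        rhs = (
            ct.p_reactive_given_neg * ct.frac_dtau_neg
            + ct.p_reactive_given_pos * (1 - ct.frac_dtau_neg)
        )
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_zero_tie_counts_as_non_negative(self):
        recs = [_record(0.0, "reactive"), _record(-1.0, "unreactive")]
        ct = condition_table(recs)
        assert ct.frac_dtau_neg == pytest.approx(0.5)
        assert ct.p_neg_given_reactive == pytest.approx(0.0)

    def test_empty_population_raises(self):
        with pytest.raises(EmptyPopulationError):
            condition_table([_record(-1.0, "undecided")])

    def test_merged_phi_is_count_weighted_mean(self):
        a = [_record(-2.0, "reactive", tid=f"a{i}") for i in range(3)] + [
            _record(-0.1, "unreactive", tid="a3")
        ]
        b = [_record(-2.0, "reactive", tid="b0")] + [
            _record(0.4, "unreactive", tid=f"b{i}") for i in range(1, 5)
        ]
        phi_a = condition_table(a).phi_iso
        phi_b = condition_table(b).phi_iso
        merged = condition_table(a + b).phi_iso
        assert merged == pytest.approx((4 * phi_a + 5 * phi_b) / 9, abs=1e-12)

    def test_generator_phi_within_wilson_interval_of_construction(self):
        # 200-trajectory ensemble whose construction-level phi is measured
        # from the ground-truth ledger; the pipeline estimate must agree.
        from rotordyn.hop_analysis import analyze_ensemble
        from rotordyn.synthetic_data import generate, get_preset

        ensemble, ledger = generate(get_preset("rh_like", seed=23))
        decayed = [e for e in ledger if e.label != "undecayed"]
        phi_truth = sum(e.label == "reactive" for e in decayed) / len(decayed)
        records, _ = analyze_ensemble(ensemble)
        ct = condition_table(records)
        lo, hi = wilson_interval(ct.n_reactive, ct.n_classified)
        assert lo <= phi_truth <= hi


class TestVelocityHistogram:
    def test_single_record_lands_in_expected_bin(self):
        hist = velocity_histogram([_record(-0.5, "reactive")])
        k = np.searchsorted(hist.bin_edges, -0.5, side="right") - 1
        assert hist.counts_reactive[k] == 1
        assert hist.counts_reactive.sum() + hist.counts_unreactive.sum() == 1

    def test_mirrored_velocities_mirror_histogram(self):
        vals = [-4.3, -2.1, -0.7]
        h_neg = velocity_histogram([_record(v, "reactive", tid=f"n{i}") for i, v in enumerate(vals)])
        h_pos = velocity_histogram([_record(-v, "reactive", tid=f"p{i}") for i, v in enumerate(vals)])
        np.testing.assert_array_equal(
            h_neg.counts_reactive, h_pos.counts_reactive[::-1]
        )

    def test_uniform_negative_values_binning_oracle(self):
        vals = np.linspace(-9.95, -0.05, 10)
        recs = [_record(v, "unreactive", tid=f"t{i}") for i, v in enumerate(vals)]
        hist = velocity_histogram(recs)
        expected, _ = np.histogram(vals, bins=hist.bin_edges)
        np.testing.assert_array_equal(hist.counts_unreactive, expected)
        assert hist.counts_unreactive.sum() == 10

    def test_total_equals_classified_count(self, small_rh_records):
        records, _, _ = small_rh_records
        usable = [r for r in records if r.classified and r.velocity_defined]
        hist = velocity_histogram(records)
        assert hist.counts_reactive.sum() + hist.counts_unreactive.sum() == len(usable)


class TestDecayWindow:
    def test_examples(self):
        recs = [_record(-1, "reactive", hop_time=t, tid=f"t{t}") for t in (30, 100, 180)]
        w = decay_window(recs)
        assert w["idt"] == 30 and w["dtl"] == 150

    def test_identical_times_zero_spread(self):
        recs = [_record(-1, "reactive", hop_time=42.0, tid=f"t{i}") for i in range(3)]
        assert decay_window(recs)["dtl"] == 0.0

    def test_single_record_raises(self):
        with pytest.raises(EmptyPopulationError):
            decay_window([_record(-1, "reactive")])


class TestEnsembleAverage:
    def _two_slope_ensemble(self):
        from rotordyn.synthetic_data import embed_xyz
        from rotordyn.trajectory_io import Ensemble, Trajectory

        t = np.arange(30.0)
        trajs = []
        for tid, slope in (("a", -1.0), ("b", -2.0)):
            alpha = slope * t
            trajs.append(
                Trajectory(
                    id=tid, atom_labels=["C"] * 4 + ["H"] * 2,
                    times=t.copy(), coords=embed_xyz(alpha, alpha),
                    states=np.ones(len(t), dtype=int),
                )
            )
        return Ensemble(
            trajectories=trajs,
            dihedral_map={"alpha": (0, 1, 2, 3), "beta": (4, 1, 2, 5)},
        )

    def test_mean_of_two_linear_trajectories(self):
        from rotordyn.geometry import derive_series

        ens = self._two_slope_ensemble()
        series = {tr.id: derive_series(tr, ens.dihedral_map) for tr in ens}
        times, mean, count = ensemble_average("alpha", ens, series)
        np.testing.assert_allclose(mean, -1.5 * times, atol=1e-6)
        assert np.all(count == 2)

    def test_survivors_drop_out_after_decay(self):
        from rotordyn.geometry import derive_series

        ens = self._two_slope_ensemble()
        ens.trajectories[1].states[10:] = 0  # trajectory b decays at frame 10
        series = {tr.id: derive_series(tr, ens.dihedral_map) for tr in ens}
        times, mean, count = ensemble_average("alpha", ens, series)
        np.testing.assert_allclose(mean[:10], -1.5 * times[:10], atol=1e-6)
        np.testing.assert_allclose(mean[10:], -1.0 * times[10:], atol=1e-6)
        assert count[9] == 2 and count[10] == 1

    def test_single_trajectory_average_is_identity(self):
        from rotordyn.geometry import derive_series

        ens = self._two_slope_ensemble()
        ens.trajectories = ens.trajectories[:1]
        series = {tr.id: derive_series(tr, ens.dihedral_map) for tr in ens}
        _, mean, _ = ensemble_average("alpha", ens, series)
        np.testing.assert_allclose(mean, series["a"]["alpha"].values, atol=1e-9)

    def test_common_phase_wag_average_preserves_amplitude(self):
        # zero phase jitter across trajectories: the survivor average of the
        # promoter velocity -0.5 d(delta_op)/dt keeps the generating amplitude
        from rotordyn.geometry import derive_series
        from rotordyn.synthetic_data import generate, get_preset

        cfg = get_preset("rh_like", n_traj=30, seed=9, wag_phase_sd=0.0)
        ens, _ = generate(cfg)
        series = {tr.id: derive_series(tr, ens.dihedral_map) for tr in ens}
        times, mean, count = ensemble_average(
            "delta_op", ens, series, velocities=True
        )
        ok = count == len(ens)  # before any decay thins the ensemble
        sig = -0.5 * mean[ok]
        expected = 0.5 * cfg.wag_amplitude * 2 * np.pi / cfg.wag_period
        assert np.nanmax(np.abs(sig)) == pytest.approx(expected, rel=0.05)
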