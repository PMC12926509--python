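"""Pulse-chase simulator: precursor curve, pool integration, noise, export."""

import json
import math

import numpy as np
import pytest

from chpsilk.errors import ConfigError
from chpsilk.ingest import build_series, read_transition_report
from chpsilk.simulate import (
    InfusionSchedule,
    PrecursorModel,
    ProteinPool,
    SimConfig,
    _integrate_enrichment,
    corrupt_and_export,
    corrupt_series,
    make_cohort,
    make_precursor_fn,
    precursor_curve,
    simulate_pool,
    simulate_two_compartment,
)

MODEL = PrecursorModel()
SCHED = InfusionSchedule()


class TestPrecursorCurve:
    def test_starts_at_zero(self):
        assert precursor_curve(MODEL, SCHED, 0.0) == 0.0

    def test_reaches_plateau_by_infusion_end(self):
        p_end = precursor_curve(MODEL, SCHED, SCHED.infusion_end_h)
        # deficit is exactly P_max * exp(-infusion_end / tau_r)
        assert p_end == pytest.approx(
            MODEL.plateau_mole_fraction, abs=2 * MODEL.plateau_mole_fraction * math.exp(-18)
        )

    def test_decay_half_life(self):
        t_end = SCHED.infusion_end_h
        boundary = precursor_curve(MODEL, SCHED, t_end)
        half = precursor_curve(MODEL, SCHED, t_end + MODEL.decay_time_const_h * math.log(2))
        assert half == pytest.approx(boundary / 2, rel=1e-12)

    def test_continuous_at_boundary(self):
        t_end = SCHED.infusion_end_h
        left = precursor_curve(MODEL, SCHED, t_end - 1e-9)
        right = precursor_curve(MODEL, SCHED, t_end + 1e-9)
        assert left == pytest.approx(right, rel=1e-6)

    def test_schedule_validation(self):
        with pytest.raises(ConfigError, match="bolus"):
            InfusionSchedule(bolus_duration_h=10.0, infusion_end_h=9.0)


class TestSimulatePool:
    def test_no_label_no_enrichment(self):
        pool = ProteinPool("TTHY", synthesis_rate=0.01, clearance_rate=0.01)
        series = simulate_pool(pool, lambda t: np.zeros_like(np.asarray(t, float)), [0.0, 4.0, 9.0])
        assert series.mole_fractions == [0.0, 0.0, 0.0]

    def test_equilibrium_enrichment_approaches_precursor(self):
        # steady-state pool under constant precursor: E -> P as t >> 1/kc
        pool = ProteinPool("TTHY", synthesis_rate=0.5, clearance_rate=0.5)
        series = simulate_pool(pool, lambda t: np.full_like(np.asarray(t, float), 0.08),
                               [0.0, 10.0, 30.0])
        assert series.mole_fractions[-1] == pytest.approx(0.08, rel=1e-6)

    def test_zero_clearance_closed_form(self):
        # kc = 0, p = P constant: E(t) = P*S*t / (A0 + S*t)
        P, S, A0 = 0.1, 0.2, 1.0
        pool = ProteinPool("ALBU", synthesis_rate=S, clearance_rate=0.0, initial_pool=A0)
        times = [0.0, 3.0, 9.0]
        series = simulate_pool(pool, lambda t: np.full_like(np.asarray(t, float), P), times)
        for t, e in zip(times, series.mole_fractions):
            assert e == pytest.approx(P * S * t / (A0 + S * t), abs=1e-6)

    def test_mass_conservation(self, default_precursor_fn):
        # total pool follows the closed form of dA/dt = S - kc*A exactly
        S, kc, A0 = 0.05, 0.02, 1.5
        e, al, au = _integrate_enrichment(S, kc, A0, 0.0, default_precursor_fn,
                                          [0.0, 4.0, 9.0, 24.0], return_amounts=True)
        total = al + au
        for t, tot in zip([0.0, 4.0, 9.0, 24.0], total[0] if total.ndim > 1 else total):
            expected = S / kc + (A0 - S / kc) * math.exp(-kc * t)
            assert tot == pytest.approx(expected, rel=1e-9)

    def test_enrichment_bounded_by_running_precursor_max(self, default_precursor_fn):
        pool = ProteinPool("CYTC", synthesis_rate=0.1, clearance_rate=0.05)
        times = [float(t) for t in range(0, 73, 4)]
        series = simulate_pool(pool, default_precursor_fn, times)
        running_max = np.maximum.accumulate(default_precursor_fn(np.array(times)))
        assert np.all(np.asarray(series.mole_fractions) <= running_max + 1e-12)

    def test_step_halving_order4_convergence(self, default_precursor_fn):
        pool = ProteinPool("TTHY", synthesis_rate=0.02, clearance_rate=0.02)
        coarse = simulate_pool(pool, default_precursor_fn, [24.0, 48.0], step=0.02)
        fine = simulate_pool(pool, default_precursor_fn, [24.0, 48.0], step=0.01)
        diff = np.max(np.abs(np.array(coarse.mole_fractions) - np.array(fine.mole_fractions)))
        assert diff < 1e-8

    def test_transit_delay_suppresses_early_label(self, default_precursor_fn):
        pool = ProteinPool("TTHY", synthesis_rate=0.02, clearance_rate=0.02, transit_delay_h=4.0)
        series = simulate_pool(pool, default_precursor_fn, [0.0, 2.0, 4.0, 8.0])
        assert series.mole_fractions[0] == series.mole_fractions[1] == 0.0
        assert series.mole_fractions[3] > 0.0

    def test_step_larger_than_spacing_rejected(self, default_precursor_fn):
        pool = ProteinPool("TTHY", synthesis_rate=0.02, clearance_rate=0.02)
        with pytest.raises(ConfigError, match="step"):
            simulate_pool(pool, default_precursor_fn, [0.0, 0.005], step=0.01)

    def test_off_grid_sample_times_rejected(self, default_precursor_fn):
        pool = ProteinPool("TTHY", synthesis_rate=0.02, clearance_rate=0.02)
        with pytest.raises(ConfigError, match="grid"):
            simulate_pool(pool, default_precursor_fn, [0.0, 1.0037], step=0.01)


class TestTwoCompartment:
    POOL = ProteinPool("TTHY", synthesis_rate=0.02, clearance_rate=0.02)
    TIMES = [float(t) for t in range(0, 49, 2)]

    def test_fast_mixing_limit(self, default_precursor_fn):
        vent, lum = simulate_two_compartment(self.POOL, default_precursor_fn, self.TIMES, 100.0)
        v = np.array(vent.mole_fractions[1:])
        l = np.array(lum.mole_fractions[1:])
        assert np.max(np.abs(l - v) / np.maximum(v, 1e-12)) < 0.01

    def test_lumbar_lags_ventricular(self, default_precursor_fn):
        vent, lum = simulate_two_compartment(self.POOL, default_precursor_fn, self.TIMES, 0.1)
        t_peak_vent = vent.times[int(np.argmax(vent.mole_fractions))]
        t_peak_lum = lum.times[int(np.argmax(lum.mole_fractions))]
        assert t_peak_lum > t_peak_vent

    def test_nonpositive_transfer_rate_rejected(self, default_precursor_fn):
        with pytest.raises(ConfigError):
            simulate_two_compartment(self.POOL, default_precursor_fn, self.TIMES, 0.0)


class TestCorruptAndExport:
    def truth_series(self, default_precursor_fn):
        pool = ProteinPool("TTHY", synthesis_rate=0.02, clearance_rate=0.02,
                           peptide_id="TTHY_TSE")
        return simulate_pool(pool, default_precursor_fn,
                             [float(t) for t in [1, 3, 5, 7, 9, 24, 48]])

    def test_noiseless_round_trip_recovers_truth(self, tmp_path, default_precursor_fn):
        truth = self.truth_series(default_precursor_fn)
        path = tmp_path / "t.csv"
        corrupt_and_export([truth], 0.0, seed=0, path=path)
        series = build_series(read_transition_report(path)).series[0]
        np.testing.assert_allclose(series.mole_fractions, truth.mole_fractions, atol=1e-9)

    def test_same_seed_identical_bytes(self, tmp_path, default_precursor_fn):
        truth = self.truth_series(default_precursor_fn)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        corrupt_and_export([truth], 0.05, seed=7, path=p1)
        corrupt_and_export([truth], 0.05, seed=7, path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_noise_scale(self, default_precursor_fn, rng):
        truth = self.truth_series(default_precursor_fn)
        records = corrupt_series(truth, rng, noise_cv=0.05)
        areas = np.array([r.peak_area for r in records if r.channel == "unlabeled"])
        expected = 1e6 * (1 - np.array(truth.mole_fractions))
        ratios = areas / expected
        assert 0.8 < ratios.mean() < 1.2
        assert np.all(ratios > 0)


class TestMakeCohort:
    def small_config(self, **kw):
        defaults = dict(
            group="NPH",
            n_subjects=2,
            pools=[ProteinPool("TTHY", synthesis_rate=0.02, clearance_rate=0.02,
                               peptide_id="TTHY_TSE")],
            sample_times_h=tuple(float(t) for t in [1, 3, 5, 7, 9, 24, 48]),
            noise_cv=0.02,
            between_subject_cv=0.1,
            seed=5,
            subject_prefix="NPH",
            production_coef_ml_per_amount=1000.0,
        )
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_bundle_files_and_truth(self, tmp_path):
        bundle = make_cohort(self.small_config(), tmp_path / "out")
        assert set(bundle.files) == {"transitions", "plasma", "truth", "production"}
        truth = json.loads((tmp_path / "out" / "truth.json").read_text())
        assert len(truth["subjects"]) == 2
        pool_truth = truth["subjects"]["NPH01"]["TTHY_TSE"]
        assert pool_truth["true_fcr_per_h"] == pytest.approx(pool_truth["clearance_rate"])

    def test_identical_subjects_without_variation(self, tmp_path):
        cfg = self.small_config(between_subject_cv=0.0, noise_cv=0.0)
        bundle = make_cohort(cfg, tmp_path / "o2")
        series = build_series(bundle.csf_records).series
        np.testing.assert_allclose(series[0].mole_fractions, series[1].mole_fractions, atol=1e-12)

    def test_seeded_rerun_identical_files(self, tmp_path):
        make_cohort(self.small_config(), tmp_path / "r1")
        make_cohort(self.small_config(), tmp_path / "r2")
        for name in ("transitions.csv", "plasma.csv", "production.csv"):
            assert (tmp_path / "r1" / name).read_bytes() == (tmp_path / "r2" / name).read_bytes()
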