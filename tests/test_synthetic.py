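import numpy as np
import pytest

from copreact.config import PipelineConfig
from copreact.errors import DomainError, SpacingError
from copreact.pipeline import extract_recording_features
from copreact.synthetic import (
    DEFAULT_MECHANICAL_DELAY_S,
    EpochSpec,
    StudySpec,
    TableSpec,
    response_curve,
    simulate_recording,
    simulate_study,
    simulate_trial_table,
)

CFG = PipelineConfig(trigger_mechanical_delay_s=DEFAULT_MECHANICAL_DELAY_S)


class TestResponseCurve:
    def test_peak_value_and_location(self):
        t = np.linspace(-0.2, 1.5, 100001)
        x = response_curve(t, 12.0, 0.15)
        assert x.max() == pytest.approx(12.0, rel=1e-8)
        assert t[np.argmax(x)] == pytest.approx(0.15, abs=1e-4)

    def test_zero_before_onset_and_at_zero(self):
        t = np.array([-0.5, -0.01, 0.0])
        np.testing.assert_array_equal(response_curve(t, 12.0, 0.15), 0.0)

    def test_derivative_max_is_d_e_over_tau(self):
        d, tau = 8.0, 0.2
        t = np.linspace(1e-9, 1.0, 2_000_001)
        v = np.diff(response_curve(t, d, tau)) / np.diff(t)
        assert v.max() == pytest.approx(d * np.e / tau, rel=1e-3)

    def test_invalid_tau(self):
        with pytest.raises(DomainError):
            response_curve(np.array([0.1]), 5.0, -0.1)


class TestSimulateRecording:
    def test_trigger_carries_three_rising_edges(self):
        rec, _ = simulate_recording(EpochSpec(seed=1))
        above = rec.trigger >= 2.5
        edges = np.flatnonzero(~above[:-1] & above[1:])
        assert edges.size == 3

    def test_same_seed_bit_identical(self):
        a, _ = simulate_recording(EpochSpec(seed=9))
        b, _ = simulate_recording(EpochSpec(seed=9))
        np.testing.assert_array_equal(a.cop_ml, b.cop_ml)
        np.testing.assert_array_equal(a.cop_ap, b.cop_ap)
        np.testing.assert_array_equal(a.trigger, b.trigger)

    def test_different_seed_differs(self):
        a, _ = simulate_recording(EpochSpec(seed=9))
        b, _ = simulate_recording(EpochSpec(seed=10))
        assert not np.array_equal(a.cop_ml, b.cop_ml)

    def test_infeasible_packing_raises(self):
        with pytest.raises(SpacingError):
            simulate_recording(EpochSpec(seed=0), duration_s=10, n_events=5,
                               min_gap_s=5)

    def test_noiseless_pipeline_recovers_truth(self):
        """Full extraction on a noise-free recording: D within 0.5% and T
        within one sample of the analytic truth; V and RMS within 1% of a
        filtered-truth oracle (the 10 Hz low-pass attenuates the onset
        velocity transient of the surrogate, so the oracle applies the
        same filter to an independently built clean series)."""
        from copreact.preprocess import FilterSpec, lowpass_zero_phase

        spec = EpochSpec(noise_sd=0.0, seed=21)
        rec, truth = simulate_recording(spec)
        feats = extract_recording_features(rec, CFG)
        assert len(feats) == 3

        # independent filtered-truth oracle on a clean standalone epoch
        fs = spec.fs
        t = np.arange(-5 * fs, 5 * fs + 1) / fs
        clean = lowpass_zero_phase(
            response_curve(t, spec.d_true, spec.tau), FilterSpec(fs=fs)
        )
        w = (t >= -1e-9) & (t <= 0.4 + 1e-9)
        v_oracle = np.gradient(clean[w], 1 / fs, edge_order=2).max()
        rms_oracle = np.sqrt(np.trapezoid(clean[w] ** 2, t[w]) / 0.4)

        for f in feats:
            assert f.d_ml == pytest.approx(spec.d_true, rel=0.005)
            assert f.t_ml == pytest.approx(spec.tau, abs=1 / fs + 1e-12)
            assert f.v_ml == pytest.approx(v_oracle, rel=0.01)
            assert f.rms_ml == pytest.approx(rms_oracle, rel=0.01)
            assert f.d_ap == pytest.approx(spec.kappa_ap * spec.d_true, rel=0.005)

    def test_direction_metadata_matches_injected_sign(self):
        rec, truth = simulate_recording(EpochSpec(noise_sd=0.0, seed=33))
        for ev, d in zip(truth["events"], rec.perturbation_direction):
            assert ev["direction"] == d
            # the raw ML excursion at the peak has the injected sign
            peak = rec.cop_ml[ev["onset_sample"] + 15]  # tau = 0.15 s
            assert np.sign(peak) == d

    def test_recovery_error_monotone_in_noise(self):
        """Bias/error of recovered D shrinks as sway noise shrinks."""
        errs = []
        for noise in (4.0, 1.0, 0.0):
            errors = []
            for seed in range(8):
                rec, truth = simulate_recording(EpochSpec(noise_sd=noise,
                                                          seed=500 + seed))
                feats = extract_recording_features(rec, CFG)
                for f in feats:
                    errors.append(abs(f.d_ml - truth["events"][0]["d_true"]))
            errs.append(np.mean(errors))
        assert errs[0] > errs[1] > errs[2]


class TestSimulateTrialTable:
    def test_all_zero_spec_gives_grand_mean(self):
        table, _ = simulate_trial_table(
            TableSpec(grand_mean=7.5, sd_between=0, sd_within=0, seed=0)
        )
        np.testing.assert_allclose(table["value"], 7.5)

    def test_balanced_structure(self):
        table, _ = simulate_trial_table(TableSpec(n_per_group=5, seed=1))
        assert len(table) == 20
        assert table.groupby(["group", "time"]).size().nunique() == 1

    def test_cell_means_converge_to_injected_effects(self):
        spec = TableSpec(n_per_group=10_000, grand_mean=10, effect_group=2,
                         effect_time=-1.5, effect_interaction=1, seed=3)
        table, truth = simulate_trial_table(spec)
        cells = table.groupby(["group", "time"])["value"].mean()
        for (g, t), mu in cells.items():
            expected = truth["cell_means"][f"{g}/{t}"]
            assert mu == pytest.approx(expected, rel=0.02)
        # marginal contrasts recover the effect definitions
        wide = table.pivot_table(index=["group", "participant"], columns="time",
                                 values="value")
        d = wide["post"] - wide["pre"]
        assert d.mean() == pytest.approx(spec.effect_time, abs=0.05)
        gdiff = d.groupby(level="group").mean()
        assert gdiff["WBED"] - gdiff["Sham"] == pytest.approx(
            spec.effect_interaction, abs=0.1
        )

    def test_seed_determinism(self):
        a, _ = simulate_trial_table(TableSpec(seed=5))
        b, _ = simulate_trial_table(TableSpec(seed=5))
        assert a.equals(b)


class TestSimulateStudy:
    def test_structure_and_determinism(self):
        recs, truth = simulate_study(StudySpec(n_per_group=2, duration_s=20,
                                               seed=4))
        assert len(recs) == 8  # 2 groups x 2 participants x 2 sessions
        assert {r.group for r in recs} == {"WBED", "Sham"}
        recs2, _ = simulate_study(StudySpec(n_per_group=2, duration_s=20, seed=4))
        np.testing.assert_array_equal(recs[0].cop_ml, recs2[0].cop_ml)

    def test_post_only_delta_hits_wbed_post_cell(self):
        _, truth = simulate_study(
            StudySpec(n_per_group=4, duration_s=20, sd_between=0, sd_session=0,
                      wbed_post_delta=-3.0, seed=6)
        )
        for p in truth["participants"]:
            if p["group"] == "WBED":
                assert p["d_true"]["post"] == pytest.approx(p["d_true"]["pre"] - 3.0)
            else:
                assert p["d_true"]["post"] == pytest.approx(p["d_true"]["pre"])
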