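import numpy as np
import pytest

import blockdecode as bd
from blockdecode.synth import (
    AVAST_TR_VALUES,
    AVAST_TR_COUNTS,
    HRFParams,
    draw_avast_tr,
    task_regressor,
)


class TestHRF:
    def test_vanishes_at_zero_and_peaks_at_one(self):
        assert bd.hrf(0.0) == 0.0
        grid = np.arange(0, 30, 0.01)
        vals = bd.hrf(grid)
        assert abs(vals.max() - 1.0) < 1e-9

    def test_peak_location_physiological(self):
        grid = np.arange(0, 30, 0.01)
        assert 4.0 <= grid[np.argmax(bd.hrf(grid))] <= 7.0

    def test_undershoot_present(self):
        late = bd.hrf(np.arange(12, 25, 0.1))
        assert late.min() < 0

    def test_invalid_shape_raises(self):
        with pytest.raises(ValueError):
            HRFParams(peak_shape=0.5)
        with pytest.raises(ValueError):
            bd.hrf(-1.0)


class TestGenerateRun:
    @pytest.mark.parametrize(
        "modality,tr,expect_frames",
        [("bold", 2.0, 150), ("asl", 4.0, 75), ("avast", 1.9, 157)],
    )
    def test_frame_counts_match_run_duration(
        self, paradigm, small_params, modality, tr, expect_frames
    ):
        r = bd.generate_run(modality, paradigm, small_params, 0, tr=tr)
        assert r.n_frames == expect_frames
        np.testing.assert_allclose(r.frame_times, np.arange(expect_frames) * tr)

    def test_roles(self, paradigm, small_params):
        r = bd.generate_run("asl", paradigm, small_params, 0)
        assert r.frame_roles[0] == "control"
        assert set(r.frame_roles[::2]) == {"control"}
        assert set(r.frame_roles[1::2]) == {"tag"}
        b = bd.generate_run("bold", paradigm, small_params, 0)
        assert set(b.frame_roles) == {"plain"}

    def test_unknown_modality_raises(self, paradigm, small_params):
        with pytest.raises(ValueError):
            bd.generate_run("pet", paradigm, small_params, 0)

    def test_seed_determinism(self, paradigm, small_params):
        a = bd.generate_run("bold", paradigm, small_params, 5)
        b = bd.generate_run("bold", paradigm, small_params, 5)
        c = bd.generate_run("bold", paradigm, small_params, 6)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_zero_cnr_roi_indistinguishable_from_background(
        self, paradigm, small_grid
    ):
        """With no signal injected, ROI and in-brain background time course
        means agree within 3 SE over seeds."""
        s = bd.SynthParams(
            grid=small_grid, cnr={"bold": 0.0, "asl": 0.0, "avast": 0.0}
        )
        roi = s.roi_mask()
        bg = s.brain_mask_true() & ~roi
        diffs = []
        for seed in range(50):
            r = bd.generate_run("bold", paradigm, s, seed)
            diffs.append(r.data[:, roi].mean() - r.data[:, bg].mean())
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-12

    def test_generator_linear_in_cnr(self, paradigm, small_grid):
        """Doubling CNR doubles the injected task-rest signal difference
        (identical seeds cancel the noise exactly)."""

        def run(cnr):
            s = bd.SynthParams(
                grid=small_grid, cnr={"bold": cnr, "asl": cnr, "avast": cnr}
            )
            return bd.generate_run("asl", paradigm, s, 7)

        base, one, two = run(0.0), run(1.0), run(2.0)
        sig1 = one.data - base.data
        sig2 = two.data - base.data
        np.testing.assert_allclose(sig2, 2 * sig1, atol=1e-10)

    def test_white_noise_when_ar_disabled(self, paradigm, small_grid):
        s = bd.SynthParams(
            grid=small_grid,
            cnr={"bold": 0.0, "asl": 0.0, "avast": 0.0},
            ar1_coeff=0.0,
            drift_slope={"bold": 0.0, "asl": 0.0, "avast": 0.0},
        )
        r = bd.generate_run("bold", paradigm, s, 3)
        x = r.data[:, 2, 2, 1]  # an out-of-brain voxel: pure noise
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(lag1) < 3 / np.sqrt(r.n_frames)

    def test_ar1_induces_positive_autocorrelation(self, paradigm, small_grid):
        s = bd.SynthParams(
            grid=small_grid,
            cnr={"bold": 0.0, "asl": 0.0, "avast": 0.0},
            ar1_coeff=0.6,
        )
        r = bd.generate_run("bold", paradigm, s, 3)
        x = r.data[:, 2, 2, 1]
        assert np.corrcoef(x[:-1], x[1:])[0, 1] > 0.3

    def test_control_minus_tag_recovers_tagging_offset(self, paradigm, small_grid):
        """At rest (no activation), mean control - mean tag ~ tag_delta."""
        s = bd.SynthParams(
            grid=small_grid, cnr={"bold": 0.0, "asl": 0.0, "avast": 0.0}
        )
        roi = s.brain_mask_true()
        diffs = []
        for seed in range(20):
            r = bd.generate_run("asl", paradigm, s, seed)
            ctrl = r.data[r.frame_roles == "control"][:, roi].mean()
            tag = r.data[r.frame_roles == "tag"][:, roi].mean()
            diffs.append(ctrl - tag)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - s.tag_delta) < 3 * se + 1e-12


class TestGenerateSubject:
    def test_six_runs_with_shared_signal(self, small_subject):
        assert set(small_subject.runs) == {"bold", "asl", "avast"}
        for mod, (r1, r2) in small_subject.runs.items():
            assert r1.n_frames == r2.n_frames
            assert not np.array_equal(r1.data, r2.data)  # independent noise

    def test_runs_differ_only_in_noise(self, paradigm, small_params):
        """Same geometry/signal: run1 - run2 of a zero-noise subject is 0."""
        s = bd.SynthParams(grid=small_params.grid, noise_sd=0.0, ar1_coeff=0.0)
        subj = bd.generate_subject(s, 11, paradigm)
        for r1, r2 in subj.runs.values():
            np.testing.assert_array_equal(r1.data, r2.data)

    def test_roi_inside_brain(self, small_subject):
        assert np.all(small_subject.brain_mask[small_subject.roi_mask])

    def test_avast_tr_matches_tailored_table(self):
        rng = np.random.default_rng(0)
        draws = np.array([draw_avast_tr(rng) for _ in range(4000)])
        assert set(np.unique(draws)) <= set(AVAST_TR_VALUES)
        freqs = np.array([(draws == v).mean() for v in AVAST_TR_VALUES])
        np.testing.assert_allclose(freqs, AVAST_TR_COUNTS / 10, atol=0.03)

    def test_subject_determinism(self, paradigm, small_params, small_subject):
        again = bd.generate_subject(small_params, 42, paradigm)
        for mod in small_subject.runs:
            np.testing.assert_array_equal(
                small_subject.runs[mod][0].data, again.runs[mod][0].data
            )
        assert again.avast_tr == small_subject.avast_tr


class TestTaskRegressor:
    def test_tracks_blocks_with_lag(self, paradigm):
        t = np.arange(0, 300, 1.0)
        h = task_regressor(paradigm, t)
        assert abs(h.max() - 1.0) < 1e-9
        assert h[0] == 0.0
        # mid-task plateau high, late-rest low
        assert h[20] > 0.8 and h[55] < 0.3

    def test_roi_params_validation(self, small_grid):
        with pytest.raises(ValueError):
            bd.SynthParams(grid=small_grid, ar1_coeff=1.5)
        with pytest.raises(ValueError):
            bd.SynthParams(
                grid=small_grid, cnr={"bold": -1.0, "asl": 0.5, "avast": 0.5}
            )
        with pytest.raises(ValueError):
            bd.SynthParams(
                grid=small_grid,
                rois={
                    "bad": bd.Ellipsoid(center=(0, 0, 0), radii=(3, 3, 2))
                },
            )
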