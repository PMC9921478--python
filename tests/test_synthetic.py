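import numpy as np
import pandas as pd
import pytest

from gaitstab import (ConditionSpec, DegradationSpec, StabilityParams,
                      StudySpec, condition_presets, degrade_trial,
                      generate_reference_trial, generate_study)
from gaitstab.study import analyze_trial_pair
from gaitstab.synthetic import generate_study as _generate_study


def _zero_sd_spec(**overrides):
    base = dict(condition="normal", step_length=0.65, step_length_sd=0.0,
                step_width=0.15, step_width_sd=0.0, stride_time=1.2,
                stride_time_sd=0.0, sway_amplitude=0.02,
                sway_variability=0.0, n_strides=10, noise_sd=0.0)
    base.update(overrides)
    return ConditionSpec(**base)


class TestReferenceTrial:
    def test_seed_determinism(self):
        spec = condition_presets(n_strides=12)["normal"]
        t1, g1 = generate_reference_trial(spec, seed=5)
        t2, g2 = generate_reference_trial(spec, seed=5)
        assert np.array_equal(t1.com, t2.com)
        for k in t1.landmarks:
            assert np.array_equal(t1.landmarks[k], t2.landmarks[k])
        pd.testing.assert_frame_equal(g1.steps, g2.steps)

    def test_zero_spread_gives_exact_means(self):
        _, gt = generate_reference_trial(_zero_sd_spec(), seed=3)
        assert np.allclose(gt.steps["step_length_m"], 0.65, atol=1e-12)
        assert np.allclose(gt.steps["step_width_m"], 0.15, atol=1e-12)

    def test_step_width_sample_mean_within_monte_carlo_error(self):
        spec = condition_presets(n_strides=200)["normal"]
        _, gt = generate_reference_trial(spec, seed=21)
        w = gt.steps["step_width_m"].to_numpy()
        se = spec.step_width_sd / np.sqrt(w.size)
        assert abs(w.mean() - spec.step_width) < 3 * se + 1e-9

    def test_ground_truth_brackets_n_strides_per_foot(self):
        spec = condition_presets(n_strides=17)["tandem"]
        _, gt = generate_reference_trial(spec, seed=2)
        for side in ("left", "right"):
            hs = gt.events[side]["heel_strikes"]
            assert hs.size - 1 == 17
            assert np.all(np.diff(hs) > 0)

    def test_normal_dimensionless_step_length_plausible(self, normal_trial):
        _, gt = normal_trial
        mean_len = gt.strides["step_length"].mean()
        assert 0.5 < mean_len < 0.9

    def test_large_sway_emits_warning(self):
        spec = _zero_sd_spec(sway_amplitude=0.2, step_width=0.1)
        with pytest.warns(UserWarning, match="sway"):
            generate_reference_trial(spec, seed=0)


class TestDegradeTrial:
    def test_all_zero_spec_is_identity(self, normal_trial):
        traj, _ = normal_trial
        out = degrade_trial(traj, DegradationSpec.none(rate=traj.rate),
                            seed=0)
        assert np.array_equal(out.com, traj.com)
        for k in traj.landmarks:
            assert np.array_equal(out.landmarks[k], traj.landmarks[k])
        assert out.system == "degraded"

    def test_seed_determinism(self, normal_trial):
        traj, _ = normal_trial
        spec = DegradationSpec()
        a = degrade_trial(traj, spec, seed=9)
        b = degrade_trial(traj, spec, seed=9)
        assert np.array_equal(a.com, b.com)
        for k in a.landmarks:
            assert np.array_equal(a.landmarks[k], b.landmarks[k])

    def test_input_unchanged(self, normal_trial):
        traj, _ = normal_trial
        before = traj.com.copy()
        degrade_trial(traj, DegradationSpec(), seed=1)
        assert np.array_equal(traj.com, before)

    def test_right_foot_ml_bias_shifts_step_width(self, normal_trial, params):
        """A +0.02 m ML bias of the right foot widens every measured step by
        0.02 m: the right foot moves laterally outward on right steps and
        the reference (other) foot moves outward on left steps."""
        traj, _ = normal_trial
        spec = DegradationSpec.none(rate=traj.rate)
        spec.foot_bias = {"right": (0.0, 0.02, 0.0)}
        deg = degrade_trial(traj, spec, seed=0)
        paired = analyze_trial_pair(traj, deg, params)
        shift = (paired["step_width_degraded"]
                 - paired["step_width_reference"])
        assert shift.mean() == pytest.approx(0.02 / params.leg_length,
                                             abs=0.003)

    def test_scale_error_scales_step_measures(self, normal_trial, params):
        """The odometry-like scale error multiplies step width by 1+scale_ml
        and step length by 1+scale_ap (verified through the full pipeline)."""
        traj, _ = normal_trial
        spec = DegradationSpec.none(rate=120.0)
        deg = degrade_trial(traj, spec, seed=0, scale_ml=-0.25,
                            scale_ap=0.04)
        paired = analyze_trial_pair(traj, deg, params)
        width_ratio = (paired["step_width_degraded"]
                       / paired["step_width_reference"]).mean()
        len_ratio = (paired["step_length_degraded"]
                     / paired["step_length_reference"]).mean()
        assert width_ratio == pytest.approx(0.75, abs=0.03)
        assert len_ratio == pytest.approx(1.04, abs=0.01)


class TestStudyGeneration:
    def test_minimal_study_has_one_paired_trial(self):
        spec = StudySpec(n_subjects=1, conditions=("normal",),
                         trials_per_condition=1, n_strides=8, seed=3)
        data = generate_study(spec)
        assert len(data.trials) == 1
        rec = data.trials[0]
        assert rec.reference.rate == 100.0
        assert rec.degraded.rate == 120.0

    def test_subjects_draw_distinct_ml_scale_errors(self):
        spec = StudySpec(n_subjects=2, conditions=("normal",),
                         trials_per_condition=1, n_strides=8, seed=1)
        info = generate_study(spec).subject_info
        assert info.loc[0, "scale_ml"] != info.loc[1, "scale_ml"]

    def test_study_determinism(self):
        spec = StudySpec(n_subjects=2, conditions=("normal", "tandem"),
                         trials_per_condition=1, n_strides=8, seed=4)
        a, b = generate_study(spec), generate_study(spec)
        for ra, rb in zip(a.trials, b.trials):
            assert np.array_equal(ra.degraded.com, rb.degraded.com)

    def test_condition_ordering_of_ground_truth_step_width(self):
        """Wide > Normal > Tandem in mean ground-truth step width."""
        spec = StudySpec(n_subjects=6, trials_per_condition=1, n_strides=25,
                         seed=12)
        gt = generate_study(spec).ground_truth()
        means = gt.groupby("condition")["step_width"].mean()
        assert means["wide"] > means["normal"] > means["tandem"]

    def test_per_subject_bias_clusters_in_agreement(self):
        """Each subject's mean between-system step-width difference tracks
        that subject's drawn ML scale error (participant-specific bias)."""
        deg = DegradationSpec(scale_mean_ml=0.0, scale_sd_ml=0.3,
                              scale_mean_ap=0.0, scale_sd_ap=0.0,
                              noise_sd=(0, 0, 0), com_noise_sd=(0, 0, 0),
                              drift_amplitude=0.0)
        spec = StudySpec(n_subjects=4, conditions=("normal",),
                         trials_per_condition=1, n_strides=30,
                         degradation=deg, seed=8)
        data = generate_study(spec)
        info = data.subject_info.set_index("subject")
        for rec in data.trials:
            params = StabilityParams(rec.leg_length)
            paired = analyze_trial_pair(rec.reference, rec.degraded, params)
            bias = (paired["step_width_reference"]
                    - paired["step_width_degraded"]).mean()
            expected = (-info.loc[rec.subject, "scale_ml"]
                        * paired["step_width_reference"].mean())
            assert bias == pytest.approx(expected, abs=0.01)
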