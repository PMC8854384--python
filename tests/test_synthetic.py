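"""Generator behaviour: statistical structure, ground truth, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynet.synthetic import (
    CohortSpec,
    DiffusionSpec,
    GroupSpec,
    StateModel,
    control_like_model,
    demo_cohort_spec,
    dlb_like_model,
    simulate_cohort,
    simulate_expression,
    simulate_motion,
    simulate_sart,
    simulate_subject,
    two_state_partitions,
)
from dynet.preprocess import framewise_displacement


def _one_state(n_regions, within, between, noise, seed=0, n_modules=2):
    part = np.repeat(np.arange(n_modules), n_regions // n_modules)
    return StateModel(
        n_regions=n_regions,
        n_states=1,
        module_partitions=[part],
        within_coupling=within,
        between_coupling=between,
        dwell_mean=5,
        noise_sd=noise,
        seed=seed,
    ), part


class TestSubjectSimulation:
    def test_uncoupled_regions_are_independent(self):
        model, _ = _one_state(20, 0.0, 0.0, 1.0)
        sim = simulate_subject(model, 4000)
        c = np.corrcoef(sim.ts.data)
        off = c[np.triu_indices(20, 1)]
        assert abs(off.mean()) < 0.02
        assert np.abs(off).max() < 0.1

    def test_modular_coupling_matches_analytic_correlation(self):
        # unit-variance signal + noise: population correlation is
        # coupling / (1 + noise_sd^2) within modules
        noise = 0.5
        model, part = _one_state(20, 0.8, 0.0, noise, seed=11)
        sim = simulate_subject(model, 2000)
        c = np.corrcoef(sim.ts.data)
        same = part[:, None] == part[None, :]
        iu = np.triu_indices(20, 1)
        within = c[iu][same[iu]]
        between = c[iu][~same[iu]]
        expected = 0.8 / (1 + noise**2)
        assert within.mean() == pytest.approx(expected, abs=0.05)
        assert abs(between.mean()) < 0.05
        assert within.mean() > between.mean()

    def test_seed_determinism(self):
        model, _ = _one_state(10, 0.5, 0.1, 0.3, seed=42)
        a = simulate_subject(model, 100)
        b = simulate_subject(model, 100)
        np.testing.assert_array_equal(a.ts.data, b.ts.data)
        np.testing.assert_array_equal(a.states, b.states)

    def test_hidden_states_are_returned_and_plausible(self):
        model = dlb_like_model(60, seed=2)
        sim = simulate_subject(model, 500)
        assert sim.states.shape == (500,)
        assert set(np.unique(sim.states)) <= {0, 1}
        runs = np.diff(np.flatnonzero(np.diff(sim.states) != 0))
        # geometric dwell with mean 20: mean run length in a broad band
        assert 8 < runs.mean() < 45

    @given(st.integers(min_value=1, max_value=4), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=10, deadline=None)
    def test_valid_models_always_simulate(self, n_modules, seed):
        n_regions = 4 * n_modules
        part = np.repeat(np.arange(n_modules), 4)
        model = StateModel(n_regions, 1, [part], 0.6, 0.2, 3.0, 0.4, seed=seed)
        sim = simulate_subject(model, 50)
        assert np.all(np.isfinite(sim.ts.data))
        assert sim.ts.data.shape == (n_regions, 50)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(within_coupling=1.2), "within_coupling"),
            (dict(between_coupling=0.9), "exceed"),
            (dict(module_partitions=[np.zeros(5, dtype=int)]), "every region"),
            (dict(dwell_mean=0.2), "dwell_mean"),
        ],
    )
    def test_invalid_models_raise(self, kwargs, match):
        base = dict(
            n_regions=8,
            n_states=1,
            module_partitions=[np.repeat([0, 1], 4)],
            within_coupling=0.6,
            between_coupling=0.2,
            dwell_mean=5,
            noise_sd=0.3,
        )
        base.update(kwargs)
        with pytest.raises(ValueError, match=match):
            StateModel(**base)


class TestCohort:
    def test_bookkeeping(self):
        spec = demo_cohort_spec(n_per_group=5, n_regions=60, n_timepoints=60, seed=0)
        subs = simulate_cohort(spec)
        assert len(subs) == 10
        groups = [s.group for s in subs]
        assert groups.count("control") == 5 and groups.count("dlb") == 5
        for s in subs:
            assert s.sim.ts.data.shape == (60, 60)
            assert s.sex in (0, 1)

    def test_zero_subjects_rejected(self):
        model = control_like_model(60)
        with pytest.raises(ValueError, match="zero subjects"):
            CohortSpec(groups=[GroupSpec("empty", 0, model)])

    def test_master_seed_changes_data_not_shape(self):
        a = simulate_cohort(demo_cohort_spec(2, 60, 60, seed=0))
        b = simulate_cohort(demo_cohort_spec(2, 60, 60, seed=1))
        assert [s.subject_id for s in a] == [s.subject_id for s in b]
        assert not np.array_equal(a[0].sim.ts.data, b[0].sim.ts.data)

    def test_dlb_preset_slower_and_less_coupled(self):
        c, d = control_like_model(60), dlb_like_model(60)
        assert d.dwell_mean >= 5 * c.dwell_mean
        assert max(d._between_per_state) < min(c._between_per_state)


class TestMotion:
    def test_clean_trace_stays_below_fd_threshold(self):
        mo = simulate_motion(200, seed=0)
        fd = framewise_displacement(mo.motion)
        assert fd.max() < 0.25

    def test_spike_flags_exactly_its_frame(self):
        k = 50
        mo = simulate_motion(200, spike_times=[k], spike_size=1.0, seed=0)
        fd = framewise_displacement(mo.motion)
        assert set(np.flatnonzero(fd > 0.25)) == {k}
        assert np.array_equal(mo.spike_frames, [k])

    def test_single_frame_trace(self):
        mo = simulate_motion(1, seed=0)
        assert framewise_displacement(mo.motion).tolist() == [0.0]

    def test_invalid_spikes_raise(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_motion(100, spike_times=[5], spike_size=-1.0)
        with pytest.raises(ValueError, match="indices"):
            simulate_motion(100, spike_times=[100], spike_size=1.0)


class TestSart:
    def test_zero_drift_is_symmetric(self):
        res = simulate_sart(DiffusionSpec(0.0, 0.12, 0.2, n_trials=10000, seed=5))
        acc = res.trials["correct"].mean()
        # binomial 3-sigma band around 0.5 at n=10,000
        assert abs(acc - 0.5) < 0.015

    def test_higher_drift_faster_and_more_accurate(self):
        lo = simulate_sart(DiffusionSpec(0.1, 0.12, 0.3, n_trials=10000, seed=1))
        hi = simulate_sart(DiffusionSpec(0.3, 0.12, 0.3, n_trials=10000, seed=1))
        assert hi.trials["correct"].mean() > lo.trials["correct"].mean()
        assert hi.trials["rt"].mean() < lo.trials["rt"].mean()

    def test_nondecision_shifts_rt_exactly(self):
        a = simulate_sart(DiffusionSpec(0.2, 0.12, 0.0, n_trials=500, seed=3))
        b = simulate_sart(DiffusionSpec(0.2, 0.12, 0.3, n_trials=500, seed=3))
        assert b.trials["rt"].mean() == pytest.approx(a.trials["rt"].mean() + 0.3)

    def test_all_omitted_raises(self):
        with pytest.raises(ValueError, match="max_rt"):
            simulate_sart(DiffusionSpec(0.0, 1.0, 0.0, n_trials=20, max_rt=0.01, seed=0))


class TestExpression:
    def test_rho_one_is_monotone_transform(self, rng):
        target = rng.standard_normal(100)
        out = simulate_expression(100, 5, planted=(target, 1.0), seed=0)
        from scipy.stats import spearmanr

        assert spearmanr(out.expression["PLANTED"], target).statistic == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_rho_realised_within_band(self, seed, rng):
        target = rng.standard_normal(333)
        out = simulate_expression(333, 20, planted=(target, 0.6), seed=seed)
        assert 0.55 <= out.realised_rho <= 0.65

    def test_target_length_mismatch(self):
        with pytest.raises(ValueError, match="n_regions"):
            simulate_expression(50, 5, planted=(np.zeros(40), 0.5))

    def test_background_is_standardised_smooth_field(self):
        out = simulate_expression(200, 3, seed=4)
        assert out.planted_gene is None
        for g in out.expression.columns:
            v = out.expression[g].to_numpy()
            assert v.std() == pytest.approx(1.0, abs=1e-6)
            # smoothness: lag-1 autocorrelation is high
            assert np.corrcoef(v[:-1], v[1:])[0, 1] > 0.8
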