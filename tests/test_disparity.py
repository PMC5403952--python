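"""Network arrangement, training gates, closeness and sub-phase errors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cyclogait as cg
from cyclogait.disparity import (
    DisparityModel,
    arrange,
    closeness,
    subphase_errors,
    worst_pair_table,
)
from cyclogait.gaitdata import GaitDataError
from cyclogait.report import subject_closeness


@pytest.fixture(scope="module")
def pair_kp(pairs):
    return next(
        p
        for p in pairs
        if p.var_a == ("knee", "angle") and p.var_b == ("knee", "power")
    )


@pytest.fixture(scope="module")
def subject_trials(normal_cohort):
    by = {}
    for t in normal_cohort:
        by.setdefault(t.subject_id, []).append(t)
    return next(iter(by.values()))


class TestArrange:
    def test_shapes_and_labels(self, subject_trials, pair_kp, reference):
        arr = arrange(subject_trials, pair_kp, reference)
        assert arr.inputs.shape == (30, 50)
        assert arr.targets.shape == (3, 50)
        assert set(np.unique(arr.inputs[20:])) <= set(range(1, 8))
        assert set(np.unique(arr.targets[2])) <= set(range(1, 8))

    def test_row_layout(self, subject_trials, pair_kp, reference):
        arr = arrange(subject_trials, pair_kp, reference)
        for i, trial in enumerate(subject_trials):
            assert np.array_equal(arr.inputs[i], trial.series[pair_kp.var_a])
            assert np.array_equal(arr.inputs[10 + i], trial.series[pair_kp.var_b])
            assert np.array_equal(arr.inputs[20 + i], trial.subphase)

    def test_zero_noise_rows_equal_targets(self, zero_noise_profile, bank, pair_kp):
        trials = cg.generate_cohort(zero_noise_profile, bank, 1, 10, seed=0)
        ref = cg.average_reference(trials)
        arr = arrange(trials, pair_kp, ref)
        for i in range(10):
            assert np.allclose(arr.inputs[i], arr.targets[0], atol=1e-12)

    def test_wrong_arity(self, subject_trials, pair_kp, reference):
        with pytest.raises(GaitDataError, match="10"):
            arrange(subject_trials[:7], pair_kp, reference)

    def test_short_subject_resampled_and_flagged(
        self, subject_trials, pair_kp, reference
    ):
        arr = arrange(
            subject_trials[:6], pair_kp, reference, allow_resample=True, seed=1
        )
        assert arr.resampled
        assert arr.inputs.shape == (30, 50)

    def test_mixed_subjects_rejected(self, normal_cohort, pair_kp, reference):
        with pytest.raises(GaitDataError, match="one subject"):
            arrange(normal_cohort[5:15], pair_kp, reference)


class TestCloseness:
    def test_identical_curves_give_100(self):
        curves = np.random.default_rng(0).normal(size=(2, 50))
        score = closeness(curves, curves, ranges=[1.0, 2.0])
        assert score.C == 100.0 and score.e_pc == 0.0

    def test_full_range_error_gives_0(self):
        target = np.zeros((2, 50))
        predicted = np.vstack([np.full(50, 3.0), np.full(50, 5.0)])
        score = closeness(predicted, target, ranges=[3.0, 5.0])
        assert score.e_pc == 1.0 and score.C == 0.0

    def test_half_points_off_by_one_range(self):
        target = np.zeros((2, 50))
        predicted = np.zeros((2, 50))
        predicted[:, :25] = 1.0
        score = closeness(predicted, target, ranges=[1.0, 1.0])
        assert score.C == pytest.approx(50.0)

    def test_zero_range_rejected(self):
        with pytest.raises(GaitDataError):
            closeness(np.zeros((2, 50)), np.zeros((2, 50)), ranges=[1.0, 0.0])

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 1), st.floats(0.1, 10))
    def test_affine_in_epc_and_bounded(self, frac, rng_val):
        """C = (1 - e_pc) * 100 exactly, and C always lies in [0, 100]."""
        target = np.zeros((2, 50))
        predicted = np.full((2, 50), frac * rng_val)
        score = closeness(predicted, target, ranges=[rng_val, rng_val])
        assert score.C == pytest.approx((1 - score.e_pc) * 100.0)
        assert 0.0 <= score.C <= 100.0
        assert score.e_pc == pytest.approx(min(frac, 1.0), abs=1e-12)


class TestSubphaseErrors:
    def test_zero_for_identical(self, reference):
        curves = np.zeros((2, 50))
        errs = subphase_errors(curves, curves, reference.subphase, [1.0, 1.0])
        assert np.allclose(errs, 0.0)

    def test_error_locality(self, reference):
        labels = reference.subphase
        target = np.zeros((2, 50))
        predicted = np.zeros((2, 50))
        predicted[0, labels == 1] = 0.5  # perturb LR samples only
        errs = subphase_errors(predicted, target, labels, [1.0, 1.0])
        assert errs[0] > 0
        assert np.allclose(errs[1:], 0.0)

    def test_matches_brute_force_oracle(self, reference):
        rng = np.random.default_rng(3)
        predicted = rng.normal(size=(2, 50))
        target = rng.normal(size=(2, 50))
        ranges = [1.3, 0.7]
        labels = reference.subphase
        errs = subphase_errors(predicted, target, labels, ranges)
        for phase in range(1, 8):
            acc = []
            for row in range(2):
                for s in range(50):
                    if labels[s] == phase:
                        acc.append(abs(predicted[row, s] - target[row, s]) / ranges[row])
            assert abs(errs[phase - 1] - np.mean(acc)) < 1e-12

    def test_missing_phase_is_nan(self):
        labels = np.r_[np.full(25, 1), np.full(25, 2)]
        errs = subphase_errors(np.zeros((2, 50)), np.zeros((2, 50)), labels, [1, 1])
        assert np.isnan(errs[2:]).all() and not np.isnan(errs[:2]).any()

    def test_consistency_with_global_epc(self, reference):
        """Count-weighted per-phase errors recompose the global e_pc."""
        rng = np.random.default_rng(5)
        target = np.zeros((2, 50))
        predicted = rng.uniform(-0.5, 0.5, size=(2, 50))  # below clip level
        labels = reference.subphase
        errs = subphase_errors(predicted, target, labels, [1.0, 1.0])
        counts = np.array([(labels == p).sum() for p in range(1, 8)])
        total = np.nansum(errs * counts * 2)
        e_pc = closeness(predicted, target, [1.0, 1.0]).e_pc
        assert total == pytest.approx(50 * 2 * e_pc, abs=1e-12)


class TestTraining:
    def test_accepted_on_synthetic_normal(self, networks):
        res = next(iter(networks.values()))
        rep = res.report
        assert rep.accepted
        assert rep.final_mse < 0.9
        assert min(rep.r_train, rep.r_val, rep.r_test) > 0.9
        assert rep.n_restarts_used <= 10
        assert sum(rep.split_sizes) == 250  # 5 subjects x 50 columns

    def test_all_36_pairs_accepted(self, networks):
        assert len(networks) == 36
        assert all(r.report.accepted for r in networks.values())

    def test_fit_is_deterministic_for_seed(self, normal_cohort, reference, pair_kp):
        m = DisparityModel.from_trials(normal_cohort, pair_kp, reference)
        r1, r2 = m.fit(seed=13), m.fit(seed=13)
        for w1, w2 in zip(r1.weights, r2.weights):
            assert np.array_equal(w1, w2)

    @pytest.mark.parametrize("pair_index", [0, 9, 18, 27])
    def test_matches_least_squares_map(
        self, networks, pairs, pair_index
    ):
        """Linear 30-7-3 net composes to one affine map; a converged fit
        must agree with closed-form least squares on its training columns."""
        res = networks[pairs[pair_index]]
        X, Y = res.model._X, res.model._Y
        ti = res.train_columns
        Xt = np.vstack([X[:, ti], np.ones(len(ti))])
        coef, *_ = np.linalg.lstsq(Xt.T, Y[:, ti].T, rcond=None)
        pred_ols = coef.T @ Xt
        A, c = res.equivalent_linear_map()
        pred_net = A @ X[:, ti] + c[:, None]
        assert np.abs(pred_net - pred_ols).max() < 1e-3

    def test_summary_mentions_criteria(self, networks):
        text = next(iter(networks.values())).summary()
        assert "30-7-3" in text and "MSE" in text and "regression R" in text

    def test_json_round_trip(self, networks, pairs, tmp_path):
        res = networks[pairs[0]]
        res.to_json(tmp_path / "net.json")
        back = cg.DisparityResults.from_json(tmp_path / "net.json")
        assert back.pair == res.pair
        assert back.report.accepted == res.report.accepted
        for w1, w2 in zip(back.weights, res.weights):
            assert np.allclose(w1, w2, atol=1e-12)


class TestSimulate:
    def test_in_sample_epc_small(self, networks, pairs, subject_trials, reference):
        res = networks[pairs[0]]
        score = res.closeness(subject_trials, reference)
        # training subject through its own converged network
        assert score.e_pc < np.sqrt(res.report.final_mse) + 0.05

    def test_zero_weight_network_outputs_biases(
        self, networks, pairs, subject_trials, reference
    ):
        res = networks[pairs[0]]
        zeroed = cg.DisparityResults(
            model=res.model,
            pair=res.pair,
            weights=[np.zeros_like(w) for w in res.weights],
            report=res.report,
            train_columns=res.train_columns,
        )
        pred, arr = zeroed.simulate(subject_trials, reference)
        # all-zero weights and biases -> scaled output 0 -> unscaled minimum
        assert np.allclose(pred[0], arr.a_min)
        assert np.allclose(pred[1], arr.b_min)

    def test_pair_mismatch_rejected(self, networks, pairs, subject_trials, reference):
        res = networks[pairs[0]]
        arr = arrange(subject_trials, pairs[1], reference)
        with pytest.raises(GaitDataError, match="pair"):
            res.predict_arrangement(arr)

    def test_pathological_scores_below_normal(
        self, networks, reference, profiles, bank
    ):
        """Same network ranks a transfemoral subject further from normal."""
        wins = 0
        for seed in range(10):
            nrm = cg.generate_cohort(
                profiles["normal"], bank, 1, 10, 20_000 + seed, subject_prefix="HN"
            )
            tf = cg.generate_cohort(
                profiles["transfemoral"], bank, 1, 10, 30_000 + seed
            )
            wins += subject_closeness(tf, networks, reference) < subject_closeness(
                nrm, networks, reference
            )
        assert wins >= 9

    def test_cohort_median_ordering(self, networks, reference, profiles, bank):
        """Median closeness: normal > orthosis > transtibial > transfemoral."""
        medians = {}
        for cohort in ("normal", "orthosis", "transtibial", "transfemoral"):
            trials = cg.generate_cohort(
                profiles[cohort], bank, 10, 10, 40_000, subject_prefix=f"X{cohort[:2]}"
            )
            by = {}
            for t in trials:
                by.setdefault(t.subject_id, []).append(t)
            medians[cohort] = np.median(
                [subject_closeness(v, networks, reference) for v in by.values()]
            )
        assert (
            medians["normal"]
            > medians["orthosis"]
            > medians["transtibial"]
            > medians["transfemoral"]
        )


class TestWorstPairTable:
    def test_planted_deficit_recovered(
        self, networks, reference, planted_subject_factory
    ):
        hits = 0
        for seed in range(10):
            subj = planted_subject_factory(10_000 + seed)
            table = worst_pair_table(subj, networks, reference)
            hits += table.argmax_pair(1).contains(("knee", "power"))
        assert hits >= 9

    def test_normal_subject_stays_in_normal_band(
        self, networks, reference, profiles, bank
    ):
        subj = cg.generate_cohort(
            profiles["normal"], bank, 1, 10, 77, subject_prefix="HN"
        )
        table = worst_pair_table(subj, networks, reference)
        assert np.nanmax(table.errors) < 10.0  # percent

    def test_deterministic_tie_break_takes_first_canonical(
        self, networks, pairs, one_trial
    ):
        """Row-averaging networks reproduce an identical-trial subject's
        targets bit-exactly, so every pair ties at exactly zero error and
        the first pair in canonical order must be selected per sub-phase."""
        # series rescaled exactly onto [0, 1] so range-normalization is the
        # identity; reference over 8 identical trials (power-of-two mean)
        base = one_trial.copy()
        for key in cg.VARKEYS:
            v = base.series[key]
            v = (v - v.min()) / (v.max() - v.min())
            # quantize to 1/64 steps so averaging identical trials is exact
            base.series[key] = np.round(v * 64) / 64
        trials = [base.copy() for _ in range(10)]
        ref = cg.average_reference(trials[:8])
        # exact projection: output o copies its first trial row verbatim
        W1 = np.zeros((7, 30))
        for o in range(3):
            W1[o, 10 * o] = 1.0
        W2 = np.zeros((3, 7))
        W2[:3, :3] = np.eye(3)
        averaging = {
            p: cg.DisparityResults(
                model=networks[p].model,
                pair=p,
                weights=[W1, np.zeros(7), W2, np.zeros(3)],
                report=networks[p].report,
                train_columns=networks[p].train_columns,
            )
            for p in pairs[:4]
        }
        table = worst_pair_table(trials, averaging, ref)
        assert np.all(table.errors == 0.0)
        assert all(table.argmax[phase] == 0 for phase in range(1, 8))

    def test_failed_network_excluded_with_warning(
        self, networks, pairs, subject_trials, reference
    ):
        import dataclasses

        res = networks[pairs[0]]
        bad_report = dataclasses.replace(res.report, accepted=False)
        bad = cg.DisparityResults(
            model=res.model,
            pair=res.pair,
            weights=res.weights,
            report=bad_report,
            train_columns=res.train_columns,
        )
        nets = {pairs[0]: bad, pairs[1]: networks[pairs[1]]}
        with pytest.warns(UserWarning, match="unaccepted"):
            table = worst_pair_table(subject_trials, nets, reference)
        assert bad.pair in table.excluded
        assert np.isnan(table.errors[0]).all()

    def test_table_frame_has_argmax_flags(self, networks, subject_trials, reference):
        table = worst_pair_table(subject_trials, networks, reference)
        frame = table.to_frame()
        assert frame.is_argmax.sum() == len(table.argmax)
        assert set(frame.subphase.unique()) == set(range(1, 8))


def test_monotone_deficit_increases_downstream_error(
    networks, reference, bank, pairs
):
    """Stronger planted attenuation -> larger mean normalized error on
    pairs containing the attenuated variable (3 levels, fixed seeds)."""
    kp_pairs = [p for p in pairs if p.contains(("knee", "power"))]
    means = []
    for scale in (0.8, 0.5, 0.2):
        scales = np.ones(7)
        scales[:] = scale
        profile = cg.CohortProfile(
            cohort="transfemoral",
            amplitude_scale={("knee", "power"): scales},
            trial_noise_sd=0.02,
            subject_offset_sd=0.02,
        )
        subj = cg.generate_cohort(profile, bank, 1, 10, 123)
        errs = [
            np.nanmean(networks[p].subphase_errors(subj, reference))
            for p in kp_pairs
        ]
        means.append(np.mean(errs))
    assert means[0] < means[1] < means[2]
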