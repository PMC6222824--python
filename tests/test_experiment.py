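import numpy as np
import pytest

from infomaxpf import (
    ExperimentConfig,
    ModelParams,
    choice_probabilities,
    make_fixture_observer,
    pf_mse,
    posterior_entropy,
    run_closed_loop,
    run_reordering,
    sample_response,
)
from infomaxpf.experiment import init_indices, run_seeds
from infomaxpf.laplace import GaussianPosterior
from infomaxpf.mcmc import SampleSet
from infomaxpf.model import ParamLayout

from conftest import simulate_dataset


class TestSampleResponse:
    def test_near_deterministic_observer(self):
        params = ModelParams(
            weights=np.array([[0.0, 50.0], [0.0, 0.0]]), lapse_mode="none"
        )
        from infomaxpf import TrueObserver

        obs = TrueObserver(params=params, seed=0)
        draws = [sample_response(obs, np.array([1.0, 1.0])) for _ in range(500)]
        assert all(d == 0 for d in draws)

    def test_uniform_probabilities_give_uniform_frequencies(self):
        layout = ParamLayout(4, 2, "none")
        from infomaxpf import TrueObserver

        obs = TrueObserver(params=layout.default_params(), seed=1)
        n = 10_000
        draws = np.array(
            [sample_response(obs, np.array([1.0, 0.0])) for _ in range(n)]
        )
        freqs = np.bincount(draws, minlength=4) / n
        sigma = np.sqrt(0.25 * 0.75 / n)
        np.testing.assert_allclose(freqs, 0.25, atol=3 * sigma)

    def test_fixed_seed_reproduces_sequence(self):
        from infomaxpf import TrueObserver

        layout = ParamLayout(3, 2, "none")
        seqs = []
        for _ in range(2):
            obs = TrueObserver(params=layout.default_params(), seed=5)
            seqs.append(
                [sample_response(obs, np.array([1.0, 0.4])) for _ in range(50)]
            )
        assert seqs[0] == seqs[1]


class TestMetrics:
    def test_pf_mse_zero_for_exact_estimate(self):
        observer, space = make_fixture_observer("fig5_fourchoice")
        assert pf_mse(observer.params, observer.params, space) == 0.0

    def test_pf_mse_uniform_vs_deterministic_truth_closed_form(self):
        observer, space = make_fixture_observer("fig3_binary")
        feats = space.features()
        p_true = choice_probabilities(observer.params, feats).probs
        uniform = np.full_like(p_true, 0.5)
        expected = np.mean((p_true - 0.5) ** 2)
        assert pf_mse(uniform, observer.params, space) == pytest.approx(expected)

    def test_pf_mse_invariant_to_consistent_relabeling(self):
        observer, space = make_fixture_observer("fig5_fourchoice")
        feats = space.features()
        p_true = choice_probabilities(observer.params, feats).probs
        rng = np.random.default_rng(0)
        p_hat = p_true + rng.normal(scale=0.02, size=p_true.shape)
        perm = [2, 0, 3, 1]
        assert pf_mse(p_hat, p_true, space) == pytest.approx(
            pf_mse(p_hat[:, perm], p_true[:, perm], space)
        )

    def test_entropy_closed_form_isotropic(self):
        layout = ParamLayout(3, 2, "none")
        n = 4
        for sigma2 in [0.25, 4.0]:
            post = GaussianPosterior(
                mode=layout.default_params(),
                cov=sigma2 * np.eye(n),
                cov_ww=sigma2 * np.eye(n),
                log_det_cov=n * np.log(sigma2),
            )
            assert posterior_entropy(post) == pytest.approx(
                (n / 2) * np.log(sigma2)
            )

    def test_entropy_shrinks_by_half_n_log4_when_cov_quartered(self):
        layout = ParamLayout(2, 2, "none")
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        mk = lambda c: GaussianPosterior(
            mode=layout.default_params(), cov=c, cov_ww=c,
            log_det_cov=np.linalg.slogdet(c)[1],
        )
        assert posterior_entropy(mk(cov)) - posterior_entropy(
            mk(cov / 4)
        ) == pytest.approx(np.log(4) * 2 / 2)

    def test_sampleset_entropy_matches_gaussian(self):
        rng = np.random.default_rng(0)
        cov = np.array([[1.0, 0.4], [0.4, 0.5]])
        draws = rng.multivariate_normal([0, 0], cov, 20000)
        ss = SampleSet(draws, np.zeros(20000), 1.0, np.eye(2),
                       layout=ParamLayout(2, 2, "none"))
        expected = 0.5 * np.linalg.slogdet(cov)[1]
        assert posterior_entropy(ss) == pytest.approx(expected, abs=0.05)


class TestFixtures:
    def test_fig3_binary_is_centered_logistic(self):
        observer, space = make_fixture_observer("fig3_binary")
        p = choice_probabilities(
            observer.params, np.array([1.0, 0.0])
        ).probs
        assert p[0] == pytest.approx(0.5)
        # slope 2: p(y=1 | x=1) = σ(2)
        p1 = choice_probabilities(observer.params, np.array([1.0, 1.0])).probs
        assert p1[0] == pytest.approx(1 / (1 + np.exp(-2.0)))

    def test_fourchoice_lapse_saturation_bound(self):
        observer, space = make_fixture_observer("fig5_fourchoice", lapse=0.2)
        probs = choice_probabilities(observer.params, space.features()).probs
        assert probs.max() <= 1 - 0.2 + 0.05 + 1e-12

    def test_rotated_boundaries_are_rotations_of_aligned_ones(self):
        aligned, space = make_fixture_observer("fig5_fourchoice")
        rotated, _ = make_fixture_observer("rotated")
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        rot = np.array([[c, -s], [s, c]])
        pts = space.candidates[::7]
        feats_rot = space.features(pts @ rot.T)
        feats = space.features(pts)
        p_aligned = choice_probabilities(aligned.params, feats).probs
        p_rotated = choice_probabilities(rotated.params, feats_rot).probs
        np.testing.assert_allclose(p_aligned, p_rotated, atol=1e-10)

    def test_invalid_kind_and_lapse(self):
        with pytest.raises(ValueError, match="kind"):
            make_fixture_observer("nope")
        with pytest.raises(ValueError, match="lapse"):
            make_fixture_observer("fig3_binary", lapse=0.9)


def test_init_indices_regular_and_within_range():
    idx = init_indices(441, 10)
    assert idx[0] == 0 and idx[-1] == 440
    assert len(idx) == 10
    spacing = np.diff(idx)
    assert spacing.max() - spacing.min() <= 1


class TestClosedLoop:
    def test_uniform_selection_reproducible_and_response_independent(self):
        """With a fixed seed the uniform stimulus sequence is identical
        across runs and does not depend on the observer's responses."""
        observer_a, space = make_fixture_observer("fig3_binary", seed=1)
        observer_b, _ = make_fixture_observer("fig3_binary", seed=99)
        cfg = ExperimentConfig(
            engine="laplace", selection="uniform", n_trials=30, seed=11
        )
        streams = run_seeds(11, 1)[0]
        tr_a = run_closed_loop(observer_a, space, cfg, rng_streams=streams)
        tr_b = run_closed_loop(observer_b, space, cfg, rng_streams=streams)
        np.testing.assert_array_equal(
            tr_a.stimulus_indices, tr_b.stimulus_indices
        )
        tr_a2 = run_closed_loop(observer_a, space, cfg, rng_streams=streams)
        np.testing.assert_array_equal(tr_a.responses, tr_a2.responses)
        np.testing.assert_array_equal(tr_a.mse, tr_a2.mse)

    def test_trace_schema(self):
        observer, space = make_fixture_observer("fig3_binary", seed=2)
        cfg = ExperimentConfig(engine="laplace", n_trials=25, n_init=5, seed=3)
        tr = run_closed_loop(observer, space, cfg)
        assert tr.n_trials == 25
        assert np.isnan(tr.mse[:4]).all()
        assert np.isfinite(tr.mse[4:]).all()
        assert np.isfinite(tr.entropy[4:]).all()
        assert tr.error is None

    def test_lapse_aware_mcmc_visits_easy_periphery_stimuli(self):
        """With a lapsing observer the lapse-aware sampler-based runner
        places some trials in the outer 20% of the grid, where easy trials
        pin down the lapse rate."""
        observer, space = make_fixture_observer(
            "fig5_fourchoice", lapse=0.2, seed=0
        )
        radius = np.linalg.norm(space.candidates, axis=1)
        outer = radius >= np.quantile(radius, 0.8)
        hits = 0
        n_runs = 5
        for streams in run_seeds(202, n_runs):
            cfg = ExperimentConfig(
                engine="mcmc", selection="infomax", lapse_mode="full",
                n_trials=40, mcmc_samples=300, seed=0,
            )
            tr = run_closed_loop(observer, space, cfg, rng_streams=streams)
            assert tr.error is None
            chosen = tr.stimulus_indices[cfg.n_init:]
            if np.any(outer[chosen]):
                hits += 1
        assert hits >= 0.9 * n_runs

    def test_mean_entropy_trace_declines(self):
        """The mean posterior-entropy trace of infomax runs declines
        steadily once past the early trials (small upticks tolerated)."""
        observer, space = make_fixture_observer("fig5_fourchoice", seed=0)
        cfg = ExperimentConfig(
            engine="laplace", selection="infomax", n_trials=60, seed=0
        )
        traces = [
            run_closed_loop(observer, space, cfg, rng_streams=streams).entropy
            for streams in run_seeds(77, 20)
        ]
        mean = np.stack(traces)[:, 9:].mean(axis=0)  # defined from trial 10
        diffs = np.diff(mean[6:])  # i.e. from trial 15 onward
        assert np.all(diffs <= 0.05)
        assert mean[-1] < mean[6]


class TestReordering:
    def _synthetic_pool(self, n_pool=300, seed=0):
        observer, space = make_fixture_observer("fig3_binary", seed=seed)
        rng = np.random.default_rng(seed)
        feats = space.features()
        idx = rng.integers(0, space.n_candidates, n_pool)
        resp = np.array(
            [sample_response(observer, feats[i], rng) for i in idx]
        )
        return observer, space, space.candidates[idx], resp

    def test_single_distinct_stimulus_keeps_recording_order(self):
        observer, space = make_fixture_observer("fig3_binary", seed=1)
        stims = np.tile(space.candidates[7], (40, 1))
        rng = np.random.default_rng(2)
        resp = rng.integers(0, 2, 40)
        cfg = ExperimentConfig(engine="laplace", n_trials=40, seed=0)
        tr = run_reordering(stims, resp, space, cfg)
        np.testing.assert_array_equal(tr.stimulus_indices, np.arange(40))

    def test_selection_never_peeks_at_responses(self):
        """Replacing every response after selection-time with another one
        leaves the selected stimulus order unchanged under fixed seeds —
        responses only enter the posterior after selection."""
        observer, space, stims, resp = self._synthetic_pool(seed=3)
        cfg = ExperimentConfig(engine="laplace", n_trials=60, seed=5)
        streams = run_seeds(5, 1)[0]
        tr = run_reordering(stims, resp, space, cfg, rng_streams=streams)
        # the selected order may *depend* on past responses (they shape the
        # posterior), but the first selection after the init block cannot
        # depend on the response it will reveal
        first_sel = tr.stimulus_indices[cfg.n_init]
        flipped = resp.copy()
        flipped[first_sel] = 1 - flipped[first_sel]
        tr2 = run_reordering(stims, flipped, space, cfg, rng_streams=streams)
        assert tr2.stimulus_indices[cfg.n_init] == first_sel

    def test_reordered_beats_uniform_subsample(self):
        """Mean PF error of the infomax-reordered first 100 trials is no
        worse than a uniform subsample of the same pool."""
        errs = {"infomax": [], "uniform": []}
        for run in range(5):
            observer, space, stims, resp = self._synthetic_pool(seed=10 + run)
            for sel in errs:
                cfg = ExperimentConfig(
                    engine="laplace", selection=sel, n_trials=100, seed=run
                )
                tr = run_reordering(
                    stims, resp, space, cfg,
                    reference=observer.params,
                )
                assert tr.error is None
                errs[sel].append(tr.mse[-1])
        assert np.mean(errs["infomax"]) <= np.mean(errs["uniform"])

    def test_pool_exhaustion_truncates_gracefully(self):
        observer, space, stims, resp = self._synthetic_pool(n_pool=30, seed=4)
        cfg = ExperimentConfig(engine="laplace", n_trials=100, seed=0)
        tr = run_reordering(stims, resp, space, cfg)
        assert tr.n_trials == 30
        assert tr.error is None


def test_full_plane_infomax_beats_axes_only():
    """Selecting from the full 2-D grid achieves lower PF error than
    restricting selection to the cardinal axes, scored on the same grid."""
    from infomaxpf.space import StimulusSpace

    observer, space = make_fixture_observer("rotated", seed=0)
    on_axis = np.isclose(space.candidates[:, 0], 0) | np.isclose(
        space.candidates[:, 1], 0
    )
    axes_space = StimulusSpace(
        candidates=space.candidates[on_axis],
        offset=space.offset,
        scale=space.scale,
    )
    finals = {"full": [], "axes": []}
    for streams in run_seeds(31, 8):
        cfg = ExperimentConfig(engine="laplace", n_trials=100, seed=0)
        tr_full = run_closed_loop(observer, space, cfg, rng_streams=streams)
        tr_axes = run_closed_loop(
            observer, axes_space, cfg, rng_streams=streams, eval_space=space
        )
        finals["full"].append(tr_full.mse[-1])
        finals["axes"].append(tr_axes.mse[-1])
    assert np.mean(finals["full"]) < np.mean(finals["axes"])
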