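"""Exclusion rules, MLE, hierarchical fitting and PSIS-LOO comparison."""

import copy

import numpy as np
import pytest
from scipy.special import logsumexp, ndtri

from problearn import AgentParams, generate_bandit_session, simulate_agent
from problearn.fitting import (
    HierarchicalRW,
    NoFitError,
    apply_exclusions,
    compare_models,
    compute_loo,
    fit_mle,
)
from problearn.models import bandit_arrays, trajectory_loglik
from problearn.tasks import SessionData, TrialRecord


def _session_with_catch(pid, n_catch_correct, n_catch_total, n_exp=4):
    """Hand-built bandit session with a controlled catch-accuracy."""
    trials = []
    idx = 0
    for i in range(n_exp):
        idx += 1
        t = TrialRecord(
            participant_id=pid, task="bandit", trial_index=idx, stimulus_id="pair",
            cue_levels=None, presented_options=("optA", "optB"), outcome="optA",
            correct_response="optA", response="optA", phase="early",
        )
        t.score()
        trials.append(t)
    for i in range(n_catch_total):
        idx += 1
        t = TrialRecord(
            participant_id=pid, task="bandit", trial_index=idx, stimulus_id=None,
            cue_levels=None, presented_options=("optA", "optB"), outcome="optA",
            correct_response="optA",
            response="optA" if i < n_catch_correct else "optB",
            is_catch=True, phase="late",
        )
        t.score()
        trials.append(t)
    return SessionData(pid, "bandit", trials)


class TestExclusions:
    def test_catch_accuracy_below_threshold_excludes_participant(self):
        cohort = [_session_with_catch("bad", 74, 100), _session_with_catch("good", 80, 100)]
        kept, report = apply_exclusions(cohort)
        assert [s.participant_id for s in kept] == ["good"]
        assert "bad" in report["excluded_participants"]
        assert report["excluded_participants"]["bad"] == pytest.approx(0.74)

    def test_exactly_75_percent_is_retained(self):
        cohort = [_session_with_catch("edge", 75, 100)]
        kept, report = apply_exclusions(cohort)
        assert len(kept) == 1
        assert report["n_excluded"] == 0

    def test_clean_cohort_passes_through_unchanged(self):
        cohort = [_session_with_catch("a", 4, 4), _session_with_catch("b", 4, 4)]
        kept, report = apply_exclusions(cohort)
        assert kept == cohort
        assert report["n_excluded"] == 0
        assert all(v == 0 for v in report["timeout_trials_per_participant"].values())

    def test_cohort_without_catch_trials_warns_not_excludes(self):
        s = _session_with_catch("x", 0, 0)
        with pytest.warns(UserWarning, match="catch"):
            kept, _ = apply_exclusions([s])
        assert len(kept) == 1

    def test_timeouts_counted_but_trials_retained(self):
        s = _session_with_catch("x", 4, 4)
        s.trials[0].response = "timeout"
        s.trials[0].score()
        kept, report = apply_exclusions([s])
        assert report["timeout_trials_per_participant"]["x"] == 1
        assert len(kept[0].trials) == len(s.trials)


class TestMLE:
    def test_flat_likelihood_flags_unidentifiable_alpha(self):
        design = generate_bandit_session(seed=1)
        s = simulate_agent(AgentParams(model="simple", alpha=0.5, beta=0.0), design, seed=2)
        f = fit_mle("simple", s, n_restarts=5, seed=0)
        n = len(s.included_trials)
        assert f.loglik == pytest.approx(n * np.log(0.5), abs=1e-8)
        assert not f.alpha_identifiable

    def test_degenerate_session_raises_no_fit_error(self):
        design = generate_bandit_session(seed=3)
        s = simulate_agent(AgentParams(model="simple", alpha=0.5, beta=2.0), design, seed=4)
        for t in s.trials:
            t.response = "timeout"
            t.score()
        with pytest.raises(NoFitError):
            fit_mle("simple", s)

    def test_optimum_matches_grid_search_oracle(self):
        """L-BFGS-B optimum agrees with a 101x101 exhaustive grid within one cell."""
        design = generate_bandit_session(seed=5)
        s = simulate_agent(AgentParams(model="simple", alpha=0.4, beta=4.0), design, seed=3)
        f = fit_mle("simple", s, n_restarts=10, seed=0)
        choices, rewards = bandit_arrays(s)
        alphas = np.linspace(1e-4, 1 - 1e-4, 101)
        betas = np.linspace(0, 10, 101)
        grid = trajectory_loglik(
            "simple", choices, rewards, alphas[:, None], betas[None, :]
        ).sum(-1)
        i, j = np.unravel_index(np.argmax(grid), grid.shape)
        assert f.loglik >= grid[i, j] - 1e-6
        assert abs(f.params.alpha - alphas[i]) <= (alphas[1] - alphas[0]) + 1e-9
        assert abs(f.params.beta - betas[j]) <= (betas[1] - betas[0]) + 1e-9

    def test_recovery_error_mostly_within_015_at_200_trials(self):
        errs = []
        for r in range(20):
            design = generate_bandit_session(seed=1000 + r, n_trials=200)
            s = simulate_agent(
                AgentParams(model="simple", alpha=0.3, beta=3.0), design, seed=2000 + r
            )
            f = fit_mle("simple", s, n_restarts=3, seed=r)
            errs.append(f.params.alpha - 0.3)
        errs = np.abs(errs)
        assert np.median(errs) < 0.15
        assert (errs < 0.15).mean() >= 0.8


@pytest.fixture(scope="module")
def small_group_fit():
    """A 16-participant hierarchical fit reused across tests."""
    rng = np.random.default_rng(77)
    sessions = []
    for i in range(16):
        design = generate_bandit_session(seed=500 + i, n_trials=40, participant_id=f"P{i:02d}")
        a = float(np.clip(rng.normal(0.4, 0.08), 0.05, 0.95))
        sessions.append(
            simulate_agent(AgentParams(model="counterfactual", alpha=a, beta=3.0), design, seed=600 + i)
        )
    model = HierarchicalRW(sessions, model="counterfactual", group="g")
    return sessions, model, model.fit(chains=2, warmup=400, draws=300, seed=9)


class TestHierarchical:
    def test_single_participant_group_rejected(self, played_bandit_session):
        with pytest.raises(ValueError, match=">= 2 participants"):
            HierarchicalRW([played_bandit_session])

    def test_alpha_estimates_within_unit_interval(self, small_group_fit):
        _, _, res = small_group_fit
        means = res.individual_means()
        assert ((means["alpha"] > 0) & (means["alpha"] < 1)).all()
        assert ((means["beta"] >= 0) & (means["beta"] <= 10)).all()

    def test_pointwise_matrix_covers_all_included_trials(self, small_group_fit):
        sessions, _, res = small_group_fit
        n_obs = sum(len(s.included_trials) for s in sessions)
        assert res.flat_loglik().shape[1] == n_obs
        assert len(res.obs_index) == n_obs

    def test_identical_sessions_shrink_individual_means_together(self):
        """Exchangeable participants with identical data get near-identical estimates."""
        design = generate_bandit_session(seed=21, n_trials=30)
        base = simulate_agent(
            AgentParams(model="counterfactual", alpha=0.4, beta=3.0), design, seed=22
        )
        sessions = []
        for i in range(8):
            s = copy.deepcopy(base)
            s.participant_id = f"C{i}"
            for t in s.trials:
                t.participant_id = s.participant_id
            sessions.append(s)
        res = HierarchicalRW(sessions, model="counterfactual").fit(
            chains=2, warmup=300, draws=200, seed=5
        )
        alphas = res.individual_means()["alpha"].to_numpy()
        assert alphas.std() < 0.02

    def test_fit_deterministic_given_seed(self):
        sessions = [
            simulate_agent(
                AgentParams(model="simple", alpha=0.4, beta=3.0),
                generate_bandit_session(seed=30 + i, participant_id=f"D{i}"),
                seed=40 + i,
            )
            for i in range(4)
        ]
        r1 = HierarchicalRW(sessions, model="simple").fit(chains=2, warmup=100, draws=50, seed=3)
        r2 = HierarchicalRW(sessions, model="simple").fit(chains=2, warmup=100, draws=50, seed=3)
        np.testing.assert_array_equal(r1.natural, r2.natural)
        np.testing.assert_array_equal(r1.pointwise_loglik, r2.pointwise_loglik)

    def test_group_mean_insensitive_to_participant_ordering(self, small_group_fit):
        sessions, _, res = small_group_fit
        res_rev = HierarchicalRW(sessions[::-1], model="counterfactual", group="g").fit(
            chains=2, warmup=400, draws=300, seed=9
        )
        a1 = res.individual_means().set_index("participant_id")["alpha"].sort_index()
        a2 = res_rev.individual_means().set_index("participant_id")["alpha"].sort_index()
        assert float(np.abs(a1.mean() - a2.mean())) < 0.03
        assert float(np.abs(a1 - a2).mean()) < 0.05

    def test_posterior_means_shrink_toward_group_mean(self, small_group_fit):
        """Partial pooling: posterior means sit closer to the group mean than MLEs
        on the probit scale."""
        sessions, _, res = small_group_fit
        post = res.individual_means().set_index("participant_id")["alpha"]
        mles = {}
        for s in sessions:
            f = fit_mle("counterfactual", s, n_restarts=4, seed=1)
            mles[s.participant_id] = f.params.alpha
        post_p = ndtri(post.to_numpy())
        mle_p = ndtri(np.clip([mles[p] for p in post.index], 1e-4, 1 - 1e-4))
        centre = post_p.mean()
        assert np.abs(post_p - centre).mean() < np.abs(mle_p - centre).mean()

    def test_summary_reports_all_hyperparameters(self, small_group_fit):
        _, _, res = small_group_fit
        summ = res.summary()
        assert {"group_alpha", "group_beta"} <= set(summ["parameter"])
        assert {"mean", "sd", "rhat", "ess_bulk"} <= set(summ.columns)


class TestLoo:
    def test_degenerate_posterior_equals_insample_sum(self):
        ll = np.tile(np.array([-0.5, -1.2, -0.3]), (50, 1))
        res = compute_loo(ll)
        assert res.elpd_loo == pytest.approx(-2.0)
        assert res.looic == pytest.approx(4.0)

    def test_loo_never_beats_insample_lpd(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-1, 0.5, size=(300, 40))
        res = compute_loo(ll)
        insample = (logsumexp(ll, axis=0) - np.log(ll.shape[0])).sum()
        assert res.elpd_loo <= insample + 1e-10

    def test_duplicated_observations_double_the_looic(self):
        rng = np.random.default_rng(1)
        ll = rng.normal(-0.8, 0.4, size=(400, 25))
        single = compute_loo(ll)
        double = compute_loo(np.concatenate([ll, ll], axis=1))
        assert double.looic == pytest.approx(2 * single.looic, rel=1e-9)

    def test_matches_arviz_psis_oracle(self):
        """Independent PSIS implementation (arviz) agrees within 0.1 elpd."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(42)
        ll = rng.normal(-0.7, 0.3, size=(500, 30)) - 0.02 * rng.gamma(2, size=(500, 1))
        mine = compute_loo(ll)
        idata = az.from_dict(
            posterior={"theta": rng.normal(size=(2, 250))},
            log_likelihood={"y": ll.reshape(2, 250, 30)},
        )
        ref = az.loo(idata, pointwise=True)
        assert mine.elpd_loo == pytest.approx(float(ref.elpd_loo), abs=0.1)
        assert np.abs(mine.pareto_k - ref.pareto_k.values).max() < 0.2

    def test_non_finite_loglik_names_offending_observation(self):
        ll = np.zeros((10, 3))
        ll[4, 1] = np.nan
        with pytest.raises(ValueError, match=r"\[1\]"):
            compute_loo(ll)


def _fake_results(model, pointwise, obs_index, group="g"):
    from problearn.fitting import HierarchicalRWResults, SamplerConfig

    C, D, n = pointwise.shape
    return HierarchicalRWResults(
        model=model, group=group, param_names=("alpha", "beta"),
        participant_ids=["p1", "p2"], obs_index=obs_index,
        mu=np.zeros((C, D, 2)), sigma=np.ones((C, D, 2)),
        natural=np.full((C, D, 2, 2), 0.5), pointwise_loglik=pointwise,
        accept_rates=np.zeros((C, 3)), config=SamplerConfig(chains=C, draws=D),
    )


class TestCompareModels:
    def test_lowest_looic_flagged_best(self):
        rng = np.random.default_rng(3)
        obs = [("p1", i) for i in range(10)] + [("p2", i) for i in range(10)]
        good = rng.normal(-0.3, 0.1, size=(2, 100, 20))
        bad = rng.normal(-0.9, 0.1, size=(2, 100, 20))
        cmp = compare_models(
            {
                "simple": _fake_results("simple", bad, obs),
                "counterfactual": _fake_results("counterfactual", good, obs),
            }
        )
        assert cmp.best() == "counterfactual"
        assert cmp.table.iloc[0]["looic"] < cmp.table.iloc[1]["looic"]

    def test_exact_tie_broken_by_model_simplicity(self):
        rng = np.random.default_rng(4)
        obs = [("p1", i) for i in range(8)] + [("p2", i) for i in range(8)]
        pw = rng.normal(-0.5, 0.1, size=(2, 100, 16))
        cmp = compare_models(
            {
                "counterfactual": _fake_results("counterfactual", pw.copy(), obs),
                "simple": _fake_results("simple", pw.copy(), obs),
            }
        )
        assert cmp.best() == "simple"

    def test_single_model_refused(self):
        rng = np.random.default_rng(5)
        obs = [("p1", 0), ("p2", 0)]
        pw = rng.normal(-0.5, 0.1, size=(2, 50, 2))
        with pytest.raises(ValueError, match=">= 2"):
            compare_models({"simple": _fake_results("simple", pw, obs)})

    def test_mismatched_observation_sets_refused(self):
        rng = np.random.default_rng(6)
        obs_a = [("p1", i) for i in range(5)]
        obs_b = [("p1", i) for i in range(1, 6)]
        pw = rng.normal(-0.5, 0.1, size=(2, 50, 5))
        with pytest.raises(ValueError, match="mismatched"):
            compare_models(
                {
                    "simple": _fake_results("simple", pw, obs_a),
                    "counterfactual": _fake_results("counterfactual", pw, obs_b),
                }
            )
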