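import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from feedbacklearn import rl, task
from conftest import make_trials


def oracle_nll(trials: pd.DataFrame, spec: rl.ModelSpec, theta) -> float:
    """Independent naive recomputation of the session likelihood: a plain
    dict-based loop with no vectorisation or compilation."""
    ap, an, beta, eps, gamma = spec.unpack(theta)
    q = {s: 0.5 for s in task.STIMULI}
    nll = 0.0
    for row in trials.sort_values("trial").itertuples(index=False):
        chosen = row.chosen_stimulus
        if chosen is None or (isinstance(chosen, float) and math.isnan(chosen)):
            continue
        other = row.stim_left if chosen == row.stim_right else row.stim_right
        if row.phase == "learning":
            if row.feedback == "win":
                q[chosen] += ap * (1.0 - q[chosen])
            elif row.feedback == "loss":
                q[chosen] += an * (0.0 - q[chosen])
        else:
            if not math.isnan(row.rt) and row.rt < 200.0:
                continue
            p = 1.0 / (1.0 + math.exp(-beta * (q[chosen] - q[other])))
            nll -= math.log(p)
            if spec.dynamics == "cipc":
                q[chosen] += eps * (1.0 - q[chosen])
                q[other] -= eps * q[other]
            elif spec.dynamics == "decay":
                q[chosen] += gamma * (0.5 - q[chosen])
                q[other] += gamma * (0.5 - q[other])
    return nll


class TestPrimitives:
    @pytest.mark.parametrize(
        "q,r,ap,an,expected",
        [
            (0.5, 1, 0.0, 0.3, 0.5),  # zero learning rate
            (0.0, 1, 0.5, 0.3, 0.5),  # midpoint step
            (0.5, 0, 0.9, 0.2, 0.4),  # loss gated by alpha_neg
        ],
    )
    def test_delta_rule_arithmetic(self, q, r, ap, an, expected):
        assert rl.q_update(q, r, ap, an) == pytest.approx(expected)

    def test_delta_rule_rejects_out_of_bounds(self):
        with pytest.raises(ValueError):
            rl.q_update(1.2, 1, 0.5, 0.5)
        with pytest.raises(ValueError):
            rl.q_update(0.5, 2, 0.5, 0.5)

    @pytest.mark.parametrize(
        "model,theta,qc,qu,expected",
        [
            ("dual_static", (0.3, 0.3, 5.0), 0.7, 0.3, (0.7, 0.3)),
            ("dual_cipc", (0.3, 0.3, 5.0, 0.0), 0.7, 0.3, (0.7, 0.3)),
            ("dual_cipc", (0.3, 0.3, 5.0, 0.5), 0.6, 0.4, (0.8, 0.2)),
            ("dual_decay", (0.3, 0.3, 5.0, 1.0), 0.9, 0.1, (0.5, 0.5)),
        ],
    )
    def test_feedbackfree_dynamics(self, model, theta, qc, qu, expected):
        out = rl.feedbackfree_update(qc, qu, rl.MODELS[model], theta)
        assert out == pytest.approx(expected)

    def test_choice_prob_symmetry_and_logistic_value(self):
        assert rl.choice_prob(0.7, 0.7, 5.0) == 0.5
        assert rl.choice_prob(0.9, 0.1, 0.0) == 0.5
        assert rl.choice_prob(1.0, 0.0, 1.0) == pytest.approx(1 / (1 + math.exp(-1)))
        assert rl.choice_prob(0.2, 0.8, 2.0) == pytest.approx(
            1 - rl.choice_prob(0.8, 0.2, 2.0)
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        rewards=hst.lists(hst.integers(0, 1), min_size=1, max_size=50),
        ap=hst.floats(0, 1),
        an=hst.floats(0, 1),
        q=hst.floats(0, 1),
    )
    def test_q_stays_bounded_under_any_update_sequence(self, rewards, ap, an, q):
        for r in rewards:
            q = rl.q_update(q, r, ap, an)
            assert 0.0 <= q <= 1.0


class TestSessionNll:
    def test_certain_model_has_zero_nll(self):
        # after a deterministic learning history, a near-infinite beta agent
        # assigns probability 1 (to double precision) to value-consistent choices
        rows = [
            {"phase": "learning", "pair": "A/B", "chosen_stimulus": "A", "feedback": "win"},
            {"phase": "test", "pair": "A/B", "chosen_stimulus": "A"},
            {"phase": "test", "pair": "A/B", "chosen_stimulus": "A"},
        ]
        trials = make_trials(rows)
        nll, n = rl.session_nll(trials, rl.MODELS["dual_static"], (0.5, 0.5, 1e9))
        assert n == 2
        assert nll == 0.0

    def test_chance_model_nll_is_n_log2(self, active_session):
        spec = rl.MODELS["dual_cipc"]
        nll, n = rl.session_nll(active_session, spec, (0.3, 0.3, 0.0, 0.2))
        assert nll == pytest.approx(n * math.log(2), abs=1e-12)

    def test_three_trial_hand_computation(self):
        # one learning win on A (alpha+=0.5 -> Q_A=0.75), then three test
        # choices under beta=2, CIPC eps=0.2; enumerated by hand
        trials = make_trials(
            [
                {"phase": "learning", "pair": "A/B", "chosen_stimulus": "A", "feedback": "win"},
                {"phase": "test", "pair": "A/B", "chosen_stimulus": "A"},
                {"phase": "test", "pair": "A/B", "chosen_stimulus": "B"},
                {"phase": "test", "pair": "A/B", "chosen_stimulus": "A"},
            ]
        )
        theta = (0.5, 0.5, 2.0, 0.2)
        p1 = 1 / (1 + math.exp(-2.0 * (0.75 - 0.5)))  # Q_A=0.75, Q_B=0.5
        # CIPC: Q_A=0.8, Q_B=0.4
        p2 = 1 / (1 + math.exp(-2.0 * (0.4 - 0.8)))
        # CIPC on B: Q_B=0.52, Q_A=0.64
        p3 = 1 / (1 + math.exp(-2.0 * (0.64 - 0.52)))
        expected = -(math.log(p1) + math.log(p2) + math.log(p3))
        nll, n = rl.session_nll(trials, rl.MODELS["dual_cipc"], theta)
        assert n == 3
        assert nll == pytest.approx(expected, abs=1e-12)

    def test_invalid_trials_contribute_nothing(self):
        trials = make_trials(
            [
                {"phase": "learning", "pair": "A/B", "chosen_stimulus": "A", "feedback": "win"},
                {"phase": "test", "pair": "A/B", "chosen_stimulus": "A", "rt": 150.0},
                {"phase": "test", "pair": "A/B", "chosen_stimulus": None, "rt": np.nan},
                {"phase": "test", "pair": "A/B", "chosen_stimulus": "A"},
            ]
        )
        nll, n = rl.session_nll(trials, rl.MODELS["dual_cipc"], (0.5, 0.5, 2.0, 0.2))
        assert n == 1

    def test_unordered_or_mixed_input_raises(self, active_session):
        spec = rl.MODELS["dual_cipc"]
        with pytest.raises(ValueError, match="ordered"):
            rl.session_nll(active_session.iloc[::-1], spec, (0.3, 0.3, 5.0, 0.1))
        mixed = pd.concat(
            [active_session, active_session.assign(participant_id="P999")]
        )
        with pytest.raises(ValueError, match="single participant"):
            rl.session_nll(mixed, spec, (0.3, 0.3, 5.0, 0.1))

    @pytest.mark.parametrize("model", ["dual_static", "dual_decay", "dual_cipc"])
    def test_matches_brute_force_oracle_on_random_sessions(self, model):
        spec = rl.MODELS[model]
        rng = np.random.default_rng(99)
        design = task.TaskDesign(
            learning_block_len=9, test_block_len=6, transfer_len=8,
            n_learning_blocks=2, n_test_blocks=2,
        )
        for i in range(50):
            agent = task.AgentParams(
                alpha_pos=rng.uniform(0.05, 0.9),
                alpha_neg=rng.uniform(0.05, 0.9),
                beta=rng.uniform(0.5, 10),
                epsilon=rng.uniform(0, 0.5),
                p_no_response=0.05,
            )
            sched = task.build_design(design, seed=i)
            sess = task.simulate_active_session(sched, agent, seed=500 + i, design=design)
            theta = [rng.uniform(lo, min(hi, 10.0)) for lo, hi in spec.bounds]
            nll, _ = rl.session_nll(sess, spec, theta)
            assert abs(nll - oracle_nll(sess, spec, theta)) < 1e-10


class TestFitting:
    def test_chance_data_yields_chance_fit(self, default_schedule):
        agent = task.AgentParams(beta=0.0, p_no_response=0.0)
        sess = task.simulate_active_session(default_schedule, agent, seed=5)
        fit = rl.fit_model(sess, rl.MODELS["dual_cipc"], n_starts=10, seed=0)
        n = fit.n_likelihood_trials
        assert fit.nll <= n * math.log(2) + 1e-9
        assert fit.nll > n * math.log(2) - 0.05 * n  # no spurious structure
        assert fit.params["beta"] < 0.5

    def test_bic_identity_and_formula(self, default_schedule):
        sess = task.simulate_active_session(default_schedule, task.AgentParams(), seed=6)
        fit = rl.fit_model(sess, rl.MODELS["dual_cipc"], n_starts=5, seed=1)
        assert fit.bic == pytest.approx(
            fit.spec.k * math.log(fit.n_likelihood_trials) + 2 * fit.nll, abs=1e-12
        )
        fit.nll, fit.n_likelihood_trials = 50.0, 100
        assert fit.bic == pytest.approx(4 * math.log(100) + 100, abs=1e-12)

    def test_no_likelihood_trials_raises(self):
        trials = make_trials(
            [{"phase": "learning", "pair": "A/B", "chosen_stimulus": "A", "feedback": "win"}]
        )
        with pytest.raises(ValueError, match="likelihood"):
            rl.fit_model(trials, rl.MODELS["dual_cipc"])

    def test_nested_model_never_fits_worse(self, default_schedule):
        sess = task.simulate_active_session(default_schedule, task.AgentParams(), seed=8)
        small = rl.fit_model(sess, rl.MODELS["single_static"], n_starts=10, seed=0)
        large = rl.fit_model(sess, rl.MODELS["dual_cipc"], n_starts=10, seed=0)
        assert large.nll <= small.nll + 1e-6

    def test_more_trials_reduce_recovery_error(self):
        # median absolute parameter-recovery error shrinks when the number of
        # likelihood trials triples
        rng = np.random.default_rng(17)
        spec = rl.MODELS["dual_cipc"]

        def median_error(test_len, transfer_len, tag):
            design = task.TaskDesign(test_block_len=test_len, transfer_len=transfer_len)
            errs = []
            for i in range(25):
                agent = task.AgentParams(
                    alpha_pos=rng.uniform(0.05, 0.7),
                    alpha_neg=rng.uniform(0.05, 0.7),
                    beta=rng.uniform(1, 10),
                    epsilon=rng.uniform(0.05, 0.5),
                    p_no_response=0.0,
                )
                sched = task.build_design(design, seed=tag + i)
                sess = task.simulate_active_session(sched, agent, seed=tag + 100 + i, design=design)
                fit = rl.fit_model(sess, spec, n_starts=10, seed=i)
                truth = np.array([agent.alpha_pos, agent.alpha_neg, agent.beta / 10, agent.epsilon])
                est = fit.theta
                est[2] /= 10  # put beta on a comparable scale
                errs.extend(np.abs(est - truth))
            return np.median(errs)

        assert median_error(90, 120, 9000) < median_error(30, 40, 8000)


class TestModelComparison:
    def test_ranking_and_winner_flag(self, active_session):
        specs = [rl.MODELS[m] for m in ("single_static", "dual_cipc")]
        ranking = rl.compare_models(active_session, specs, n_starts=5, seed=0)
        assert ranking["summed_bic"].is_monotonic_increasing
        assert ranking["winner"].sum() == 1
        assert ranking.loc[ranking["winner"], "model"].iloc[0] == ranking["model"].iloc[0]

    def test_requires_at_least_two_specs(self, active_session):
        with pytest.raises(ValueError):
            rl.compare_models(active_session, [rl.MODELS["dual_cipc"]])


class TestLatents:
    def test_latent_identities(self, active_session):
        fit = rl.fit_model(active_session, rl.MODELS["dual_cipc"], n_starts=5, seed=2)
        lat = rl.extract_latents(fit, active_session)
        fb = lat["pe"].notna()
        assert (lat.loc[fb, "spe"] == lat.loc[fb, "pe"].abs()).all()
        assert lat["q_chosen"].dropna().between(0, 1).all()
        assert lat["dq"].dropna().between(-1, 1).all()
        assert (lat["dq"] - (lat["q_chosen"] - lat["q_unchosen"])).abs().max() < 1e-12
        # PE exists exactly on feedback trials
        has_fb = active_session["feedback"].isin(["win", "loss"]).to_numpy()
        assert (fb.to_numpy() == has_fb).all()
        assert abs(lat["spe_centered"].mean()) < 1e-12

    def test_pe_arithmetic(self):
        trials = make_trials(
            [{"phase": "learning", "pair": "A/B", "chosen_stimulus": "A", "feedback": "win"}]
        )
        _, _, lat = rl.session_nll(
            trials, rl.MODELS["dual_static"], (0.3, 0.3, 5.0), return_latents=True
        )
        assert lat["pe"].iloc[0] == pytest.approx(0.5)  # r=1 vs Q0=0.5
        assert lat["spe"].iloc[0] == pytest.approx(0.5)
        assert lat["dq"].iloc[0] == pytest.approx(0.0)
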