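import numpy as np
import pytest

from problearn import AgentParams, generate_bandit_session, simulate_agent


@pytest.fixture(scope="session")
def played_bandit_session():
    """A 20-trial bandit session played by a counterfactual agent."""
    design = generate_bandit_session(seed=42)
    params = AgentParams(model="counterfactual", alpha=0.4, beta=3.0)
    return simulate_agent(params, design, seed=7, timeout_prob=0.0)


@pytest.fixture(scope="session")
def long_played_session():
    """A 200-trial bandit session played by a simple-RW agent."""
    design = generate_bandit_session(seed=11, n_trials=200)
    params = AgentParams(model="simple", alpha=0.3, beta=3.0)
    return simulate_agent(params, design, seed=5, timeout_prob=0.0)


def brute_force_session_loglik(params, session):
    """Independent trial-by-trial likelihood oracle (plain Python loop)."""
    V = [0.0, 0.0]
    total = 0.0
    pointwise = []
    for t in session.trials:
        if t.is_catch or t.response in (None, "timeout"):
            continue
        c = t.presented_options.index(t.response)
        p = 1.0 / (1.0 + np.exp(-params.beta * (V[c] - V[1 - c])))
        lp = float(np.log(p))
        total += lp
        pointwise.append(lp)
        R = 1.0 if t.response == t.outcome else -1.0
        if params.model == "simple":
            V[c] += params.alpha * (R - V[c])
        elif params.model == "posneg":
            d = R - V[c]
            rate = params.alpha_pos if d >= 0 else params.alpha_neg
            V[c] += rate * d
        else:
            V[c] += params.alpha * (R - V[c])
            V[1 - c] += params.alpha * (-R - V[1 - c])
    return total, np.asarray(pointwise)
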