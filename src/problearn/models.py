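"""Rescorla-Wagner model variants for the two-armed bandit.

Three delta-rule learners over a reward signal coded R in {-1, +1}:

* ``simple`` — one learning rate; only the chosen option is updated:
  V <- V + alpha * (R - V).
* ``posneg`` — separate learning rates for positive (alpha+) and negative
  (alpha-) prediction errors; zero prediction errors take the alpha+ branch.
* ``counterfactual`` — fictitious updating: the chosen option learns from R
  and the unchosen option from -R, valid because the task's outcomes are
  anti-correlated (exactly one option rewarded per trial).

Choices follow a softmax on the value difference with inverse temperature
beta: p(a) = 1 / (1 + exp(-beta * (V_a - V_b))).  All values start at 0.
Likelihood contributions precede the update on the same trial
(predict-then-learn).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tasks import SessionData

__all__ = [
    "MODELS",
    "N_PARAMS",
    "AgentParams",
    "update_simple",
    "update_posneg",
    "update_counterfactual",
    "choice_prob",
    "trajectory_loglik",
    "session_loglik",
    "bandit_arrays",
]

MODELS = ("simple", "posneg", "counterfactual")

#: free parameters per model (used for parsimony tie-breaks)
N_PARAMS = {"simple": 2, "posneg": 3, "counterfactual": 2}

BETA_MAX = 10.0


def _check_alpha(alpha: float, name: str = "alpha") -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"{name} must lie in (0, 1), got {alpha}")


@dataclass(frozen=True)
class AgentParams:
    """Parameters of one agent: learning rate(s) and inverse temperature.

    ``alpha`` is used by the simple and counterfactual models;
    ``alpha_pos``/``alpha_neg`` by the posneg model.  ``beta`` is bounded to
    [0, 10].
    """

    model: str
    beta: float
    alpha: float | None = None
    alpha_pos: float | None = None
    alpha_neg: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if not 0.0 <= self.beta <= BETA_MAX:
            raise ValueError(f"beta must lie in [0, {BETA_MAX}], got {self.beta}")
        if self.model in ("simple", "counterfactual"):
            if self.alpha is None:
                raise ValueError(f"{self.model} model requires alpha")
            _check_alpha(self.alpha)
        else:
            if self.alpha_pos is None or self.alpha_neg is None:
                raise ValueError("posneg model requires alpha_pos and alpha_neg")
            _check_alpha(self.alpha_pos, "alpha_pos")
            _check_alpha(self.alpha_neg, "alpha_neg")

    def to_dict(self) -> dict:
        d = {"model": self.model, "beta": float(self.beta)}
        if self.model == "posneg":
            d["alpha_pos"] = float(self.alpha_pos)
            d["alpha_neg"] = float(self.alpha_neg)
        else:
            d["alpha"] = float(self.alpha)
        return d


def update_simple(V: float, R: float, alpha: float) -> tuple[float, float]:
    """One delta-rule step for the chosen option: returns (V', delta)."""
    _check_alpha(alpha)
    delta = R - V
    return V + alpha * delta, delta


def update_posneg(
    V: float, R: float, alpha_pos: float, alpha_neg: float
) -> tuple[float, float]:
    """Delta-rule step with valence-dependent rates; delta >= 0 uses alpha_pos."""
    _check_alpha(alpha_pos, "alpha_pos")
    _check_alpha(alpha_neg, "alpha_neg")
    delta = R - V
    rate = alpha_pos if delta >= 0 else alpha_neg
    return V + rate * delta, delta


def update_counterfactual(
    Vc: float, Vnc: float, R: float, alpha: float
) -> tuple[float, float]:
    """Fictitious update: chosen learns from R, unchosen from -R.

    Returns (Vc', Vnc').
    """
    _check_alpha(alpha)
    return Vc + alpha * (R - Vc), Vnc + alpha * (-R - Vnc)


def choice_prob(V_a, V_b, beta):
    """Softmax probability of choosing option a over b."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta must be non-negative")
    d = np.asarray(V_a, dtype=float) - np.asarray(V_b, dtype=float)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-beta * d))
    return p


def trajectory_loglik(
    model: str,
    choices: np.ndarray,
    rewards: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    alpha_neg: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Pointwise log-likelihood of observed bandit choices, vectorised.

    Parameters
    ----------
    model
        One of ``simple``, ``posneg``, ``counterfactual``.
    choices, rewards
        Integer arrays of shape ``(..., T)``.  ``choices`` in {0, 1} indexes
        the chosen option; ``rewards`` in {-1, +1} is the reward of the
        *chosen* option.  Leading axes may index participants, posterior
        draws, or both.
    alpha, beta
        Arrays broadcastable to the leading shape ``(...)``.  For the posneg
        model, ``alpha`` is the positive-PE rate and ``alpha_neg`` the
        negative-PE rate.
    mask
        Boolean ``(..., T)``; ``False`` marks trials that contribute no
        likelihood term and trigger no update (timeouts).  Default all-True.

    Returns
    -------
    Array ``(..., T)`` of pointwise log-likelihoods; masked trials are 0.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    choices = np.asarray(choices)
    rewards = np.asarray(rewards, dtype=float)
    T = choices.shape[-1]
    lead = np.broadcast_shapes(
        choices.shape[:-1], np.shape(alpha), np.shape(beta)
    )
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), lead)
    beta = np.broadcast_to(np.asarray(beta, dtype=float), lead)
    if model == "posneg":
        if alpha_neg is None:
            raise ValueError("posneg model requires alpha_neg")
        alpha_neg = np.broadcast_to(np.asarray(alpha_neg, dtype=float), lead)
    if mask is None:
        mask = np.ones(lead + (T,), dtype=bool)
    else:
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), lead + (T,))
    choices = np.broadcast_to(choices, lead + (T,))
    rewards = np.broadcast_to(rewards, lead + (T,))

    V = np.zeros(lead + (2,), dtype=float)
    out = np.zeros(lead + (T,), dtype=float)
    idx = np.indices(lead, sparse=True) if lead else ()
    for t in range(T):
        c = choices[..., t]
        m = mask[..., t]
        Vc = V[(*idx, c)] if lead else V[c]
        Vu = V[(*idx, 1 - c)] if lead else V[1 - c]
        # log p(observed choice) via a numerically safe logistic
        z = beta * (Vc - Vu)
        lp = -np.logaddexp(0.0, -z)
        out[..., t] = np.where(m, lp, 0.0)

        R = rewards[..., t]
        delta_c = R - Vc
        if model == "simple":
            Vc_new = Vc + alpha * delta_c
            Vu_new = Vu
        elif model == "posneg":
            rate = np.where(delta_c >= 0, alpha, alpha_neg)
            Vc_new = Vc + rate * delta_c
            Vu_new = Vu
        else:  # counterfactual
            Vc_new = Vc + alpha * delta_c
            Vu_new = Vu + alpha * (-R - Vu)
        if lead:
            V[(*idx, c)] = np.where(m, Vc_new, Vc)
            V[(*idx, 1 - c)] = np.where(m, Vu_new, Vu)
        else:
            V[c] = Vc_new if m else Vc
            V[1 - c] = Vu_new if m else Vu
    return out


def bandit_arrays(session: SessionData) -> tuple[np.ndarray, np.ndarray]:
    """Extract (choices, rewards) arrays from a played bandit session.

    Catch trials and timeouts are dropped; ``choices`` indexes
    ``presented_options`` and ``rewards`` is +1 when the chosen option was the
    rewarded one, else -1.
    """
    if session.task != "bandit":
        raise ValueError(f"expected a bandit session, got task {session.task!r}")
    choices, rewards = [], []
    for t in session.included_trials:
        c = t.presented_options.index(t.response)
        choices.append(c)
        rewards.append(1.0 if t.response == t.outcome else -1.0)
    return np.asarray(choices, dtype=int), np.asarray(rewards, dtype=float)


def session_loglik(
    params: AgentParams, session: SessionData
) -> tuple[float, np.ndarray]:
    """Total and pointwise log-likelihood of one bandit session under ``params``.

    Timed-out and catch trials contribute no term and trigger no update.  A
    session with no included trials returns (0.0, empty vector).
    """
    choices, rewards = bandit_arrays(session)
    if choices.size == 0:
        return 0.0, np.empty(0)
    if params.model == "posneg":
        pw = trajectory_loglik(
            params.model, choices, rewards, params.alpha_pos, params.beta,
            alpha_neg=params.alpha_neg,
        )
    else:
        pw = trajectory_loglik(params.model, choices, rewards, params.alpha, params.beta)
    return float(pw.sum()), pw
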