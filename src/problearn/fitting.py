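"""Preprocessing, estimation and model comparison for bandit sessions.

Two estimation routes are provided:

* :func:`fit_mle` — per-participant maximum likelihood (multi-start
  L-BFGS-B), a fast point-estimation companion.
* :class:`HierarchicalRW` — a hierarchical Bayesian model fitted per group.
  Individual parameters are non-centred deviations around group-level
  location/scale on a transformed scale (probit link mapping the learning
  rate to (0, 1) and the inverse temperature to (0, 10)), with
  weakly-informative Normal(0, 1) hyperpriors on the locations and
  half-Normal(1) on the scales.  Posterior sampling uses an adaptive
  Metropolis-within-Gibbs scheme (random-walk proposals per participant and
  per hyperparameter, step sizes tuned during warmup); convergence is
  monitored with the split-chain R-hat statistic and effective sample sizes.

Model comparison uses Pareto-smoothed importance-sampling leave-one-out
cross-validation (PSIS-LOO); LOOIC = -2 * elpd_loo, lower is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, logsumexp

from .models import MODELS, N_PARAMS, AgentParams, BETA_MAX, bandit_arrays, trajectory_loglik
from .tasks import SessionData

__all__ = [
    "NoFitError",
    "apply_exclusions",
    "MLEFit",
    "fit_mle",
    "HierarchicalRW",
    "HierarchicalRWResults",
    "LooResult",
    "compute_loo",
    "psis_log_weights",
    "ModelComparison",
    "compare_models",
]


class NoFitError(ValueError):
    """Raised when a session carries no likelihood-bearing trials."""


# ---------------------------------------------------------------------------
# preprocessing


def apply_exclusions(
    sessions: list[SessionData], catch_threshold: float = 0.75
) -> tuple[list[SessionData], dict]:
    """Apply the study's exclusion rules to a cohort of sessions.

    Participants whose pooled catch-trial accuracy across all their sessions
    is strictly below ``catch_threshold`` are removed entirely (exactly 75%
    is retained).  Timed-out trials stay in the record — they are excluded
    from likelihoods downstream — and are counted in the report.

    Returns the filtered session list and a report dict.
    """
    by_pid: dict[str, list[SessionData]] = {}
    for s in sessions:
        by_pid.setdefault(s.participant_id, []).append(s)

    excluded: dict[str, float] = {}
    timeouts: dict[str, int] = {}
    no_catch = []
    for pid, sess_list in by_pid.items():
        catch = [t for s in sess_list for t in s.catch_trials]
        timeouts[pid] = sum(
            1
            for s in sess_list
            for t in s.experimental_trials
            if t.response == "timeout"
        )
        scored = [t for t in catch if t.correct is not None]
        if not scored:
            no_catch.append(pid)
            continue
        acc = float(np.mean([t.correct for t in scored]))
        if acc < catch_threshold:
            excluded[pid] = acc
    if no_catch:
        warnings.warn(
            f"no scored catch trials for participants {no_catch}; "
            "catch-based exclusion not applied to them",
            stacklevel=2,
        )
    kept = [s for s in sessions if s.participant_id not in excluded]
    report = {
        "catch_threshold": catch_threshold,
        "excluded_participants": excluded,
        "n_excluded": len(excluded),
        "timeout_trials_per_participant": timeouts,
        "participants_without_catch": no_catch,
    }
    return kept, report


# ---------------------------------------------------------------------------
# maximum likelihood

_ALPHA_LO, _ALPHA_HI = 1e-4, 1 - 1e-4


@dataclass
class MLEFit:
    """Point estimate for one session: parameters, log-likelihood, diagnostics."""

    params: AgentParams
    loglik: float
    n_trials: int
    alpha_identifiable: bool
    n_restarts: int


def _neg_loglik(x: np.ndarray, model: str, choices: np.ndarray, rewards: np.ndarray) -> float:
    if model == "posneg":
        pw = trajectory_loglik(model, choices, rewards, x[0], x[2], alpha_neg=x[1])
    else:
        pw = trajectory_loglik(model, choices, rewards, x[0], x[1])
    return -float(pw.sum())


def fit_mle(
    model: str,
    session: SessionData,
    n_restarts: int = 10,
    seed: int = 0,
) -> MLEFit:
    """Maximum-likelihood parameters for one bandit session.

    Multi-start L-BFGS-B within the parameter bounds (learning rates in
    (0, 1), beta in [0, 10]); the best of ``n_restarts`` seeded starts is
    returned.  When the likelihood is flat in the learning rate (beta at 0),
    ``alpha_identifiable`` is False.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    choices, rewards = bandit_arrays(session)
    n = choices.size
    if n == 0:
        raise NoFitError(
            f"session for {session.participant_id!r} has no included trials"
        )
    rng = np.random.default_rng(seed)
    n_alpha = 2 if model == "posneg" else 1
    bounds = [(_ALPHA_LO, _ALPHA_HI)] * n_alpha + [(0.0, BETA_MAX)]
    best = None
    for _ in range(max(1, n_restarts)):
        x0 = np.concatenate(
            [rng.uniform(0.05, 0.95, size=n_alpha), rng.uniform(0.1, 5.0, size=1)]
        )
        res = optimize.minimize(
            _neg_loglik,
            x0,
            args=(model, choices, rewards),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    loglik = -float(best.fun)
    # flat likelihood: beta ~ 0 makes the learning rate unidentifiable
    identifiable = not (x[-1] < 1e-3 or abs(loglik - n * np.log(0.5)) < 1e-8)
    x = np.clip(x, [_ALPHA_LO] * n_alpha + [0.0], [_ALPHA_HI] * n_alpha + [BETA_MAX])
    if model == "posneg":
        params = AgentParams(model=model, alpha_pos=x[0], alpha_neg=x[1], beta=x[2])
    else:
        params = AgentParams(model=model, alpha=x[0], beta=x[1])
    return MLEFit(
        params=params,
        loglik=loglik,
        n_trials=n,
        alpha_identifiable=identifiable,
        n_restarts=n_restarts,
    )


# ---------------------------------------------------------------------------
# PSIS-LOO


def _gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Fit a generalized Pareto distribution to exceedances (sorted ascending).

    Empirical-Bayes profile estimator with a weak prior pulling the shape
    toward 0.5 for small tails; returns (k, sigma).
    """
    n = x.size
    prior_bs, prior_k = 3.0, 10.0
    m = 30 + int(np.sqrt(n))
    jj = np.arange(1, m + 1, dtype=float)
    b = 1.0 - np.sqrt(m / (jj - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k = np.mean(np.log1p(-b[:, None] * x), axis=1)
    L = n * (np.log(-b / k) - k - 1.0)
    w = 1.0 / np.exp(L - L[:, None]).sum(axis=1)
    w /= w.sum()
    keep = w >= 10 * np.finfo(float).eps
    b, w = b[keep], w[keep]
    w /= w.sum()
    b_post = float(np.sum(b * w))
    k_post = float(np.mean(np.log1p(-b_post * x)))
    sigma = -k_post / b_post
    # weak prior pulling the shape toward 0.5 stabilises small tails
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    return k_post, sigma


def _gpd_quantile(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma * np.expm1(-k * np.log1p(-p)) / k


def psis_log_weights(log_ratios: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pareto-smoothed importance-sampling log weights.

    Parameters
    ----------
    log_ratios
        ``(draws, n_obs)`` raw log importance ratios (for LOO: the negative
        pointwise log-likelihood).

    Returns
    -------
    (log_weights, k_hat): self-normalised smoothed log weights of the same
    shape (logsumexp over draws = 0 per observation) and the Pareto shape
    diagnostic per observation.
    """
    lw = np.asarray(log_ratios, dtype=float)
    if lw.ndim != 2:
        raise ValueError("log_ratios must be a (draws, n_obs) matrix")
    if not np.all(np.isfinite(lw)):
        bad = np.where(~np.isfinite(lw).all(axis=0))[0]
        raise ValueError(f"non-finite log ratios at observations {bad.tolist()}")
    S, n_obs = lw.shape
    n_tail = int(np.ceil(min(S / 5.0, 3.0 * np.sqrt(S))))
    out = np.empty_like(lw)
    khat = np.full(n_obs, -np.inf)
    for i in range(n_obs):
        x = lw[:, i] - lw[:, i].max()
        if n_tail >= 5:
            srt = np.sort(x)
            cutoff = srt[-n_tail - 1]
            tail_ids = np.where(x > cutoff)[0]
            tail = x[tail_ids]
            if tail.size >= 5 and np.ptp(tail) > 0:
                exc = np.sort(np.exp(tail) - np.exp(cutoff))
                k, sigma = _gpd_fit(exc)
                if np.isfinite(k):
                    khat[i] = k
                    probs = (np.arange(1, tail.size + 1) - 0.5) / tail.size
                    smoothed = np.log(_gpd_quantile(probs, k, sigma) + np.exp(cutoff))
                    order = np.argsort(tail)
                    x[tail_ids[order]] = smoothed
        x = np.minimum(x, 0.0)
        out[:, i] = x - logsumexp(x)
    return out, khat


@dataclass
class LooResult:
    """PSIS-LOO estimate: elpd_loo, LOOIC = -2 elpd_loo, SE and Pareto k."""

    elpd_loo: float
    looic: float
    se_elpd: float
    se_looic: float
    pareto_k: np.ndarray
    pointwise_elpd: np.ndarray
    n_obs: int

    @property
    def n_bad_k(self) -> int:
        return int(np.sum(self.pareto_k > 0.7))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LooResult(elpd_loo={self.elpd_loo:.2f}, looic={self.looic:.2f}, "
            f"se={self.se_looic:.2f}, n_obs={self.n_obs}, bad_k={self.n_bad_k})"
        )


def compute_loo(pointwise_loglik: np.ndarray) -> LooResult:
    """PSIS-LOO from a ``(draws, n_obs)`` pointwise log-likelihood matrix."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("pointwise log-likelihood must be (draws >= 2, n_obs)")
    if not np.all(np.isfinite(ll)):
        bad = np.where(~np.isfinite(ll).all(axis=0))[0]
        raise ValueError(f"non-finite log-likelihoods at observations {bad.tolist()}")
    lw, khat = psis_log_weights(-ll)
    elpd_i = logsumexp(lw + ll, axis=0)
    n = ll.shape[1]
    elpd = float(elpd_i.sum())
    se = float(np.sqrt(n * np.var(elpd_i)))
    return LooResult(
        elpd_loo=elpd,
        looic=-2.0 * elpd,
        se_elpd=se,
        se_looic=2.0 * se,
        pareto_k=khat,
        pointwise_elpd=elpd_i,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# hierarchical Bayesian model


def _link(raw: np.ndarray, scale: float) -> np.ndarray:
    return scale * ndtr(raw)


@dataclass
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept_block: float = 0.25
    target_accept_scalar: float = 0.44


class HierarchicalRW:
    """Hierarchical Rescorla-Wagner model for one group of bandit sessions.

    Parameters
    ----------
    sessions
        Played bandit sessions (one per participant) — timeouts and catch
        trials are excluded from the likelihood automatically.
    model
        ``simple``, ``posneg`` or ``counterfactual``.
    group
        Optional group label carried into results tables.

    Notes
    -----
    Individual parameters are generated non-centrally: for participant ``i``
    and parameter ``j``, ``raw_ij = mu_j + sigma_j * z_ij`` with
    ``z_ij ~ N(0, 1)``, mapped to the natural scale by a probit link
    (learning rates: ``Phi(raw)``; inverse temperature: ``10 * Phi(raw)``).
    """

    PARAM_NAMES = {
        "simple": ("alpha", "beta"),
        "posneg": ("alpha_pos", "alpha_neg", "beta"),
        "counterfactual": ("alpha", "beta"),
    }

    def __init__(
        self, sessions: list[SessionData], model: str = "counterfactual", group: str | None = None
    ):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}")
        if len(sessions) < 2:
            raise ValueError(
                f"hierarchical fitting needs >= 2 participants, got {len(sessions)}"
            )
        self.model = model
        self.group = group
        self.param_names = self.PARAM_NAMES[model]
        self.link_scales = tuple(
            BETA_MAX if p == "beta" else 1.0 for p in self.param_names
        )
        self.participant_ids = [s.participant_id for s in sessions]
        arrays = [bandit_arrays(s) for s in sessions]
        if any(c.size == 0 for c, _ in arrays):
            empty = [
                pid for pid, (c, _) in zip(self.participant_ids, arrays) if c.size == 0
            ]
            raise NoFitError(f"no included trials for participants {empty}")
        self.n_participants = len(sessions)
        Tmax = max(c.size for c, _ in arrays)
        N = self.n_participants
        self.choices = np.zeros((N, Tmax), dtype=int)
        self.rewards = np.ones((N, Tmax))
        self.mask = np.zeros((N, Tmax), dtype=bool)
        for i, (c, r) in enumerate(arrays):
            self.choices[i, : c.size] = c
            self.rewards[i, : c.size] = r
            self.mask[i, : c.size] = True
        self.obs_index = [
            (pid, t)
            for pid, (c, _) in zip(self.participant_ids, arrays)
            for t in range(c.size)
        ]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        model: str = "counterfactual",
        group: str | None = None,
        better_options: dict[str, str] | None = None,
    ) -> "HierarchicalRW":
        """Build from a tidy trial table (the standard CSV schema), bandit rows only."""
        from .tasks import read_sessions_csv
        import io

        bdf = df[df["task"] == "bandit"]
        if bdf.empty:
            raise NoFitError("no bandit trials in the supplied table")
        buf = io.StringIO()
        bdf.to_csv(buf, index=False)
        buf.seek(0)
        sessions = read_sessions_csv(buf)
        if better_options:
            for s in sessions:
                better = better_options.get(s.participant_id)
                if better:
                    for t in s.trials:
                        if not t.is_catch:
                            t.correct_response = better
        return cls(sessions, model=model, group=group)

    # -- likelihood ---------------------------------------------------------

    def _natural(self, raw: np.ndarray) -> np.ndarray:
        """Map raw (..., P) to natural-scale parameters."""
        out = np.empty_like(raw)
        for j, scale in enumerate(self.link_scales):
            out[..., j] = _link(raw[..., j], scale)
        return out

    def _pointwise(self, nat: np.ndarray) -> np.ndarray:
        """Pointwise loglik (..., N, T) from natural parameters (..., N, P)."""
        if self.model == "posneg":
            return trajectory_loglik(
                self.model,
                self.choices,
                self.rewards,
                nat[..., 0],
                nat[..., 2],
                alpha_neg=nat[..., 1],
                mask=self.mask,
            )
        return trajectory_loglik(
            self.model, self.choices, self.rewards, nat[..., 0], nat[..., 1],
            mask=self.mask,
        )

    def _loglik_per_participant(self, raw: np.ndarray) -> np.ndarray:
        return self._pointwise(self._natural(raw)).sum(axis=-1)

    # -- sampling -----------------------------------------------------------

    def fit(
        self,
        chains: int = 4,
        warmup: int = 1000,
        draws: int = 1000,
        seed: int = 0,
        rhat_threshold: float = 1.1,
    ) -> "HierarchicalRWResults":
        """Sample the posterior; returns a results object with draws and diagnostics."""
        cfg = SamplerConfig(chains=chains, warmup=warmup, draws=draws, seed=seed)
        N, P = self.n_participants, len(self.param_names)
        seeds = np.random.SeedSequence(seed).spawn(chains)
        store_mu = np.empty((chains, draws, P))
        store_sigma = np.empty((chains, draws, P))
        store_z = np.empty((chains, draws, N, P))
        n_obs = int(self.mask.sum())
        store_ll = np.empty((chains, draws, n_obs))
        accept = np.zeros((chains, 3))

        for c in range(chains):
            rng = np.random.default_rng(seeds[c])
            mu = rng.normal(0, 0.3, size=P)
            log_sigma = np.log(rng.uniform(0.3, 0.7, size=P))
            z = rng.normal(0, 0.5, size=(N, P))
            s_z = np.full(N, 0.3)
            s_mu = np.full(P, 0.2)
            s_sig = np.full(P, 0.2)

            sigma = np.exp(log_sigma)
            ll_i = self._loglik_per_participant(mu + sigma * z)
            acc_counts = np.zeros(3)
            n_scalar = 0
            for it in range(warmup + draws):
                adapting = it < warmup
                gamma = min(0.25, 5.0 / (it + 10.0) ** 0.6)

                # participant-level block (vectorised accept/reject)
                z_prop = z + s_z[:, None] * rng.normal(size=(N, P))
                ll_prop = self._loglik_per_participant(mu + sigma * z_prop)
                logr = (
                    ll_prop
                    - ll_i
                    + 0.5 * (z**2).sum(axis=1)
                    - 0.5 * (z_prop**2).sum(axis=1)
                )
                acc = np.log(rng.uniform(size=N)) < logr
                z[acc] = z_prop[acc]
                ll_i = np.where(acc, ll_prop, ll_i)
                if adapting:
                    s_z *= np.exp(gamma * (acc - cfg.target_accept_block))
                acc_counts[0] += acc.mean()

                # hyperparameter scalar blocks
                total = ll_i.sum()
                for j in range(P):
                    mu_p = mu.copy()
                    mu_p[j] += s_mu[j] * rng.normal()
                    ll_p = self._loglik_per_participant(mu_p + sigma * z)
                    logr = (
                        ll_p.sum() - total - 0.5 * mu_p[j] ** 2 + 0.5 * mu[j] ** 2
                    )
                    a = np.log(rng.uniform()) < logr
                    if a:
                        mu = mu_p
                        ll_i = ll_p
                        total = ll_p.sum()
                    if adapting:
                        s_mu[j] *= np.exp(gamma * (a - cfg.target_accept_scalar))
                    acc_counts[1] += a
                    n_scalar += 1

                    ls_p = log_sigma.copy()
                    ls_p[j] += s_sig[j] * rng.normal()
                    sig_p = np.exp(ls_p)
                    ll_p = self._loglik_per_participant(mu + sig_p * z)
                    # half-Normal(1) prior on sigma, plus log-Jacobian
                    logr = (
                        ll_p.sum()
                        - total
                        - 0.5 * sig_p[j] ** 2
                        + 0.5 * sigma[j] ** 2
                        + ls_p[j]
                        - log_sigma[j]
                    )
                    a = np.log(rng.uniform()) < logr
                    if a:
                        log_sigma = ls_p
                        sigma = sig_p
                        ll_i = ll_p
                        total = ll_p.sum()
                    if adapting:
                        s_sig[j] *= np.exp(gamma * (a - cfg.target_accept_scalar))
                    acc_counts[2] += a

                if not adapting:
                    d = it - warmup
                    store_mu[c, d] = mu
                    store_sigma[c, d] = sigma
                    store_z[c, d] = z
                    pw = self._pointwise(self._natural(mu + sigma * z))
                    store_ll[c, d] = pw[self.mask]
            total_it = warmup + draws
            accept[c] = [
                acc_counts[0] / total_it,
                acc_counts[1] / max(1, n_scalar),
                acc_counts[2] / max(1, n_scalar),
            ]

        raw = store_mu[:, :, None, :] + store_sigma[:, :, None, :] * store_z
        natural = self._natural(raw)  # (C, D, N, P)
        return HierarchicalRWResults(
            model=self.model,
            group=self.group,
            param_names=self.param_names,
            participant_ids=self.participant_ids,
            obs_index=self.obs_index,
            mu=store_mu,
            sigma=store_sigma,
            natural=natural,
            pointwise_loglik=store_ll,
            accept_rates=accept,
            config=cfg,
            rhat_threshold=rhat_threshold,
            link_scales=self.link_scales,
            model_data=self,
        )


@dataclass
class HierarchicalRWResults:
    """Posterior draws, per-participant estimates and diagnostics for one group fit."""

    model: str
    group: str | None
    param_names: tuple[str, ...]
    participant_ids: list[str]
    obs_index: list[tuple[str, int]]
    mu: np.ndarray  # (C, D, P) raw-scale group locations
    sigma: np.ndarray  # (C, D, P) raw-scale group scales
    natural: np.ndarray  # (C, D, N, P) natural-scale individual parameters
    pointwise_loglik: np.ndarray  # (C, D, n_obs)
    accept_rates: np.ndarray
    config: SamplerConfig
    rhat_threshold: float = 1.1
    link_scales: tuple[float, ...] = (1.0, 10.0)
    model_data: HierarchicalRW | None = None
    _diagnostics: dict | None = field(default=None, repr=False)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def individual_means(self) -> pd.DataFrame:
        """Posterior mean of each natural-scale parameter per participant."""
        means = self.natural.mean(axis=(0, 1))  # (N, P)
        df = pd.DataFrame(means, columns=list(self.param_names))
        df.insert(0, "participant_id", self.participant_ids)
        if self.group is not None:
            df.insert(1, "group", self.group)
        return df

    def group_level_draws(self) -> dict[str, np.ndarray]:
        """Natural-scale group-location draws, (C, D) per parameter."""
        out = {}
        for j, (name, scale) in enumerate(zip(self.param_names, self.link_scales)):
            out[name] = scale * ndtr(self.mu[:, :, j])
        return out

    def flat_loglik(self) -> np.ndarray:
        """Pointwise log-likelihood as (chains*draws, n_obs)."""
        C, D, n = self.pointwise_loglik.shape
        return self.pointwise_loglik.reshape(C * D, n)

    # -- diagnostics ---------------------------------------------------------

    def diagnostics(self) -> dict:
        if self._diagnostics is None:
            import arviz as az

            posterior = {
                f"mu_{p}": self.mu[:, :, j] for j, p in enumerate(self.param_names)
            }
            posterior.update(
                {f"sigma_{p}": self.sigma[:, :, j] for j, p in enumerate(self.param_names)}
            )
            idata = az.from_dict(posterior=posterior)
            rhat = az.rhat(idata)
            ess = az.ess(idata)
            rhat_d = {v: float(rhat[v].values) for v in rhat.data_vars}
            ess_d = {v: float(ess[v].values) for v in ess.data_vars}
            max_rhat = max(rhat_d.values())
            converged = bool(max_rhat <= self.rhat_threshold)
            if not converged:
                warnings.warn(
                    f"split R-hat exceeds {self.rhat_threshold} "
                    f"(max {max_rhat:.3f}); inspect the chains",
                    stacklevel=2,
                )
            self._diagnostics = {
                "rhat": rhat_d,
                "max_rhat": max_rhat,
                "ess_bulk": ess_d,
                "min_ess_bulk": min(ess_d.values()),
                "accept_rates": self.accept_rates.tolist(),
                "converged": converged,
            }
        return self._diagnostics

    def loo(self) -> LooResult:
        """PSIS-LOO over all included trials of the group."""
        return compute_loo(self.flat_loglik())

    def summary(self) -> pd.DataFrame:
        """Group-level posterior summary on the natural scale plus diagnostics."""
        diag = self.diagnostics()
        rows = []
        gl = self.group_level_draws()
        for j, name in enumerate(self.param_names):
            loc = gl[name]
            rows.append(
                {
                    "parameter": f"group_{name}",
                    "mean": float(loc.mean()),
                    "sd": float(loc.std()),
                    "hdi_2.5%": float(np.quantile(loc, 0.025)),
                    "hdi_97.5%": float(np.quantile(loc, 0.975)),
                    "rhat": diag["rhat"][f"mu_{name}"],
                    "ess_bulk": diag["ess_bulk"][f"mu_{name}"],
                }
            )
            sig = self.sigma[:, :, j]
            rows.append(
                {
                    "parameter": f"sigma_{name} (raw scale)",
                    "mean": float(sig.mean()),
                    "sd": float(sig.std()),
                    "hdi_2.5%": float(np.quantile(sig, 0.025)),
                    "hdi_97.5%": float(np.quantile(sig, 0.975)),
                    "rhat": diag["rhat"][f"sigma_{name}"],
                    "ess_bulk": diag["ess_bulk"][f"sigma_{name}"],
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        """Serialisable point estimates + diagnostics (no draws)."""
        return {
            "model": self.model,
            "group": self.group,
            "param_names": list(self.param_names),
            "individual_means": self.individual_means().to_dict(orient="records"),
            "group_level_mean": {
                k: float(v.mean()) for k, v in self.group_level_draws().items()
            },
            "diagnostics": self.diagnostics(),
            "sampler": {
                "chains": self.config.chains,
                "warmup": self.config.warmup,
                "draws": self.config.draws,
                "seed": self.config.seed,
            },
        }


# ---------------------------------------------------------------------------
# model comparison

_MODEL_ORDER = {m: i for i, m in enumerate(MODELS)}


@dataclass
class ModelComparison:
    """Per-group LOOIC table with the best (lowest-LOOIC) model flagged."""

    table: pd.DataFrame

    def best(self, group: str | None = None) -> str:
        t = self.table
        if group is not None:
            t = t[t["group"] == group]
        return str(t.loc[t["best"], "model"].iloc[0])

    def wide(self) -> pd.DataFrame:
        """Rows = group, columns = model LOOICs (report layout)."""
        return self.table.pivot(index="group", columns="model", values="looic")


def compare_models(
    fits: dict[str, "HierarchicalRWResults"] | dict[str, dict[str, "HierarchicalRWResults"]],
) -> ModelComparison:
    """Compare >= 2 fitted models by LOOIC, per group.

    Accepts either ``{model_name: results}`` for a single group or
    ``{group: {model_name: results}}``.  Fits within a group must cover the
    identical observation set.  Ties are broken by parsimony (fewer
    parameters), then by canonical model order.
    """
    first = next(iter(fits.values()))
    grouped: dict[str | None, dict[str, HierarchicalRWResults]]
    if isinstance(first, dict):
        grouped = fits  # type: ignore[assignment]
    else:
        grouped = {first.group: fits}  # type: ignore[dict-item]

    rows = []
    for group, model_fits in grouped.items():
        if len(model_fits) < 2:
            raise ValueError(
                f"model comparison needs >= 2 fitted models, got {len(model_fits)} "
                f"for group {group!r}"
            )
        obs_sets = {name: r.obs_index for name, r in model_fits.items()}
        ref_name, ref_obs = next(iter(obs_sets.items()))
        for name, obs in obs_sets.items():
            if obs != ref_obs:
                raise ValueError(
                    f"cannot compare fits with mismatched observation sets: "
                    f"{name!r} vs {ref_name!r} for group {group!r}"
                )
        for name, r in model_fits.items():
            loo = r.loo()
            rows.append(
                {
                    "group": group,
                    "model": name,
                    "looic": loo.looic,
                    "se_looic": loo.se_looic,
                    "elpd_loo": loo.elpd_loo,
                    "max_pareto_k": float(loo.pareto_k.max()),
                    "n_bad_k": loo.n_bad_k,
                    "n_params": N_PARAMS.get(r.model, np.nan),
                }
            )
    table = pd.DataFrame(rows)
    table["_order"] = table["model"].map(lambda m: _MODEL_ORDER.get(m, 99))
    table = (
        table.sort_values(["group", "looic", "n_params", "_order"])
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    table["best"] = False
    for group in table["group"].unique():
        idx = table.index[table["group"] == group][0]
        table.loc[idx, "best"] = True
    return ModelComparison(table)
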