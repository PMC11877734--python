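"""Synthetic two-group cohorts: agents playing the three tasks.

Emulates the study population the analysis pipeline assumes — two groups of
52 participants whose bandit behaviour is produced by Rescorla-Wagner agents
with group-differing learning rates (defaults: autistic-group mean 0.39, SD
0.05; non-autistic 0.34, SD 0.06), occasional timeouts and occasional catch
errors — so every downstream component can be exercised and validated
(parameter recovery, model recovery, group tests) without any participant
data.

The single-cue and multi-cue responder is a cue-weight associative learner
(delta rule over the binary cue features with a softmax read-out).  No such
model is part of the bandit analysis; it exists only so accuracy summaries
have realistic inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import MODELS, AgentParams, choice_prob
from .tasks import (
    SessionData,
    generate_bandit_session,
    generate_multicue_session,
    generate_singlecue_session,
)

__all__ = [
    "CohortSpec",
    "CohortData",
    "ResponderParams",
    "simulate_agent",
    "simulate_cohort",
    "recovery_experiment",
]


@dataclass(frozen=True)
class ResponderParams:
    """Cue-weight associative learner for the single-/multi-cue tasks (synthetic only)."""

    learning_rate: float = 0.3
    inverse_temperature: float = 2.0


@dataclass(frozen=True)
class CohortSpec:
    """Generating conditions for a synthetic cohort.

    ``group_alpha`` maps group label to (mean, SD) of a normal distribution
    truncated to (0, 1) from which true learning rates are drawn; ``beta``
    is drawn from Normal(3, 0.5) truncated to (0, 10).
    """

    seed: int
    n_per_group: int = 52
    model: str = "counterfactual"
    group_alpha: dict = field(
        default_factory=lambda: {
            "autistic": (0.39, 0.05),
            "non_autistic": (0.34, 0.06),
        }
    )
    beta_mean: float = 3.0
    beta_sd: float = 0.5
    timeout_prob: float = 0.02
    catch_error_prob: float = 0.02
    p_contingency: float = 0.7
    n_bandit_trials: int = 20
    tasks: tuple[str, ...] = ("bandit",)

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        for g, (m, sd) in self.group_alpha.items():
            if not 0 < m < 1 or sd < 0:
                raise ValueError(f"invalid alpha distribution for group {g!r}")
        for t in self.tasks:
            if t not in ("bandit", "single_cue", "multi_cue"):
                raise ValueError(f"unknown task {t!r}")


@dataclass
class CohortData:
    """Roster with true parameters plus all generated-and-played sessions."""

    spec: CohortSpec
    roster: pd.DataFrame
    sessions: list[SessionData]

    def sessions_for(self, task: str, group: str | None = None) -> list[SessionData]:
        pids = (
            set(self.roster.loc[self.roster["group"] == group, "participant_id"])
            if group is not None
            else None
        )
        return [
            s
            for s in self.sessions
            if s.task == task and (pids is None or s.participant_id in pids)
        ]

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.roster["group"]))

    def trials_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.sessions], ignore_index=True)

    def long_table(self) -> pd.DataFrame:
        """Model-ready long table (group + condition attached, catch/timeouts dropped)."""
        from .stats import make_long_table

        cmap = {}
        for s in self.sessions:
            if s.task == "single_cue":
                cmap[s.participant_id] = {"condition": s.metadata.get("condition", "")}
        return make_long_table(self.trials_frame(), self.roster, condition_map=None)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Rejection sampling; degenerate SD returns the (clipped) mean."""
    if sd == 0:
        return float(np.clip(mean, lo + 1e-9, hi - 1e-9))
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


def simulate_agent(
    params: AgentParams | ResponderParams,
    session_design: SessionData,
    seed: int,
    timeout_prob: float = 0.0,
    catch_error_prob: float = 0.0,
) -> SessionData:
    """Play a session design with an agent; returns the session with responses.

    Bandit designs require :class:`AgentParams` (choices sampled from the
    softmax over running values, values updated per model with the realised
    rewards); single-/multi-cue designs require :class:`ResponderParams`.
    Timeouts are injected per experimental trial with ``timeout_prob`` (no
    value update); catch responses are correct with probability
    ``1 - catch_error_prob``.
    """
    task = session_design.task
    if task == "bandit" and not isinstance(params, AgentParams):
        raise ValueError("bandit sessions require AgentParams")
    if task in ("single_cue", "multi_cue") and not isinstance(params, ResponderParams):
        raise ValueError(f"{task} sessions require ResponderParams")
    rng = np.random.default_rng(seed)
    session = SessionData(
        participant_id=session_design.participant_id,
        task=task,
        trials=[replace_trial(t) for t in session_design.trials],
        metadata=dict(session_design.metadata),
    )

    if task == "bandit":
        V = np.zeros(2)
        options = None
        for t in session.trials:
            if t.is_catch:
                _respond_catch(t, rng, catch_error_prob)
                continue
            options = t.presented_options
            if rng.random() < timeout_prob:
                t.response = "timeout"
                t.score()
                continue
            p_a = choice_prob(V[0], V[1], params.beta)
            c = 0 if rng.random() < p_a else 1
            t.response = options[c]
            t.score()
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
        return session

    # associative responder over +/-1-coded cue features
    w = np.zeros(4)
    for t in session.trials:
        if t.is_catch:
            _respond_catch(t, rng, catch_error_prob)
            continue
        if rng.random() < timeout_prob:
            t.response = "timeout"
            t.score()
            continue
        x = 2.0 * np.asarray(t.cue_levels, dtype=float) - 1.0
        v = float(w @ x) / 4.0
        p_first = 1.0 / (1.0 + np.exp(-params.inverse_temperature * v))
        first, second = t.presented_options  # ("high","low") or ("periodA","periodB")
        t.response = first if rng.random() < p_first else second
        t.score()
        y = 1.0 if t.outcome == first else -1.0
        w += params.learning_rate * (y - v) * x / 4.0
    return session


def replace_trial(t):
    from dataclasses import replace as _replace

    return _replace(t)


def _respond_catch(t, rng: np.random.Generator, catch_error_prob: float) -> None:
    if rng.random() < catch_error_prob:
        wrong = [o for o in t.presented_options if o != t.correct_response]
        t.response = str(rng.choice(wrong)) if wrong else t.correct_response
    else:
        t.response = t.correct_response
    t.score()


def _draw_params(spec: CohortSpec, group: str, rng: np.random.Generator) -> AgentParams:
    mean, sd = spec.group_alpha[group]
    beta = _truncated_normal(rng, spec.beta_mean, spec.beta_sd, 0.0, 10.0)
    if spec.model == "posneg":
        return AgentParams(
            model="posneg",
            alpha_pos=_truncated_normal(rng, mean, sd, 0.0, 1.0),
            alpha_neg=_truncated_normal(rng, mean, sd, 0.0, 1.0),
            beta=beta,
        )
    return AgentParams(
        model=spec.model,
        alpha=_truncated_normal(rng, mean, sd, 0.0, 1.0),
        beta=beta,
    )


def simulate_cohort(spec: CohortSpec) -> CohortData:
    """Draw per-participant parameters and play every requested task.

    Deterministic from ``spec.seed`` via per-participant child seeds.
    """
    root = np.random.SeedSequence(spec.seed)
    group_seqs = root.spawn(len(spec.group_alpha))
    roster_rows = []
    sessions: list[SessionData] = []
    responder = ResponderParams()
    for g_idx, (group, gseq) in enumerate(zip(spec.group_alpha, group_seqs)):
        part_seqs = gseq.spawn(spec.n_per_group)
        for i, pseq in enumerate(part_seqs):
            pid = f"{group}_{i + 1:03d}"
            child = pseq.generate_state(8)
            rng = np.random.default_rng(child[0])
            params = _draw_params(spec, group, rng)
            row = {"participant_id": pid, "group": group, "model": spec.model}
            row.update({k: v for k, v in params.to_dict().items() if k != "model"})
            roster_rows.append(row)
            if "bandit" in spec.tasks:
                design = generate_bandit_session(
                    int(child[1] % 2**31),
                    p_contingency=spec.p_contingency,
                    n_trials=spec.n_bandit_trials,
                    participant_id=pid,
                )
                sessions.append(
                    simulate_agent(
                        params,
                        design,
                        int(child[2] % 2**31),
                        timeout_prob=spec.timeout_prob,
                        catch_error_prob=spec.catch_error_prob,
                    )
                )
            if "single_cue" in spec.tasks:
                for k, cond in enumerate(("deterministic", "probabilistic")):
                    design = generate_singlecue_session(
                        cond, int(child[3 + k] % 2**31), participant_id=pid
                    )
                    sessions.append(
                        simulate_agent(
                            responder,
                            design,
                            int(child[5] % 2**31) + k,
                            timeout_prob=spec.timeout_prob,
                            catch_error_prob=spec.catch_error_prob,
                        )
                    )
            if "multi_cue" in spec.tasks:
                design = generate_multicue_session(
                    int(child[6] % 2**31), participant_id=pid
                )
                sessions.append(
                    simulate_agent(
                        responder,
                        design,
                        int(child[7] % 2**31),
                        timeout_prob=spec.timeout_prob,
                        catch_error_prob=spec.catch_error_prob,
                    )
                )
    roster = pd.DataFrame(roster_rows)
    return CohortData(spec=spec, roster=roster, sessions=sessions)


def recovery_experiment(
    spec: CohortSpec,
    models: tuple[str, ...] = MODELS,
    n_replicates: int = 1,
    sampler: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Simulate-fit-compare validation harness for the whole pipeline.

    Per replicate: simulate a cohort from ``spec`` (bandit task), apply the
    exclusion rules, fit every requested model hierarchically per group,
    select by LOOIC, and score (i) whether the generating model was selected,
    (ii) correlation and bias of recovered (posterior-mean) vs true learning
    rates, (iii) the group-difference t-test.  Fit failures are recorded per
    replicate, not fatal.  A 0-replicate request returns an empty report.
    """
    from dataclasses import replace as dc_replace

    from .fitting import HierarchicalRW, apply_exclusions, compare_models
    from .stats import independent_ttest

    sampler = dict(chains=2, warmup=500, draws=500) | (sampler or {})
    base_seed = spec.seed if seed is None else seed
    rep_seqs = np.random.SeedSequence(base_seed).spawn(max(n_replicates, 1))
    alpha_col = "alpha_pos" if spec.model == "posneg" else "alpha"

    replicates = []
    for r in range(n_replicates):
        states = rep_seqs[r].generate_state(2)
        rep_spec = dc_replace(spec, seed=int(states[0] % 2**31))
        fit_seed = int(states[1] % 2**31)
        entry: dict = {"replicate": r, "errors": []}
        try:
            cohort = simulate_cohort(rep_spec)
            sessions, excl = apply_exclusions(cohort.sessions_for("bandit"))
            entry["n_excluded"] = excl["n_excluded"]
            fits_by_group: dict = {}
            selected: dict = {}
            for group in cohort.groups:
                gpids = set(
                    cohort.roster.loc[
                        cohort.roster["group"] == group, "participant_id"
                    ]
                )
                gs = [s for s in sessions if s.participant_id in gpids]
                fits = {}
                for m in models:
                    fits[m] = HierarchicalRW(gs, model=m, group=group).fit(
                        seed=fit_seed, **sampler
                    )
                if len(fits) >= 2:
                    selected[group] = compare_models(fits).best()
                fits_by_group[group] = fits
            entry["selected_model"] = selected
            entry["generating_model_selected"] = {
                g: (sel == spec.model) for g, sel in selected.items()
            }

            # parameter recovery on the generating model's fit
            true_alpha, est_alpha, group_means = [], [], {}
            for group in cohort.groups:
                fit = fits_by_group[group].get(spec.model)
                if fit is None:
                    continue
                means = fit.individual_means().set_index("participant_id")
                truth = cohort.roster.set_index("participant_id")
                common = [p for p in means.index if p in truth.index]
                true_alpha.extend(truth.loc[common, alpha_col].tolist())
                est = means.loc[common, alpha_col if alpha_col in means else "alpha"]
                est_alpha.extend(est.tolist())
                group_means[group] = est.to_numpy()
            ta, ea = np.asarray(true_alpha), np.asarray(est_alpha)
            if ta.size >= 3:
                entry["alpha_corr"] = float(np.corrcoef(ta, ea)[0, 1])
                entry["alpha_bias"] = float(np.mean(ea - ta))
            if len(group_means) == 2:
                (g1, v1), (g2, v2) = group_means.items()
                t, dfree, p = independent_ttest(v1, v2)
                entry["group_ttest"] = {"groups": [g1, g2], "t": t, "df": dfree, "p": p}
                entry["recovered_group_means"] = {
                    g1: float(np.mean(v1)),
                    g2: float(np.mean(v2)),
                }
        except Exception as exc:  # recorded, not fatal
            entry["errors"].append(f"{type(exc).__name__}: {exc}")
        replicates.append(entry)

    report: dict = {
        "spec": {
            "n_per_group": spec.n_per_group,
            "model": spec.model,
            "group_alpha": dict(spec.group_alpha),
            "n_bandit_trials": spec.n_bandit_trials,
            "seed": base_seed,
        },
        "n_replicates": n_replicates,
        "replicates": replicates,
    }
    if n_replicates > 0:
        ok = [r for r in replicates if not r["errors"]]
        if ok:
            sel = [
                all(r.get("generating_model_selected", {}).values()) for r in ok
            ]
            report["summary"] = {
                "n_ok": len(ok),
                "generating_model_selection_rate": float(np.mean(sel)),
                "mean_alpha_corr": float(
                    np.mean([r["alpha_corr"] for r in ok if "alpha_corr" in r])
                )
                if any("alpha_corr" in r for r in ok)
                else None,
                "ttest_rejection_rate": float(
                    np.mean(
                        [r["group_ttest"]["p"] < 0.05 for r in ok if "group_ttest" in r]
                    )
                )
                if any("group_ttest" in r for r in ok)
                else None,
            }
    return report
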