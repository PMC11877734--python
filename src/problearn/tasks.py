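"""Generative designs for the three probabilistic-learning tasks.

Three tasks are modelled:

* **single-cue** — art pieces carry one target feature that predicts an art
  period either deterministically (100%) or probabilistically (75%);
  100 experimental trials, 50 per period, plus 8 catch trials.
* **multi-cue** — 16 stimuli formed by the Cartesian product of four binary
  cues, each with a fixed probability of receiving a "high" rating; the set
  is repeated 8 times (128 trials, blocked by set and shuffled within set),
  plus 8 catch trials.
* **bandit** — a two-armed bandit in which one option is rewarded on 70% of
  trials with strictly anti-correlated outcomes (exactly one option rewarded
  per trial); 20 experimental trials plus 2 catch trials, no reversals.

Sessions are fully reproducible from an integer seed and serialise to a tidy
one-row-per-trial CSV with a JSON metadata side-car.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpec",
    "TrialRecord",
    "SessionData",
    "MULTICUE_P_HIGH_TABLE",
    "build_multicue_stimuli",
    "generate_multicue_session",
    "generate_singlecue_session",
    "generate_bandit_session",
    "write_sessions_csv",
    "read_sessions_csv",
]

#: Design table for the multi-cue task: (C1, C2, C3, C4) -> p(high rating).
#: Stimuli with p(high) in [0.4, 0.6] are "ambiguous", the rest "unambiguous".
MULTICUE_P_HIGH_TABLE: tuple[tuple[tuple[int, int, int, int], float], ...] = (
    ((0, 0, 0, 0), 0.100),
    ((0, 0, 0, 1), 0.133),
    ((0, 0, 1, 0), 0.166),
    ((0, 1, 0, 0), 0.200),
    ((1, 0, 0, 0), 0.400),
    ((1, 0, 0, 1), 0.429),
    ((1, 0, 1, 0), 0.458),
    ((1, 1, 0, 0), 0.487),
    ((1, 1, 0, 1), 0.516),
    ((1, 1, 1, 0), 0.545),
    ((0, 0, 1, 1), 0.574),
    ((1, 0, 1, 1), 0.600),
    ((0, 1, 1, 0), 0.800),
    ((0, 1, 0, 1), 0.833),
    ((0, 1, 1, 1), 0.866),
    ((1, 1, 1, 1), 0.900),
)

AMBIGUOUS_BAND = (0.4, 0.6)

CSV_COLUMNS = [
    "participant_id",
    "task",
    "trial_index",
    "stimulus_id",
    "cue_levels",
    "outcome",
    "response",
    "correct",
    "is_catch",
    "phase",
    "block",
]


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus: its cue levels, outcome contingency and condition label."""

    stimulus_id: int | str
    cue_levels: tuple[int, ...]
    p_high: float
    condition: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError(f"p_high must lie in [0, 1], got {self.p_high}")


@dataclass
class TrialRecord:
    """One trial of any task.

    ``response`` is ``None`` for an unplayed design trial, ``"timeout"`` for a
    timed-out trial, otherwise the chosen option.  ``correct`` follows the
    most-probable-outcome rule and is ``None`` when there is no scoreable
    response.
    """

    participant_id: str
    task: str
    trial_index: int
    stimulus_id: int | str | None
    cue_levels: tuple[int, ...] | None
    presented_options: tuple[str, ...]
    outcome: str
    correct_response: str
    response: str | None = None
    correct: bool | None = None
    is_catch: bool = False
    phase: str = ""
    block: int = 1

    def score(self) -> None:
        """Fill ``correct`` from ``response`` using the most-probable-outcome rule."""
        if self.response is None or self.response == "timeout":
            self.correct = None
        else:
            self.correct = self.response == self.correct_response


@dataclass
class SessionData:
    """An ordered sequence of trials for one participant and task."""

    participant_id: str
    task: str
    trials: list[TrialRecord]
    metadata: dict = field(default_factory=dict)

    @property
    def experimental_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if not t.is_catch]

    @property
    def catch_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.is_catch]

    @property
    def included_trials(self) -> list[TrialRecord]:
        """Experimental trials with a scoreable (non-timeout) response."""
        return [
            t
            for t in self.experimental_trials
            if t.response is not None and t.response != "timeout"
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "participant_id": t.participant_id,
                    "task": t.task,
                    "trial_index": t.trial_index,
                    "stimulus_id": "" if t.stimulus_id is None else t.stimulus_id,
                    "cue_levels": ""
                    if t.cue_levels is None
                    else "|".join(str(b) for b in t.cue_levels),
                    "outcome": t.outcome,
                    "response": "" if t.response is None else t.response,
                    "correct": "" if t.correct is None else t.correct,
                    "is_catch": t.is_catch,
                    "phase": t.phase,
                    "block": t.block,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _interleave_catch(
    exp_trials: list[TrialRecord], catch_trials: list[TrialRecord], rng: np.random.Generator
) -> list[TrialRecord]:
    """Insert catch trials at uniformly drawn inter-trial slots (no replacement)."""
    n_slots = len(exp_trials) + 1
    positions = sorted(rng.choice(n_slots, size=len(catch_trials), replace=False))
    out: list[TrialRecord] = []
    ci = 0
    for i in range(len(exp_trials) + 1):
        while ci < len(positions) and positions[ci] == i:
            out.append(catch_trials[ci])
            ci += 1
        if i < len(exp_trials):
            out.append(exp_trials[i])
    for idx, t in enumerate(out, start=1):
        t.trial_index = idx
    return out


def _assign_phase(trials: Iterable[TrialRecord], n_experimental: int) -> None:
    """Early = first half of experimental trials; catch trials excluded from the count."""
    half = n_experimental // 2
    exp_seen = 0
    for t in trials:
        if not t.is_catch:
            exp_seen += 1
            t.phase = "early" if exp_seen <= half else "late"
        else:
            t.phase = "early" if exp_seen < half else "late"


def build_multicue_stimuli(
    cue_assignment: Sequence[int] = (0, 1, 2, 3),
) -> list[StimulusSpec]:
    """Build the 16 multi-cue stimuli from the design table.

    Parameters
    ----------
    cue_assignment
        Permutation mapping the four physical cue slots to the design columns
        C1..C4 (``cue_levels[k]`` displays design column ``cue_assignment[k]``).
        Relabelling the physical cues permutes only the presented levels; the
        design-column -> p(high) map is untouched.
    """
    assignment = tuple(int(c) for c in cue_assignment)
    if sorted(assignment) != [0, 1, 2, 3]:
        raise ValueError(
            f"cue_assignment must be a permutation of (0, 1, 2, 3), got {cue_assignment}"
        )
    stimuli = []
    for sid, (design_bits, p_high) in enumerate(MULTICUE_P_HIGH_TABLE, start=1):
        levels = tuple(design_bits[assignment[k]] for k in range(4))
        condition = (
            "ambiguous"
            if AMBIGUOUS_BAND[0] <= p_high <= AMBIGUOUS_BAND[1]
            else "unambiguous"
        )
        stimuli.append(
            StimulusSpec(
                stimulus_id=sid, cue_levels=levels, p_high=p_high, condition=condition
            )
        )
    return stimuli


def generate_multicue_session(
    seed: int,
    n_repeats: int = 8,
    participant_id: str = "P000",
    cue_assignment: Sequence[int] | None = None,
    n_catch: int = 8,
    p_high_override: dict[int, float] | None = None,
) -> SessionData:
    """Generate one multi-cue session: 16*n_repeats experimental trials + catch trials.

    Presentation is blocked by set (each block one shuffled pass over the 16
    stimuli).  Each trial's rating is drawn by comparing p(high) with a uniform
    random number.  ``p_high_override`` substitutes contingencies for selected
    stimulus ids (testing hook for degenerate probabilities).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    if cue_assignment is None:
        cue_assignment = tuple(int(x) for x in rng.permutation(4))
    stimuli = build_multicue_stimuli(cue_assignment)
    if p_high_override:
        stimuli = [
            StimulusSpec(
                s.stimulus_id,
                s.cue_levels,
                p_high_override.get(int(s.stimulus_id), s.p_high),
                s.condition,
            )
            for s in stimuli
        ]
    by_id = {int(s.stimulus_id): s for s in stimuli}

    exp: list[TrialRecord] = []
    for block in range(1, n_repeats + 1):
        order = rng.permutation(16)
        for j in order:
            s = stimuli[j]
            outcome = "high" if s.p_high > rng.random() else "low"
            most_probable = "high" if s.p_high > 0.5 else "low"
            exp.append(
                TrialRecord(
                    participant_id=participant_id,
                    task="multi_cue",
                    trial_index=0,
                    stimulus_id=s.stimulus_id,
                    cue_levels=s.cue_levels,
                    presented_options=("high", "low"),
                    outcome=outcome,
                    correct_response=most_probable,
                    block=block,
                )
            )
    catch = []
    for _ in range(n_catch):
        label = str(rng.choice(["high", "low"]))
        catch.append(
            TrialRecord(
                participant_id=participant_id,
                task="multi_cue",
                trial_index=0,
                stimulus_id=None,
                cue_levels=None,
                presented_options=("high", "low"),
                outcome=label,
                correct_response=label,
                is_catch=True,
            )
        )
    trials = _interleave_catch(exp, catch, rng)
    _assign_phase(trials, len(exp))
    meta = {
        "seed": int(seed),
        "task": "multi_cue",
        "cue_assignment": list(cue_assignment),
        "n_repeats": int(n_repeats),
        "p_high": {int(k): float(v.p_high) for k, v in by_id.items()},
    }
    return SessionData(participant_id, "multi_cue", trials, meta)


def generate_singlecue_session(
    condition: str,
    seed: int,
    participant_id: str = "P000",
    n_trials: int = 100,
    n_catch: int = 8,
) -> SessionData:
    """Generate one single-cue session (100 trials, 50 per art period).

    One of four binary features is the target.  In the deterministic condition
    the target level matches the period on every trial; in the probabilistic
    condition on exactly 75% of trials (fixed count, 37/38 split between
    periods at random).  Non-target features are i.i.d. uniform bits.
    """
    if condition not in ("deterministic", "probabilistic"):
        raise ValueError(
            f"condition must be 'deterministic' or 'probabilistic', got {condition!r}"
        )
    if n_trials % 4 != 0:
        raise ValueError("n_trials must be divisible by 4")
    rng = np.random.default_rng(seed)
    target_feature = int(rng.integers(4))
    periods = np.array(["periodA"] * (n_trials // 2) + ["periodB"] * (n_trials // 2))
    rng.shuffle(periods)

    # Congruency assignment: fixed 75% count in the probabilistic condition.
    congruent = np.ones(n_trials, dtype=bool)
    if condition == "probabilistic":
        n_congruent = int(round(0.75 * n_trials))
        n_incon = n_trials - n_congruent
        # split incongruent trials as evenly as possible between periods,
        # the odd one assigned to a random period
        n_incon_a = n_incon // 2 + (int(rng.integers(2)) if n_incon % 2 else 0)
        n_incon_b = n_incon - n_incon_a
        idx_a = np.flatnonzero(periods == "periodA")
        idx_b = np.flatnonzero(periods == "periodB")
        congruent[rng.choice(idx_a, size=n_incon_a, replace=False)] = False
        congruent[rng.choice(idx_b, size=n_incon_b, replace=False)] = False

    exp: list[TrialRecord] = []
    for i in range(n_trials):
        period = str(periods[i])
        # target level 1 codes for periodA
        level_for_period = 1 if period == "periodA" else 0
        target_level = level_for_period if congruent[i] else 1 - level_for_period
        cues = [int(b) for b in rng.integers(0, 2, size=4)]
        cues[target_feature] = target_level
        # most probable outcome given the target-feature level
        most_probable = "periodA" if target_level == 1 else "periodB"
        exp.append(
            TrialRecord(
                participant_id=participant_id,
                task="single_cue",
                trial_index=0,
                stimulus_id=f"{condition[:4]}_{i + 1}",
                cue_levels=tuple(cues),
                presented_options=("periodA", "periodB"),
                outcome=period,
                correct_response=most_probable,
            )
        )
    catch = []
    for _ in range(n_catch):
        label = str(rng.choice(["periodA", "periodB"]))
        catch.append(
            TrialRecord(
                participant_id=participant_id,
                task="single_cue",
                trial_index=0,
                stimulus_id=None,
                cue_levels=None,
                presented_options=("periodA", "periodB"),
                outcome=label,
                correct_response=label,
                is_catch=True,
            )
        )
    trials = _interleave_catch(exp, catch, rng)
    _assign_phase(trials, len(exp))
    meta = {
        "seed": int(seed),
        "task": "single_cue",
        "condition": condition,
        "target_feature": target_feature,
        "predictive_strength": 1.0 if condition == "deterministic" else 0.75,
        "n_congruent": int(congruent.sum()),
    }
    return SessionData(participant_id, "single_cue", trials, meta)


def generate_bandit_session(
    seed: int,
    p_contingency: float = 0.7,
    n_trials: int = 20,
    participant_id: str = "P000",
    n_catch: int = 2,
) -> SessionData:
    """Generate one two-armed-bandit session.

    One option (chosen uniformly at random) is the "better" option and carries
    the reward with probability ``p_contingency`` on each trial, independently;
    outcomes are anti-correlated (exactly one option rewarded per trial).  The
    contingency is constant — no reversals.
    """
    if not 0.0 < p_contingency <= 1.0:
        raise ValueError(f"p_contingency must lie in (0, 1], got {p_contingency}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    options = ("optA", "optB")
    better = options[int(rng.integers(2))]
    worse = options[1] if better == options[0] else options[0]

    exp: list[TrialRecord] = []
    for _ in range(n_trials):
        rewarded = better if rng.random() < p_contingency else worse
        exp.append(
            TrialRecord(
                participant_id=participant_id,
                task="bandit",
                trial_index=0,
                stimulus_id="pair",
                cue_levels=None,
                presented_options=options,
                outcome=rewarded,
                correct_response=better,
            )
        )
    catch = []
    for _ in range(n_catch):
        label = str(rng.choice(options))
        catch.append(
            TrialRecord(
                participant_id=participant_id,
                task="bandit",
                trial_index=0,
                stimulus_id=None,
                cue_levels=None,
                presented_options=options,
                outcome=label,
                correct_response=label,
                is_catch=True,
            )
        )
    trials = _interleave_catch(exp, catch, rng)
    _assign_phase(trials, len(exp))
    meta = {
        "seed": int(seed),
        "task": "bandit",
        "better_option": better,
        "p_contingency": float(p_contingency),
        "n_trials": int(n_trials),
    }
    return SessionData(participant_id, "bandit", trials, meta)


def write_sessions_csv(
    sessions: Iterable[SessionData], csv_path: str | Path, metadata_path: str | Path | None = None
) -> pd.DataFrame:
    """Write sessions as one tidy CSV plus an optional JSON metadata side-car."""
    sessions = list(sessions)
    df = pd.concat([s.to_frame() for s in sessions], ignore_index=True)
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(csv_path, index=False)
    if metadata_path is not None:
        meta = {
            f"{s.participant_id}:{s.task}:{s.metadata.get('condition', '')}": s.metadata
            for s in sessions
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=2))
    return df


def _record_from_row(row: pd.Series) -> TrialRecord:
    cue_levels = None
    if isinstance(row["cue_levels"], str) and row["cue_levels"]:
        cue_levels = tuple(int(b) for b in row["cue_levels"].split("|"))
    stimulus_id = row["stimulus_id"]
    if pd.isna(stimulus_id) or stimulus_id == "":
        stimulus_id = None
    response = row["response"]
    if pd.isna(response) or response == "":
        response = None
    correct = row["correct"]
    if pd.isna(correct) or correct == "":
        correct = None
    else:
        correct = str(correct).lower() in ("true", "1")
    task = row["task"]
    options = {
        "bandit": ("optA", "optB"),
        "single_cue": ("periodA", "periodB"),
        "multi_cue": ("high", "low"),
    }[task]
    rec = TrialRecord(
        participant_id=str(row["participant_id"]),
        task=task,
        trial_index=int(row["trial_index"]),
        stimulus_id=stimulus_id,
        cue_levels=cue_levels,
        presented_options=options,
        outcome=str(row["outcome"]),
        correct_response="",
        response=response,
        correct=correct,
        is_catch=bool(row["is_catch"]) if not isinstance(row["is_catch"], str) else row["is_catch"].lower() == "true",
        phase=str(row["phase"]),
        block=int(row["block"]),
    )
    return rec


def read_sessions_csv(
    csv_path: str | Path, metadata_path: str | Path | None = None
) -> list[SessionData]:
    """Read sessions back from the tidy CSV schema (one SessionData per participant+task)."""
    df = pd.read_csv(csv_path, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV is missing required columns: {missing}")
    meta_all: dict = {}
    if metadata_path is not None and Path(metadata_path).exists():
        meta_all = json.loads(Path(metadata_path).read_text())
    sessions = []
    for (pid, task), grp in df.groupby(["participant_id", "task"], sort=False):
        grp = grp.sort_values("trial_index")
        trials = [_record_from_row(row) for _, row in grp.iterrows()]
        # reconstruct bandit correct_response from metadata when available
        meta = {}
        for key, m in meta_all.items():
            if key.startswith(f"{pid}:{task}"):
                meta = m
                break
        if task == "bandit" and "better_option" in meta:
            for t in trials:
                if not t.is_catch:
                    t.correct_response = meta["better_option"]
        for t in trials:
            if t.is_catch:
                t.correct_response = t.outcome
        sessions.append(SessionData(str(pid), str(task), trials, meta))
    return sessions
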