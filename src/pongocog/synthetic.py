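"""Seeded session plans and simulated trial tables for both experiments.

The generators mirror the two task designs:

* **Dot-probe** — every stimulus pair is probed exactly twice across a
  subject's sessions, once congruently (probe behind the large-flange or
  symmetrised face) and once incongruently, in seeded random order with
  probe sides balanced within each session.  Reaction times follow a
  Student-t location-scale model with session-level intercept variation, the
  generative mirror of the robust regression fitted downstream, plus two
  contamination processes for the filtering stage to remove: anticipatory
  taps (uniform 50-199 ms) and slow, distracted responses (a large positive
  shift).
* **Preference** — each subject completes six sessions in two contiguous
  three-session blocks (flanged stimuli coded red in one block, green in the
  other; block order counterbalanced across subjects), each session opening
  with 8 forced trials (4 per colour) before 16 free choices.  The two
  choice dots sit at opposite ends of a diameter of a circle around the
  screen centre, so the flanged dot's vertical position is ``R cos(phi)``
  with a uniform angle, rescaled to at most +/-0.35 of screen height
  (positive = lower on screen).  Choices are Bernoulli draws from a logistic
  model with colour, order and height effects and subject / session-within-
  subject / colour-slope random effects.

All outputs are plain pandas DataFrames, byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "StimulusPair",
    "DotProbeGenParams",
    "ChoiceGenParams",
    "default_flange_pairs",
    "default_symmetry_pairs",
    "schedule_dotprobe",
    "simulate_dotprobe",
    "make_repetition_plan",
    "schedule_preference",
    "simulate_choices",
]

RT_FLOOR_MS = 50.0
HEIGHT_RADIUS = 0.35


@dataclass(frozen=True)
class StimulusPair:
    """One stimulus pair: two versions of the same face.

    ``width_diff`` (px) is the absolute width difference between the
    enlarged and reduced flange versions; it exists only for the flange
    task (symmetry pairs differ in mirroring, not width).
    """

    pair_id: str
    task: str  # "flange" | "symmetry"
    width_diff: float | None = None

    def __post_init__(self) -> None:
        if self.task not in ("flange", "symmetry"):
            raise ValueError(f"unknown task {self.task!r}")
        if (self.width_diff is not None) != (self.task == "flange"):
            raise ValueError("width_diff must be present iff task == 'flange'")
        if self.width_diff is not None and self.width_diff < 0:
            raise ValueError("width_diff must be nonnegative")


def default_flange_pairs(n: int = 72, seed: int = 0) -> list[StimulusPair]:
    """Flange-task pairs with a +/-15% width manipulation.

    Width differences are drawn uniformly over 20-80 px, a plausible spread
    for flange widths of roughly 70-260 px under a proportional resize.
    """
    rng = np.random.default_rng(seed)
    diffs = rng.uniform(20.0, 80.0, size=n)
    return [StimulusPair(f"F{i + 1:03d}", "flange", float(d)) for i, d in enumerate(diffs)]


def default_symmetry_pairs(n: int = 80) -> list[StimulusPair]:
    """Symmetry-task pairs (original face vs. symmetrised version)."""
    return [StimulusPair(f"S{i + 1:03d}", "symmetry") for i in range(n)]


@dataclass(frozen=True)
class DotProbeGenParams:
    """Truth values for the dot-probe RT generator (all in ms).

    Effects are on the +/-1 sum-coded scale, so the condition-level gap is
    twice the coefficient.  ``resid_df`` must exceed 2 so the Student-t
    residual has finite variance.
    """

    intercept_ms: float = 700.0
    b_congruent_ms: float = 0.0
    b_left_ms: float = 0.0
    session_sd_ms: float = 30.0
    resid_scale_ms: float = 80.0
    resid_df: float = 5.0
    p_anticipatory: float = 0.05
    p_slow: float = 0.05
    slow_shift_ms: float = 1500.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_anticipatory <= 1.0 and 0.0 <= self.p_slow <= 1.0):
            raise ValueError("contamination probabilities must be in [0, 1]")
        if self.resid_df <= 2:
            raise ValueError("resid_df must exceed 2 so the residual variance exists")
        if self.resid_scale_ms <= 0 or self.session_sd_ms < 0 or self.slow_shift_ms <= 0:
            raise ValueError("scale parameters out of range")


@dataclass(frozen=True)
class ChoiceGenParams:
    """Truth values for the preference-choice generator (logit scale).

    Defaults reproduce the study's observed regime: no net category
    preference, a red-colour bias (green-coded flanged stimuli chosen less),
    a weak order effect and a strong energy-saving height effect (lower dot
    chosen more).  Colour and order are +/-1 sum-coded (green = +1,
    red-block-first = +1); height is in screen fractions.
    """

    logit_intercept: float = 0.0
    b_green: float = -0.40
    b_order: float = -0.128
    b_height: float = 4.05
    subject_sd: float = 0.25
    session_sd: float = 0.25
    colour_slope_sd: float = 0.15

    def __post_init__(self) -> None:
        if min(self.subject_sd, self.session_sd, self.colour_slope_sd) < 0:
            raise ValueError("random-effect sds must be nonnegative")


def schedule_dotprobe(
    pairs: list[StimulusPair],
    n_sessions: int,
    trials_per_session: int,
    seed: int,
    subject_id: str = "subj",
) -> pd.DataFrame:
    """Randomised trial plan probing every pair once per congruence level.

    Requires ``n_sessions * trials_per_session == 2 * len(pairs)``.  Probe
    sides are balanced within each session up to rounding.
    """
    n_trials = n_sessions * trials_per_session
    if n_trials != 2 * len(pairs):
        raise ValueError(
            f"session grid holds {n_sessions} x {trials_per_session} = {n_trials} trials "
            f"but {len(pairs)} pairs need exactly {2 * len(pairs)} (two probes per pair)"
        )
    tasks = {p.task for p in pairs}
    if len(tasks) != 1:
        raise ValueError(f"pairs must share one task, found {sorted(tasks)}")
    ids = [p.pair_id for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("pair_id values must be unique within a task")

    rng = np.random.default_rng(seed)
    slots = [(p, cong) for p in pairs for cong in ("congruent", "incongruent")]
    order = rng.permutation(len(slots))

    rows = []
    for sess in range(n_sessions):
        n_left = trials_per_session // 2
        sides = np.array(["left"] * n_left + ["right"] * (trials_per_session - n_left))
        if trials_per_session % 2:  # odd session size: coin-flip the extra side
            if rng.random() < 0.5:
                sides[n_left] = "left"
        rng.shuffle(sides)
        for t in range(trials_per_session):
            pair, cong = slots[order[sess * trials_per_session + t]]
            rows.append(
                {
                    "subject_id": subject_id,
                    "session_id": f"s{sess + 1:02d}",
                    "trial_index": t + 1,
                    "task": pair.task,
                    "congruence": cong,
                    "probe_side": sides[t],
                    "pair_id": pair.pair_id,
                    "width_diff": pair.width_diff if pair.width_diff is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def simulate_dotprobe(plan: pd.DataFrame, params: DotProbeGenParams, seed: int) -> pd.DataFrame:
    """Simulate reaction times for a dot-probe plan.

    RT = intercept + b_congruent*c + b_left*l + session effect
    + Student-t(resid_df) * resid_scale, with c, l sum-coded +/-1.  A trial
    is then replaced by an anticipatory tap (Uniform(50, 199) ms) with
    probability ``p_anticipatory``, or shifted by ``slow_shift_ms`` with
    probability ``p_slow``.  Simulated RTs below 50 ms are clipped there and
    flagged in the ``clipped`` column; the ``contaminant`` column records the
    injected process for downstream ground-truth checks.
    """
    rng = np.random.default_rng(seed)
    out = plan.copy().reset_index(drop=True)
    n = len(out)

    sessions = out["session_id"].unique()
    sess_eff = dict(zip(sessions, params.session_sd_ms * rng.standard_normal(len(sessions))))
    c = np.where(out["congruence"] == "congruent", 1.0, -1.0)
    l = np.where(out["probe_side"] == "left", 1.0, -1.0)
    rt = (
        params.intercept_ms
        + params.b_congruent_ms * c
        + params.b_left_ms * l
        + out["session_id"].map(sess_eff).to_numpy()
        + params.resid_scale_ms * rng.standard_t(params.resid_df, size=n)
    )

    slow = rng.random(n) < params.p_slow
    rt = rt + np.where(slow, params.slow_shift_ms, 0.0)
    antic = rng.random(n) < params.p_anticipatory
    rt = np.where(antic, rng.uniform(RT_FLOOR_MS, 199.0, size=n), rt)

    clipped = rt < RT_FLOOR_MS
    rt = np.maximum(rt, RT_FLOOR_MS)

    out["rt_ms"] = rt
    out["is_repetition"] = out.get("is_repetition", False)
    out["contaminant"] = np.select([antic, slow], ["anticipatory", "slow"], default="none")
    out["clipped"] = clipped
    return out


def make_repetition_plan(excluded: pd.DataFrame, trials_per_session: int = 24) -> pd.DataFrame:
    """Plan subject-specific repetition sessions for excluded trials.

    Each subject's excluded (pair, congruence) combinations are re-run in
    fresh sessions labelled ``rep01``, ``rep02``, ... of at most
    ``trials_per_session`` trials, keeping the original probe side.
    """
    parts = []
    for subject, grp in excluded.groupby("subject_id", sort=True):
        grp = grp.reset_index(drop=True)
        for i, chunk in grp.groupby(grp.index // trials_per_session):
            rep = chunk[
                ["subject_id", "task", "congruence", "probe_side", "pair_id", "width_diff"]
            ].copy()
            rep["session_id"] = f"rep{i + 1:02d}"
            rep["trial_index"] = np.arange(1, len(chunk) + 1)
            rep["is_repetition"] = True
            parts.append(rep)
    if not parts:
        cols = ["subject_id", "task", "congruence", "probe_side", "pair_id", "width_diff",
                "session_id", "trial_index", "is_repetition"]
        return pd.DataFrame(columns=cols)
    return pd.concat(parts, ignore_index=True)


def schedule_preference(
    subjects: list[str],
    seed: int,
    sessions_per_block: int = 3,
    n_forced: int = 8,
    n_choice: int = 16,
) -> pd.DataFrame:
    """Session plan for the two-alternative preference task.

    Half the subjects (rounded up, seeded assignment) receive the
    red-flanged block first; within a block the session order is randomised.
    Forced trials precede choice trials in every session, with forced
    colours balanced and shuffled.
    """
    if not subjects:
        raise ValueError("need at least one subject")
    if n_forced % 2:
        raise ValueError("n_forced must be even (half per colour)")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(np.asarray(subjects, dtype=object)))
    red_first = set(shuffled[: (len(subjects) + 1) // 2])

    rows = []
    for subject in subjects:
        order = "red_first" if subject in red_first else "green_first"
        blocks = ["red_flanged", "green_flanged"] if order == "red_first" else ["green_flanged", "red_flanged"]
        sess_no = 0
        for block in blocks:
            for _ in rng.permutation(sessions_per_block):  # nominal within-block shuffle
                sess_no += 1
                session_id = f"p{sess_no}"
                flanged_colour = "red" if block == "red_flanged" else "green"
                forced_colours = np.array(["red"] * (n_forced // 2) + ["green"] * (n_forced // 2))
                rng.shuffle(forced_colours)
                heights = HEIGHT_RADIUS * np.cos(rng.uniform(0.0, 2.0 * np.pi, n_forced + n_choice))
                for t in range(n_forced + n_choice):
                    rows.append(
                        {
                            "subject_id": subject,
                            "session_id": session_id,
                            "trial_index": t + 1,
                            "phase": "forced" if t < n_forced else "choice",
                            "block": block,
                            "order": order,
                            "flanged_colour": flanged_colour,
                            "forced_colour": forced_colours[t] if t < n_forced else "",
                            "flanged_dot_height": float(heights[t]),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_choices(plan: pd.DataFrame, params: ChoiceGenParams, seed: int) -> pd.DataFrame:
    """Simulate binary choices (1 = flanged stimulus) for a preference plan.

    Choice-phase probability: logistic(intercept + b_green*g + b_order*o
    + b_height*height + subject effect + session-within-subject effect
    + subject colour slope * g), with g = +1 for green-coded flanged stimuli
    and o = +1 for red-block-first subjects.  Forced trials deterministically
    emit the forced colour's category.
    """
    rng = np.random.default_rng(seed)
    out = plan.copy().reset_index(drop=True)

    subjects = out["subject_id"].unique()
    a = dict(zip(subjects, params.subject_sd * rng.standard_normal(len(subjects))))
    slope = dict(zip(subjects, params.colour_slope_sd * rng.standard_normal(len(subjects))))
    sess_keys = out[["subject_id", "session_id"]].drop_duplicates()
    s_eff = {
        (r.subject_id, r.session_id): params.session_sd * rng.standard_normal()
        for r in sess_keys.itertuples()
    }

    g = np.where(out["flanged_colour"] == "green", 1.0, -1.0)
    o = np.where(out["order"] == "red_first", 1.0, -1.0)
    eta = (
        params.logit_intercept
        + params.b_green * g
        + params.b_order * o
        + params.b_height * out["flanged_dot_height"].to_numpy()
        + out["subject_id"].map(a).to_numpy()
        + pd.MultiIndex.from_frame(out[["subject_id", "session_id"]]).map(s_eff).to_numpy()
        + out["subject_id"].map(slope).to_numpy() * g
    )
    p = expit(eta.astype(float))
    choice = (rng.random(len(out)) < p).astype(np.int64)

    forced = out["phase"] == "forced"
    forced_is_flanged = (out["forced_colour"] == out["flanged_colour"]).astype(np.int64)
    out["choice"] = np.where(forced, forced_is_flanged, choice)
    out["p_true"] = np.where(forced, forced_is_flanged.astype(float), p)
    return out
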