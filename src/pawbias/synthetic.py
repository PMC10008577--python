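"""Synthetic data emulating the study's generating structure, with ground truth.

Two families of generators:

* ``gen_paw_events`` draws per-dog right-paw probabilities theta from a
  symmetric beta distribution (the concentration knob maps directly to
  the expected |LI| strength of lateralization), shares each dog's
  latent theta across conditions (producing the observed baseline-OFT
  consistency), and shrinks the OFT-condition theta toward 0.5 by an
  ``acute_shift`` factor to emulate the acute-stress drift toward
  ambilaterality.  Trials are Bernoulli(theta), 50 per completed
  session.
* ``gen_trajectory`` simulates an open-field recording: a sticky
  three-state Markov chain (resting / marginal / running) drives
  frame-to-frame speed, heading evolves by small jitter plus injected
  turning episodes (sustained same-sign angular increments summing past
  45 deg, closed by a sub-2-deg frame), and positions integrate speed
  along the heading.  Tracking noise and likelihood dropouts are applied
  last.  Ground truth (state path, injected events) is returned
  alongside so recovery can be measured exactly.

Defaults mirror the study conditions: 28 chronically stressed and 32
healthy dogs, 50 trials per session, completion rates of roughly 78%
(food-reaching) and 63% (Kong), group mean |LI| 0.35 vs 0.53, and
5-minute 30-fps recordings with the novel object active in the final
minute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy import stats as sps

from .exceptions import ValidationError
from .laterality import PawEventSequence
from .trajectory import Arena, Trajectory, TurningEvent, make_trajectory

MEAN_ABS_LI_CS = 0.35
MEAN_ABS_LI_EH = 0.53


def mean_abs_li_of_concentration(a: float) -> float:
    """E|2 theta - 1| for theta ~ Beta(a, a)."""
    if a <= 0:
        raise ValidationError("concentration must be positive")
    dist = sps.beta(a, a)
    val, _ = integrate.quad(lambda t: abs(2 * t - 1) * dist.pdf(t), 0.0, 1.0)
    return float(val)


@lru_cache(maxsize=64)
def concentration_for_mean_abs_li(target: float) -> float:
    """Invert the concentration -> E|2 theta - 1| map (monotone decreasing)."""
    if not 0.0 < target < 1.0:
        raise ValidationError("target mean |LI| must lie in (0, 1)")
    return float(
        optimize.brentq(
            lambda a: mean_abs_li_of_concentration(a) - target, 1e-3, 200.0
        )
    )


@dataclass(frozen=True)
class LateralityGenConfig:
    """Knobs for the paw-event generator; defaults are the study conditions."""

    n_cs: int = 28
    n_eh: int = 32
    trials_per_session: int = 50
    concentration_cs: Optional[float] = None  # default: tuned to mean |LI| 0.35
    concentration_eh: Optional[float] = None  # default: tuned to mean |LI| 0.53
    acute_shift: float = 0.25  # OFT theta shrinkage toward 0.5
    theta_jitter_sd: float = 0.05  # per-condition wobble; keeps baseline-OFT r < 1
    completion_rate: Union[float, Mapping[str, float]] = field(
        default_factory=lambda: {"FRT": 0.78, "KT": 0.63}
    )
    tests: tuple[str, ...] = ("FRT", "KT")
    seed: int = 0

    def resolved_concentrations(self) -> tuple[float, float]:
        a_cs = (
            self.concentration_cs
            if self.concentration_cs is not None
            else concentration_for_mean_abs_li(MEAN_ABS_LI_CS)
        )
        a_eh = (
            self.concentration_eh
            if self.concentration_eh is not None
            else concentration_for_mean_abs_li(MEAN_ABS_LI_EH)
        )
        return a_cs, a_eh

    def completion(self, test: str) -> float:
        if isinstance(self.completion_rate, Mapping):
            return float(self.completion_rate.get(test, 1.0))
        return float(self.completion_rate)

    def validate(self) -> None:
        problems = []
        if self.n_cs < 0 or self.n_eh < 0:
            problems.append("group sizes must be non-negative")
        if self.n_cs + self.n_eh == 0:
            problems.append("at least one dog required")
        if self.trials_per_session < 1:
            problems.append("trials_per_session must be >= 1")
        a_cs, a_eh = (
            self.concentration_cs,
            self.concentration_eh,
        )
        for name, a in (("concentration_cs", a_cs), ("concentration_eh", a_eh)):
            if a is not None and a <= 0:
                problems.append(f"{name} must be positive")
        if not 0.0 <= self.acute_shift <= 1.0:
            problems.append("acute_shift must lie in [0, 1]")
        if self.theta_jitter_sd < 0:
            problems.append("theta_jitter_sd must be >= 0")
        for t in self.tests:
            if not 0.0 <= self.completion(t) <= 1.0:
                problems.append(f"completion rate for {t} outside [0, 1]")
        if problems:
            raise ValidationError("; ".join(problems))


def gen_paw_events(
    config: LateralityGenConfig,
) -> tuple[list[PawEventSequence], pd.DataFrame]:
    """Generate paw-event sequences plus the ground-truth preference table.

    Returns ``(sequences, truth)`` where ``truth`` has one row per
    dog x test with the latent baseline and OFT right-paw probabilities
    and per-condition completion flags.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a_cs, a_eh = config.resolved_concentrations()
    subjects = [(f"CS{i+1:02d}", "CS") for i in range(config.n_cs)] + [
        (f"EH{i+1:02d}", "EH") for i in range(config.n_eh)
    ]
    sequences: list[PawEventSequence] = []
    truth_rows = []
    for subject_id, group in subjects:
        a = a_cs if group == "CS" else a_eh
        for test in config.tests:
            theta_latent = rng.beta(a, a)
            rate = config.completion(test)
            row = {"subject_id": subject_id, "group": group, "test": test,
                   "theta_latent": theta_latent}
            for condition in ("baseline", "OFT"):
                theta = theta_latent
                if config.theta_jitter_sd > 0:
                    theta = theta + rng.normal(0.0, config.theta_jitter_sd)
                theta = float(np.clip(theta, 0.005, 0.995))
                if condition == "OFT":
                    theta = 0.5 + (1.0 - config.acute_shift) * (theta - 0.5)
                completed = bool(rng.random() < rate)
                n_trials = (
                    config.trials_per_session
                    if completed
                    else int(rng.integers(
                        max(1, config.trials_per_session // 2),
                        config.trials_per_session,
                    ))
                )
                events = tuple(
                    "R" if u < theta else "L" for u in rng.random(n_trials)
                )
                sequences.append(
                    PawEventSequence(subject_id, test, condition, events)
                )
                row[f"theta_{condition}"] = theta
                row[f"completed_{condition}"] = completed
            truth_rows.append(row)
    return sequences, pd.DataFrame(truth_rows)


def gen_covariates(
    n_cs: int = 28,
    n_eh: int = 32,
    seed: int = 0,
    include_physiology: bool = True,
) -> pd.DataFrame:
    """Per-subject covariate table: sex, sterilization, age, physiology.

    Sex ratio, age structure and the physiological condition means/SEs
    follow the study cohort (e.g. cortisol 2.00 ng/mL baseline vs 4.78
    post-OFT; heart and respiratory rates rising across baseline /
    before-OFT / after-OFT).  Values are drawn from normal distributions
    around those means with a subject-level intercept giving
    within-subject correlation of about 0.5; physiological values are
    floored at plausible minima.
    """
    rng = np.random.default_rng(seed)
    subjects = [(f"CS{i+1:02d}", "CS") for i in range(n_cs)] + [
        (f"EH{i+1:02d}", "EH") for i in range(n_eh)
    ]
    n = len(subjects)
    df = pd.DataFrame(
        {
            "subject_id": [s for s, _ in subjects],
            "group": [g for _, g in subjects],
            "sex": np.where(rng.random(n) < 0.4, "M", "F"),
            "sterilized": rng.integers(0, 2, n),
            "age_months": np.round(8 + rng.gamma(2.0, 14.0, n)).astype(int),
        }
    )
    if include_physiology:
        def repeated(means, total_sd, floor):
            between = total_sd * math.sqrt(0.5)
            within = total_sd * math.sqrt(0.5)
            intercept = rng.normal(0.0, between, n)
            cols = {}
            for label, mu in means.items():
                cols[label] = np.maximum(
                    mu + intercept + rng.normal(0.0, within, n), floor
                )
            return cols
        for label, vals in repeated(
            {"cortisol_baseline": 2.00, "cortisol_oft": 4.78}, 2.5, 0.1
        ).items():
            df[label] = np.round(vals, 3)
        for label, vals in repeated(
            {"hr_baseline": 102.68, "hr_before_oft": 108.23, "hr_after_oft": 123.63},
            21.0, 40.0,
        ).items():
            df[label] = np.round(vals, 1)
        for label, vals in repeated(
            {"rr_baseline": 53.79, "rr_before_oft": 69.79, "rr_after_oft": 93.97},
            28.0, 10.0,
        ).items():
            df[label] = np.round(vals, 1)
    return df


def gen_repeated_measures(
    n_per_group: tuple[int, int] = (20, 20),
    groups: tuple[str, str] = ("CS", "EH"),
    conditions: Sequence[str] = ("baseline", "OFT"),
    cell_means: Optional[np.ndarray] = None,
    between_sd: float = 1.0,
    within_sd: float = 1.0,
    covariate_effect: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format split-plot table for exercising the mixed models.

    ``cell_means`` is a (group x condition) array; the subject intercept
    SD ``between_sd`` and residual SD ``within_sd`` set the
    within-subject correlation between_sd^2 / (between_sd^2 +
    within_sd^2).  A binary sex covariate is drawn per subject and adds
    ``covariate_effect`` to every value of sex-coded-1 subjects.
    """
    rng = np.random.default_rng(seed)
    conditions = list(conditions)
    if cell_means is None:
        cell_means = np.zeros((2, len(conditions)))
    cell_means = np.asarray(cell_means, dtype=float)
    if cell_means.shape != (2, len(conditions)):
        raise ValidationError(
            f"cell_means must be shape (2, {len(conditions)}), got {cell_means.shape}"
        )
    rows = []
    idx = 0
    for gi, (gname, ng) in enumerate(zip(groups, n_per_group)):
        for _ in range(ng):
            idx += 1
            subject = f"S{idx:03d}"
            intercept = rng.normal(0.0, between_sd)
            sex = int(rng.random() < 0.5)
            for ci, cond in enumerate(conditions):
                rows.append(
                    {
                        "subject_id": subject,
                        "group": gname,
                        "condition": cond,
                        "sex": sex,
                        "value": cell_means[gi, ci]
                        + intercept
                        + covariate_effect * sex
                        + rng.normal(0.0, within_sd),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trajectory generator


def sticky_transition_matrix(stay: float = 0.95, n_states: int = 3) -> np.ndarray:
    off = (1.0 - stay) / (n_states - 1)
    t = np.full((n_states, n_states), off)
    np.fill_diagonal(t, stay)
    return t


@dataclass(frozen=True)
class TrajectoryGenConfig:
    """Knobs for the open-field trajectory generator."""

    duration_s: float = 300.0
    frame_rate: float = 30.0
    transition_matrix: Optional[np.ndarray] = None  # default sticky 0.95
    state_speed_means: tuple[float, float, float] = (0.2, 2.0, 8.0)
    state_speed_sds: tuple[float, float, float] = (0.1, 0.1, 0.1)
    heading_jitter_sd: float = 0.5  # deg/frame between turning episodes
    turn_rate: tuple[float, float, float] = (0.0, 0.004, 0.008)  # per frame, per state
    left_turn_prob: float = 0.5
    tracking_noise_sd: float = 1.0
    dropout_prob: float = 0.02
    body_length: float = 40.0
    start_xy: tuple[float, float] = (500.0, 500.0)
    object_xy: tuple[float, float] = (650.0, 350.0)
    object_epoch_s: float = 60.0  # object active for the final minute
    seed: int = 0

    def resolved_transmat(self) -> np.ndarray:
        t = (
            sticky_transition_matrix()
            if self.transition_matrix is None
            else np.asarray(self.transition_matrix, dtype=float)
        )
        if t.shape != (3, 3) or not np.allclose(t.sum(axis=1), 1.0) or (t < 0).any():
            raise ValidationError("transition matrix must be row-stochastic 3x3")
        return t

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate)) + 1

    def validate(self) -> None:
        problems = []
        if self.duration_s <= 0 or self.frame_rate <= 0:
            problems.append("duration and frame rate must be positive")
        if any(r < 0 for r in self.turn_rate):
            problems.append("turn rates must be >= 0")
        if not 0.0 <= self.left_turn_prob <= 1.0:
            problems.append("left_turn_prob must lie in [0, 1]")
        if self.tracking_noise_sd < 0 or not 0 <= self.dropout_prob < 1:
            problems.append("noise sd must be >= 0 and dropout_prob in [0, 1)")
        if self.object_epoch_s > self.duration_s:
            problems.append("object epoch longer than recording")
        if self.heading_jitter_sd < 0:
            problems.append("heading_jitter_sd must be >= 0")
        if problems:
            raise ValidationError("; ".join(problems))


@dataclass(frozen=True)
class TrajectoryGroundTruth:
    """Latent truth for one generated recording."""

    states: np.ndarray  # per speed step, 0=resting 1=marginal 2=running
    speeds: np.ndarray
    headings: np.ndarray  # per frame, degrees
    events: tuple[TurningEvent, ...]

    def occupancy(self) -> dict[str, float]:
        from .trajectory import STATE_NAMES

        return {
            name: float((self.states == k).mean())
            for k, name in enumerate(STATE_NAMES)
        }


def gen_trajectory(
    config: TrajectoryGenConfig,
) -> tuple[Trajectory, TrajectoryGroundTruth]:
    """Simulate one open-field recording with ground truth.

    The latent state chain drives speed; heading accrues small jitter
    plus injected turning episodes (increments of 5-15 deg of one sign
    until a 60-120 deg target is passed, then a closing sub-1-deg
    frame).  Episodes whose accumulated angle exceeds 45 deg are
    recorded as ground-truth turning events with the same indexing the
    detector uses (difference-series frames).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    transmat = config.resolved_transmat()
    n_frames = config.n_frames
    n_steps = n_frames - 1

    # latent state chain (stationary start approximated by uniform draw)
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.integers(0, 3)
    for t in range(1, n_steps):
        states[t] = rng.choice(3, p=transmat[states[t - 1]])
    means = np.asarray(config.state_speed_means)
    sds = np.asarray(config.state_speed_sds)
    speeds = np.abs(rng.normal(means[states], sds[states]))

    headings = np.empty(n_frames)
    headings[0] = rng.uniform(-180.0, 180.0)
    events: list[TurningEvent] = []
    t = 0
    while t < n_steps:
        if rng.random() < config.turn_rate[states[t]]:
            sign = 1.0 if rng.random() < config.left_turn_prob else -1.0
            target = rng.uniform(60.0, 120.0)
            start = t
            cum = 0.0
            while abs(cum) < target and t < n_steps:
                inc = sign * rng.uniform(5.0, 15.0)
                headings[t + 1] = headings[t] + inc
                cum += inc
                t += 1
            if t < n_steps:  # closing frame: |difference| < 2 deg
                headings[t + 1] = headings[t] + sign * rng.uniform(0.2, 1.0)
                end = t
                t += 1
            else:
                end = n_steps - 1
            if abs(cum) > 45.0:
                events.append(
                    TurningEvent(
                        start_frame=start,
                        end_frame=end,
                        cumulative_angle=cum,
                        direction="left" if cum > 0 else "right",
                    )
                )
        else:
            headings[t + 1] = headings[t] + rng.normal(0.0, config.heading_jitter_sd)
            t += 1

    rad = np.radians(headings)
    unit = np.column_stack([np.cos(rad), np.sin(rad)])
    body = np.empty((n_frames, 2))
    body[0] = config.start_xy
    body[1:] = config.start_xy + np.cumsum(speeds[:, None] * unit[:-1], axis=0)
    head = body + config.body_length * unit

    coords = {"body": body.copy(), "head": head.copy()}
    likelihoods = {}
    for bp in coords:
        if config.tracking_noise_sd > 0:
            coords[bp] = coords[bp] + rng.normal(
                0.0, config.tracking_noise_sd, coords[bp].shape
            )
        lik = rng.uniform(0.95, 1.0, n_frames)
        drop = rng.random(n_frames) < config.dropout_prob
        if drop.any():
            lik[drop] = rng.uniform(0.0, 0.5, int(drop.sum()))
            coords[bp][drop] += rng.normal(0.0, 50.0, (int(drop.sum()), 2))
        likelihoods[bp] = lik

    epoch_frames = int(round(config.object_epoch_s * config.frame_rate))
    arena = Arena(
        object_xy=config.object_xy,
        object_epoch=(n_frames - epoch_frames, n_frames),
    )
    traj = make_trajectory(
        coords, likelihoods, frame_rate=config.frame_rate, arena=arena
    )
    truth = TrajectoryGroundTruth(
        states=states,
        speeds=speeds,
        headings=headings,
        events=tuple(events),
    )
    return traj, truth
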