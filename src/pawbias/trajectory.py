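"""Open-field pose-trajectory analytics.

Consumes markerless pose-estimation exports (the DeepLabCut CSV dialect:
three header rows scorer/bodyparts/coords, then per-frame x, y,
likelihood per bodypart) and derives the study's kinematic measures:

* cleaning: low-likelihood points filled by interpolation, coordinates
  smoothed with a cubic smoothing spline;
* speed: frame-to-frame Euclidean displacement of the body centroid,
  used as the activity proxy;
* three-state segmentation of the log-speed profile with a Gaussian
  hidden Markov model (states relabelled by ascending emission mean to
  resting / marginal / running);
* body-to-novel-object distance and time-near-object proportion over
  the object's active epoch (the final minute of the test);
* egocentric turning events: consecutive same-sign changes of the
  head-relative-to-body orientation accumulating past 45 deg, an event
  being closed (and counted once) at the first frame whose angular
  change falls below 2 deg.

Coordinates follow the image convention (y increases downward), so a
positive wrapped orientation change is a clockwise turn on screen; with
an overhead camera that is the subject's LEFT turn.  This sign
convention is fixed here and exercised by the mirror-equivariance tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy.interpolate import UnivariateSpline

from .exceptions import (
    ConvergenceError,
    DataError,
    UntrackableVideoError,
    ValidationError,
)

logger = logging.getLogger(__name__)

STATE_NAMES = ("resting", "marginal", "running")
DEFAULT_FRAME_RATE = 30.0
DEFAULT_LIKELIHOOD_THRESHOLD = 0.9
DEFAULT_SMOOTHING = 4.0  # target mean squared spline residual, px^2
TURN_ACCUMULATE_DEG = 45.0
TURN_STOP_DEG = 2.0


@dataclass(frozen=True)
class Arena:
    """Static arena metadata: novel-object position, active epoch, scale."""

    object_xy: Optional[tuple[float, float]] = None
    object_epoch: Optional[tuple[int, int]] = None  # [start, end) frame range
    px_per_m: Optional[float] = None


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed 2-D positions and likelihoods for named bodyparts.

    ``data`` has two-level columns (bodypart, coord) with coord in
    {x, y, likelihood}; rows are uniformly spaced frames.
    """

    data: pd.DataFrame
    frame_rate: float = DEFAULT_FRAME_RATE
    arena: Arena = field(default_factory=Arena)

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        for bp in self.bodyparts:
            lik = self.data[(bp, "likelihood")].to_numpy()
            if ((lik < 0) | (lik > 1)).any():
                raise ValidationError(f"likelihoods for {bp!r} outside [0, 1]")

    @property
    def bodyparts(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def xy(self, bodypart: str) -> np.ndarray:
        self._require(bodypart)
        return self.data[bodypart][["x", "y"]].to_numpy(dtype=float)

    def likelihood(self, bodypart: str) -> np.ndarray:
        self._require(bodypart)
        return self.data[(bodypart, "likelihood")].to_numpy(dtype=float)

    def _require(self, bodypart: str) -> None:
        if bodypart not in self.bodyparts:
            raise ValidationError(
                f"unknown bodypart {bodypart!r}; available: {list(self.bodyparts)}"
            )


def make_trajectory(
    coords: dict[str, np.ndarray],
    likelihoods: Optional[dict[str, np.ndarray]] = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
    arena: Optional[Arena] = None,
) -> Trajectory:
    """Assemble a Trajectory from (n, 2) coordinate arrays per bodypart."""
    pieces = {}
    for bp, xy in coords.items():
        xy = np.asarray(xy, dtype=float)
        lik = (
            np.ones(len(xy))
            if likelihoods is None or bp not in likelihoods
            else np.asarray(likelihoods[bp], dtype=float)
        )
        pieces[(bp, "x")] = xy[:, 0]
        pieces[(bp, "y")] = xy[:, 1]
        pieces[(bp, "likelihood")] = lik
    df = pd.DataFrame(pieces)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
    return Trajectory(data=df, frame_rate=frame_rate, arena=arena or Arena())


# ---------------------------------------------------------------------------
# Pose-file I/O (DeepLabCut CSV export dialect)


def read_pose_tracks(
    path,
    frame_rate: float = DEFAULT_FRAME_RATE,
    arena: Optional[Arena] = None,
    required_bodyparts: Sequence[str] = ("body", "head"),
) -> Trajectory:
    """Read a pose CSV with the three-row scorer/bodyparts/coords header."""
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValidationError(f"malformed pose CSV {path}: {exc}") from exc
    if df.columns.nlevels != 3:
        raise ValidationError(
            f"{path}: expected 3 header rows (scorer/bodyparts/coords)"
        )
    df.columns = df.columns.droplevel(0)  # drop the scorer level
    df.columns.names = ["bodyparts", "coords"]
    available = list(dict.fromkeys(df.columns.get_level_values(0)))
    for bp in required_bodyparts:
        if bp not in available:
            raise ValidationError(
                f"{path}: required bodypart {bp!r} missing; available: {available}"
            )
    for bp in available:
        coords = set(df[bp].columns)
        if not {"x", "y", "likelihood"} <= coords:
            raise ValidationError(
                f"{path}: bodypart {bp!r} needs x/y/likelihood columns, has {sorted(coords)}"
            )
    df = df.astype(float).reset_index(drop=True)
    return Trajectory(data=df, frame_rate=frame_rate, arena=arena or Arena())


def write_pose_tracks(traj: Trajectory, path, scorer: str = "pawbias") -> None:
    """Write the three-header pose CSV dialect."""
    df = traj.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, bp, coord) for bp, coord in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    df.to_csv(path, index=True, index_label=None)


# ---------------------------------------------------------------------------
# Cleaning and kinematics


def clean_trajectory(
    traj: Trajectory,
    likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
    smoothing: float = DEFAULT_SMOOTHING,
) -> Trajectory:
    """Fill low-likelihood points and smooth coordinates with a cubic spline.

    Points with likelihood below ``likelihood_threshold`` are replaced by
    linear interpolation from neighbouring confident frames, then each
    coordinate series is smoothed by a cubic smoothing spline whose
    total squared residual budget is ``smoothing * n_frames`` (so
    ``smoothing`` is the tolerated mean squared residual per point, in
    px^2; 0 gives an interpolating spline).  Filled points get
    likelihood 1.0 in the output.  Raises
    :class:`UntrackableVideoError` when more than half of a bodypart's
    frames are sub-threshold.
    """
    if traj.n_frames < 10:
        raise ValidationError("need at least 10 frames to clean")
    if smoothing < 0:
        raise ValidationError("smoothing must be >= 0")
    t = np.arange(traj.n_frames, dtype=float)
    out = traj.data.copy()
    for bp in traj.bodyparts:
        lik = traj.likelihood(bp)
        bad = lik < likelihood_threshold
        if bad.mean() > 0.5:
            raise UntrackableVideoError(
                f"bodypart {bp!r}: {bad.mean():.0%} of frames below likelihood "
                f"{likelihood_threshold}; video untrackable"
            )
        for coord in ("x", "y"):
            s = pd.Series(traj.data[(bp, coord)].to_numpy(dtype=float))
            s[bad] = np.nan
            s = s.interpolate(method="linear", limit_direction="both")
            values = s.to_numpy()
            if smoothing > 0 and np.ptp(values) > 0:
                spl = UnivariateSpline(t, values, k=3, s=smoothing * traj.n_frames)
                values = spl(t)
            out[(bp, coord)] = values
        out[(bp, "likelihood")] = np.where(bad, 1.0, lik)
    return replace(traj, data=out)


@dataclass(frozen=True)
class SpeedProfile:
    """Per-frame speed (length n_frames - 1), in px/frame."""

    speed: np.ndarray
    frame_rate: float
    bodypart: str = "body"

    @property
    def mean(self) -> float:
        return float(self.speed.mean())

    def in_mps(self, px_per_m: float) -> np.ndarray:
        return self.speed * self.frame_rate / px_per_m


def compute_speed(traj: Trajectory, bodypart: str = "body") -> SpeedProfile:
    """Frame-to-frame Euclidean displacement of one bodypart (px/frame)."""
    xy = traj.xy(bodypart)
    d = np.diff(xy, axis=0)
    return SpeedProfile(
        speed=np.hypot(d[:, 0], d[:, 1]),
        frame_rate=traj.frame_rate,
        bodypart=bodypart,
    )


@dataclass(frozen=True)
class ProximityResult:
    """Object-proximity summary over the active epoch."""

    mean_distance: float
    proportion_near: float
    near_threshold: float
    n_frames: int


def median_body_length(traj: Trajectory) -> float:
    """Median head-to-body distance; the default proximity scale."""
    d = traj.xy("head") - traj.xy("body")
    return float(np.median(np.hypot(d[:, 0], d[:, 1])))


def object_proximity(
    traj: Trajectory,
    near_threshold: Optional[float] = None,
    bodypart: str = "body",
) -> ProximityResult:
    """Mean body-to-object distance and fraction of near frames, epoch-only.

    ``near_threshold`` defaults to one median body length.  Requires the
    arena's object position and active epoch (the object is present only
    during the final minute of the test).
    """
    if traj.arena.object_xy is None:
        raise ValidationError("arena.object_xy not set")
    if traj.arena.object_epoch is None:
        raise ValidationError("arena.object_epoch not set")
    start, end = traj.arena.object_epoch
    if not (0 <= start < end <= traj.n_frames):
        raise ValidationError(
            f"object epoch [{start}, {end}) outside recording of {traj.n_frames} frames"
        )
    if near_threshold is None:
        near_threshold = median_body_length(traj)
    ox, oy = traj.arena.object_xy
    xy = traj.xy(bodypart)[start:end]
    dist = np.hypot(xy[:, 0] - ox, xy[:, 1] - oy)
    return ProximityResult(
        mean_distance=float(dist.mean()),
        proportion_near=float((dist <= near_threshold).mean()),
        near_threshold=float(near_threshold),
        n_frames=end - start,
    )


def object_distance_series(traj: Trajectory, bodypart: str = "body") -> np.ndarray:
    """Per-frame body-to-object distance for the whole recording."""
    if traj.arena.object_xy is None:
        raise ValidationError("arena.object_xy not set")
    ox, oy = traj.arena.object_xy
    xy = traj.xy(bodypart)
    return np.hypot(xy[:, 0] - ox, xy[:, 1] - oy)


# ---------------------------------------------------------------------------
# State segmentation


@dataclass(frozen=True)
class StateSegmentation:
    """HMM segmentation: labels 0/1/2 = resting/marginal/running."""

    labels: np.ndarray
    means: np.ndarray  # emission means on the log-speed scale, ascending
    variances: np.ndarray
    transition_matrix: np.ndarray
    occupancy: dict[str, float]
    log_likelihood: float

    @property
    def state_names(self) -> tuple[str, ...]:
        return STATE_NAMES


def segment_states(
    profile: SpeedProfile,
    seed: int = 0,
    n_states: int = 3,
    n_restarts: int = 5,
    n_iter: int = 200,
    eps: float = 1e-6,
) -> StateSegmentation:
    """Fit a Gaussian HMM to log(speed + eps) and Viterbi-decode states.

    EM is restarted ``n_restarts`` times and the best-scoring converged
    fit is kept.  The first restart is fully deterministic: emission
    means start at the 10th/50th/90th percentiles of the log-speed (a
    spread covering slow/medium/fast regimes), uniform start and
    transition probabilities, data-variance emissions.  Remaining
    restarts use seeded k-means initialisation to probe other basins.
    States are relabelled by ascending emission mean to resting /
    marginal / running, which makes the labelling invariant to EM's
    arbitrary state order.
    """
    x = np.log(np.asarray(profile.speed, dtype=float) + eps).reshape(-1, 1)
    if x.shape[0] < 100:
        raise ValidationError("need at least 100 speed frames to segment")
    if np.ptp(x) == 0.0:
        raise DataError("degenerate single-speed profile; no states to separate")
    best = None
    traces = []
    for r in range(n_restarts):
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=n_iter,
            tol=1e-4,
            random_state=int(seed) + r,
        )
        if r == 0:
            model.init_params = ""
            model.startprob_ = np.full(n_states, 1.0 / n_states)
            model.transmat_ = np.full((n_states, n_states), 1.0 / n_states)
            model.means_ = np.quantile(
                x, np.linspace(0.1, 0.9, n_states)
            ).reshape(-1, 1)
            model.covars_ = np.full((n_states, 1), float(x.var()))
        try:
            model.fit(x)
        except ValueError:
            continue
        traces.append(list(model.monitor_.history))
        if not model.monitor_.converged:
            continue
        score = model.score(x)
        if best is None or score > best[0]:
            best = (score, model)
    if best is None:
        raise ConvergenceError(
            f"EM failed to converge in {n_restarts} restarts of {n_iter} iterations",
            loglik_trace=[ll for t in traces for ll in t],
        )
    score, model = best
    raw_labels = model.predict(x)
    order = np.argsort(model.means_.ravel())  # ascending mean: resting first
    relabel = np.empty(n_states, dtype=int)
    relabel[order] = np.arange(n_states)
    labels = relabel[raw_labels]
    trans = model.transmat_[np.ix_(order, order)]
    occupancy = {
        STATE_NAMES[k]: float((labels == k).mean()) for k in range(n_states)
    }
    return StateSegmentation(
        labels=labels,
        means=model.means_.ravel()[order],
        variances=model.covars_.ravel()[order],
        transition_matrix=trans,
        occupancy=occupancy,
        log_likelihood=float(score),
    )


# ---------------------------------------------------------------------------
# Heading and turning


def wrap_degrees(angle) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped


def heading_series(traj: Trajectory) -> np.ndarray:
    """Per-frame orientation of the head-minus-body vector, degrees.

    Angles are in (-180, 180] in image coordinates.  Frames where head
    and body coincide carry the previous frame's orientation forward
    (logged); a coincident first frame takes the first valid orientation.
    """
    v = traj.xy("head") - traj.xy("body")
    norms = np.hypot(v[:, 0], v[:, 1])
    angles = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    angles = wrap_degrees(angles)
    degenerate = norms == 0.0
    if degenerate.all():
        raise DataError("head and body coincide in every frame")
    if degenerate.any():
        logger.warning(
            "%d frame(s) with coincident head/body; carrying orientation forward",
            int(degenerate.sum()),
        )
        s = pd.Series(np.where(degenerate, np.nan, angles))
        angles = s.ffill().bfill().to_numpy()
    return angles


def angular_differences(angles: Sequence[float]) -> np.ndarray:
    """Wrapped frame-to-frame orientation changes, degrees in (-180, 180]."""
    a = np.asarray(angles, dtype=float)
    return wrap_degrees(np.diff(a))


@dataclass(frozen=True)
class TurningEvent:
    """One detected turn over the angular-difference series.

    ``start_frame``/``end_frame`` index the difference series (difference
    i is the change from frame i to frame i+1); ``end_frame`` is the
    closing frame (|difference| < stop threshold) or the final index for
    a turn still in progress at the end of the recording.
    """

    start_frame: int
    end_frame: int
    cumulative_angle: float
    direction: str  # "left" (positive, clockwise on screen) or "right"


def detect_turnings(
    diffs: Sequence[float],
    accumulate_threshold: float = TURN_ACCUMULATE_DEG,
    stop_threshold: float = TURN_STOP_DEG,
) -> list[TurningEvent]:
    """Detect turning events from wrapped angular differences.

    Consecutive same-sign differences accumulate; once the magnitude of
    the accumulated angle exceeds ``accumulate_threshold`` the turn is
    armed, and it is emitted (counted once, guarding against double
    counting turns beyond 90 deg) at the first subsequent frame whose
    absolute difference is below ``stop_threshold``.  While unarmed, a
    sign change resets the accumulator to the current difference; while
    armed, all differences keep accumulating until closure.  A turn
    still armed at the end of the series is emitted there.
    """
    if accumulate_threshold <= 0 or stop_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    diffs = np.asarray(list(diffs), dtype=float)
    if diffs.size < 2:
        return []
    events: list[TurningEvent] = []
    acc = 0.0
    start: Optional[int] = None
    armed = False
    for i, d in enumerate(diffs):
        if armed:
            if abs(d) < stop_threshold:
                events.append(_make_event(start, i, acc))
                acc, start, armed = 0.0, None, False
            else:
                acc += d
            continue
        if d == 0.0:
            continue  # neutral frame: neither resets nor accumulates
        if acc != 0.0 and (d > 0) != (acc > 0):
            acc, start = 0.0, None  # direction changed before arming
        if start is None:
            start = i
        acc += d
        if abs(acc) > accumulate_threshold:
            armed = True
    if armed:
        events.append(_make_event(start, len(diffs) - 1, acc))
    return events


def _make_event(start: int, end: int, acc: float) -> TurningEvent:
    return TurningEvent(
        start_frame=int(start),
        end_frame=int(end),
        cumulative_angle=float(acc),
        direction="left" if acc > 0 else "right",
    )


def turning_bias(events: Iterable[TurningEvent]) -> float:
    """Proportion of left turns; NaN (missing) when there are no events."""
    events = list(events)
    if not events:
        return float("nan")
    n_left = sum(1 for e in events if e.direction == "left")
    return n_left / len(events)


def approach_turning_bias(
    events: Iterable[TurningEvent],
    traj: Trajectory,
    bodypart: str = "body",
) -> float:
    """Turning bias restricted to object-epoch turns made while approaching.

    A turn qualifies when its start frame lies inside the object epoch
    and the body-to-object distance decreases net over the event
    (approach defined as a negative distance trend).  NaN when no turn
    qualifies.
    """
    if traj.arena.object_epoch is None:
        raise ValidationError("arena.object_epoch not set")
    start, end = traj.arena.object_epoch
    if not (0 <= start < end <= traj.n_frames):
        raise ValidationError("object epoch outside recording range")
    dist = object_distance_series(traj, bodypart)
    selected = []
    for e in events:
        if not (start <= e.start_frame < end):
            continue
        d0 = dist[e.start_frame]
        d1 = dist[min(e.end_frame + 1, len(dist) - 1)]
        if d1 < d0:
            selected.append(e)
    return turning_bias(selected)
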