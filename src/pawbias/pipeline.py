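"""Orchestration: run the full study analysis from input tables to reports.

``run_laterality_study`` turns a long-format paw-event CSV (plus an
optional covariate table) into the study's laterality report bundle:
per-dog records, the preference-distribution table with exact binomial
p-values, LI and |LI| correlation matrices across test x condition,
population-bias t-tests, 2 x 2 mixed ANCOVAs (group x condition with a
sex covariate) and first-paw association tests.

``run_oft_analysis`` turns a directory of pose CSVs into per-subject
kinematic metrics (average speed, state occupancies, object proximity,
turning counts and biases) and the group comparisons and cortisol-speed
correlations built on them.

Sections that cannot be computed from the supplied inputs are skipped
with a logged reason, never silently; reruns with identical config and
seed produce byte-identical CSV outputs (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import laterality as lat
from . import stats as st
from . import trajectory as tj
from .exceptions import DataError, PawbiasError, ValidationError

logger = logging.getLogger(__name__)

SEX_CODES = {"M": 0, "F": 1, "m": 0, "f": 1, "0": 0, "1": 1, 0: 0, 1: 1}


@dataclass
class StudyConfig:
    """Paths, thresholds and seed for a full study run."""

    events_csv: Optional[Path] = None
    covariates_csv: Optional[Path] = None
    pose_dir: Optional[Path] = None
    output_dir: Path = Path("pawbias_out")
    z_cutoff: float = lat.Z_CUTOFF
    null_prop: float = lat.NULL_PROPORTION
    target_trials: int = lat.TARGET_TRIALS
    drop_incomplete: bool = True
    likelihood_threshold: float = tj.DEFAULT_LIKELIHOOD_THRESHOLD
    smoothing: float = tj.DEFAULT_SMOOTHING
    near_threshold: Optional[float] = None
    frame_rate: float = tj.DEFAULT_FRAME_RATE
    object_xy: Optional[tuple[float, float]] = None
    object_epoch_s: float = 60.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.normalize()
        return cfg

    def normalize(self) -> None:
        for name in ("events_csv", "covariates_csv", "pose_dir", "output_dir"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        if self.object_xy is not None:
            self.object_xy = tuple(float(v) for v in self.object_xy)
        if not 0 < self.z_cutoff < 10:
            raise ValidationError("z_cutoff outside a sensible range")
        if not 0 < self.null_prop < 1:
            raise ValidationError("null_prop must lie in (0, 1)")
        if not 0 <= self.likelihood_threshold <= 1:
            raise ValidationError("likelihood_threshold must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d


def _package_version() -> str:
    from . import __version__

    return __version__


@dataclass
class ReportBundle:
    """Named tables plus the skip log; writes one CSV per table."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    skipped: list[dict] = field(default_factory=list)

    def skip(self, section: str, reason: str) -> None:
        logger.warning("skipping %s: %s", section, reason)
        self.skipped.append({"section": section, "reason": reason})

    def write(self, outdir: Path, config: StudyConfig, kind: str) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in sorted(self.tables.items()):
            table.to_csv(outdir / f"{name}.csv", index=False)
        manifest = {
            "kind": kind,
            "config": config.to_dict(),
            "seed": config.seed,
            "version": _package_version(),
            "tables": sorted(self.tables),
            "skipped": self.skipped,
        }
        with open(outdir / f"{kind}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _load_covariates(config: StudyConfig) -> Optional[pd.DataFrame]:
    if config.covariates_csv is None:
        return None
    cov = pd.read_csv(config.covariates_csv, dtype={"subject_id": str})
    if "subject_id" not in cov.columns:
        raise ValidationError("covariates CSV must have a subject_id column")
    if "sex" in cov.columns:
        codes = cov["sex"].map(SEX_CODES)
        if codes.isna().any():
            raise ValidationError("sex column must be M/F or 0/1")
        cov["sex_code"] = codes.astype(int)
    return cov


def _round_for_display(df: pd.DataFrame) -> pd.DataFrame:
    """Display rounding: LI-like values to 2 decimals, p-values to 3."""
    out = df.copy()
    for col in out.columns:
        low = col.lower()
        if low.startswith("p_value") or low == "p":
            out[col] = out[col].round(3)
        elif out[col].dtype.kind == "f":
            out[col] = out[col].round(2)
    return out


def run_laterality_study(config: StudyConfig) -> ReportBundle:
    """Full laterality analysis from the event CSV; see module docstring."""
    if config.events_csv is None:
        raise ValidationError("config.events_csv is required")
    sequences = lat.read_paw_events(config.events_csv)
    if not sequences:
        raise DataError("event CSV contains no sessions")
    records = lat.score_cohort(sequences, target_trials=config.target_trials)
    analysis = [r for r in records if r.complete or not config.drop_incomplete]
    if not analysis:
        raise DataError("no completed sessions after filtering")

    bundle = ReportBundle()
    rec_frame = lat.records_to_frame(records)
    covariates = _load_covariates(config)
    if covariates is not None:
        rec_frame = rec_frame.merge(covariates, on="subject_id", how="left")
    bundle.tables["records"] = rec_frame

    # Preference-distribution table with exact binomial p-values per class
    dist_frames = []
    strata = sorted({(r.test, r.condition) for r in analysis})
    for test, condition in strata:
        stratum = [r for r in analysis if r.test == test and r.condition == condition]
        dist = lat.preference_distribution_test(stratum, null_prop=config.null_prop)
        dist_frames.append(dist.to_frame())
    bundle.tables["preference_distribution"] = pd.concat(
        dist_frames, ignore_index=True
    )

    # Population-level bias per stratum
    bias_rows = []
    for test, condition in strata:
        lis = [r.li for r in analysis if r.test == test and r.condition == condition]
        try:
            res = lat.population_bias_test(lis)
        except PawbiasError as exc:
            bundle.skip(f"population_bias/{test}/{condition}", str(exc))
            continue
        bias_rows.append(
            {"test": test, "condition": condition, "mean_li": res.mean,
             "se": res.se, "t": res.t, "df": res.df, "p_value": res.p, "n": res.n}
        )
    if bias_rows:
        bundle.tables["population_bias"] = pd.DataFrame(bias_rows)

    # Correlation matrices across the four test x condition LI series
    adf = lat.records_to_frame(analysis)
    adf["series"] = adf["test"] + "_" + adf["condition"]
    for value in ("li", "abs_li"):
        wide = adf.pivot_table(
            index="subject_id", columns="series", values=value, aggfunc="first"
        )
        if wide.shape[1] < 2:
            bundle.skip(f"correlations_{value}", "fewer than two series available")
            continue
        r, p = st.correlation_matrix(wide)
        bundle.tables[f"correlations_{value}"] = r.reset_index(names="series")
        bundle.tables[f"correlations_{value}_p"] = p.reset_index(names="series")

    # Mixed ANCOVAs (group x condition, sex covariate) on LI and |LI| per test
    if covariates is None or "group" not in covariates.columns:
        bundle.skip("ancova", "covariates with a group column are required")
    elif "sex_code" not in covariates.columns:
        bundle.skip("ancova", "sex covariate missing")
    else:
        merged = adf.merge(
            covariates[["subject_id", "group", "sex_code"]], on="subject_id"
        )
        ancova_rows = []
        for test in sorted(merged["test"].unique()):
            sub = merged[merged["test"] == test]
            for value in ("li", "abs_li"):
                try:
                    res = st.mixed_ancova(
                        sub, covariate="sex_code", dv=value,
                        within="condition", between="group",
                    )
                except PawbiasError as exc:
                    bundle.skip(f"ancova/{test}/{value}", str(exc))
                    continue
                for eff in res.effects:
                    row = {"test": test, "dv": value, "n": res.n_subjects}
                    row.update(eff.to_dict())
                    ancova_rows.append(row)
        if ancova_rows:
            bundle.tables["ancova"] = pd.DataFrame(ancova_rows)

    # First-paw association per stratum
    fp_rows = []
    for test, condition in strata:
        stratum = [r for r in analysis if r.test == test and r.condition == condition]
        try:
            res = lat.first_paw_association(stratum)
        except PawbiasError as exc:
            bundle.skip(f"first_paw/{test}/{condition}", str(exc))
            continue
        fp_rows.append(
            {
                "test": test, "condition": condition, "t": res.t, "df": res.df,
                "p_value": res.p, "cohen_d": res.cohen_d,
                "mean_li_left_first": res.mean_left_first,
                "mean_li_right_first": res.mean_right_first,
                "n_left_first": res.n_left_first,
                "n_right_first": res.n_right_first,
            }
        )
    if fp_rows:
        bundle.tables["first_paw"] = pd.DataFrame(fp_rows)

    bundle.tables["preference_distribution_display"] = _round_for_display(
        bundle.tables["preference_distribution"]
    )
    return bundle


# ---------------------------------------------------------------------------
# Open-field analysis


OFT_METRICS = (
    "avg_speed",
    "proximity_proportion",
    "resting",
    "running",
    "turning_bias",
    "approach_turning_bias",
)


def _analyze_pose_file(path: Path, config: StudyConfig, seed: int) -> dict:
    arena = None
    traj = tj.read_pose_tracks(path, frame_rate=config.frame_rate)
    if config.object_xy is not None:
        epoch_frames = int(round(config.object_epoch_s * config.frame_rate))
        arena = tj.Arena(
            object_xy=config.object_xy,
            object_epoch=(max(0, traj.n_frames - epoch_frames), traj.n_frames),
        )
        traj = dataclasses.replace(traj, arena=arena)
    traj = tj.clean_trajectory(
        traj,
        likelihood_threshold=config.likelihood_threshold,
        smoothing=config.smoothing,
    )
    profile = tj.compute_speed(traj)
    seg = tj.segment_states(profile, seed=seed)
    angles = tj.heading_series(traj)
    events = tj.detect_turnings(tj.angular_differences(angles))
    n_left = sum(1 for e in events if e.direction == "left")
    row = {
        "subject_id": path.stem,
        "n_frames": traj.n_frames,
        "avg_speed": profile.mean,
        "resting": seg.occupancy["resting"],
        "marginal": seg.occupancy["marginal"],
        "running": seg.occupancy["running"],
        "n_turns_left": n_left,
        "n_turns_right": len(events) - n_left,
        "turning_bias": tj.turning_bias(events),
    }
    if arena is not None:
        prox = tj.object_proximity(traj, near_threshold=config.near_threshold)
        row["proximity_proportion"] = prox.proportion_near
        row["mean_object_distance"] = prox.mean_distance
        row["approach_turning_bias"] = tj.approach_turning_bias(events, traj)
    return row


def _gated_values(x: np.ndarray) -> tuple[np.ndarray, str]:
    """Apply the normality gate; log-transform when it says so."""
    try:
        gate = st.normality_gate(x)
    except PawbiasError:
        return x, "parametric"
    if gate.decision == "log_transform":
        return np.log(x), "log_transform"
    return x, gate.decision


def run_oft_analysis(config: StudyConfig) -> ReportBundle:
    """Open-field kinematics and group statistics; see module docstring."""
    if config.pose_dir is None:
        raise ValidationError("config.pose_dir is required")
    pose_dir = Path(config.pose_dir)
    files = sorted(pose_dir.glob("*.csv"))
    if not files:
        raise DataError(f"no pose CSV files found in {pose_dir}")
    bundle = ReportBundle()
    rows = []
    for i, path in enumerate(files):
        rows.append(_analyze_pose_file(path, config, seed=config.seed + i))
    metrics = pd.DataFrame(rows)
    covariates = _load_covariates(config)
    if covariates is not None:
        metrics = metrics.merge(covariates, on="subject_id", how="left")
    bundle.tables["oft_metrics"] = metrics

    if covariates is None or "group" not in metrics.columns:
        bundle.skip("group_comparisons", "covariates with group labels required")
        return bundle

    cmp_rows = []
    for metric in OFT_METRICS:
        if metric not in metrics.columns:
            bundle.skip(f"group_comparisons/{metric}", "metric not computed")
            continue
        sub = metrics.dropna(subset=[metric, "group"])
        a = sub.loc[sub["group"] == "CS", metric].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == "EH", metric].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            bundle.skip(f"group_comparisons/{metric}", "fewer than 2 dogs per group")
            continue
        pooled = np.concatenate([a, b])
        _, transform = _gated_values(pooled)
        if transform == "log_transform":
            a, b = np.log(a), np.log(b)
        try:
            res = st.welch_t(a, b)
        except PawbiasError as exc:
            bundle.skip(f"group_comparisons/{metric}", str(exc))
            continue
        cmp_rows.append(
            {
                "metric": metric, "transform": transform, "t": res.statistic,
                "df": res.df2, "p_value": res.p, "cohen_d": res.effect_size,
                "mean_cs": float(a.mean()), "mean_eh": float(b.mean()),
                "n_cs": int(a.size), "n_eh": int(b.size),
            }
        )
    if cmp_rows:
        bundle.tables["group_comparisons"] = pd.DataFrame(cmp_rows)

    _cortisol_speed_correlations(bundle, metrics)
    return bundle


def _corr_row(frame, cortisol_col, label, stratum):
    sub = frame.dropna(subset=[cortisol_col, "avg_speed"])
    if len(sub) < 3:
        return None
    try:
        res = st.pearson_correlation(sub[cortisol_col], sub["avg_speed"])
    except PawbiasError:
        return None
    return {
        "cortisol": cortisol_col, "split": label, "stratum": str(stratum),
        "r": res.statistic, "p_value": res.p, "n": len(sub),
    }


def _cortisol_speed_correlations(bundle: ReportBundle, metrics: pd.DataFrame) -> None:
    cort_cols = [c for c in ("cortisol_baseline", "cortisol_oft") if c in metrics]
    if not cort_cols:
        bundle.skip("cortisol_speed", "no cortisol columns in covariates")
        return
    rows = []
    for col in cort_cols:
        for grp, sub in metrics.groupby("group"):
            row = _corr_row(sub, col, "group", grp)
            if row:
                rows.append(row)
        for split in ("sex", "sterilized"):
            if split not in metrics.columns or metrics[split].isna().all():
                bundle.skip(f"cortisol_speed/{split}", f"{split} covariate missing")
                continue
            for level, sub in metrics.groupby(split):
                row = _corr_row(sub, col, split, level)
                if row:
                    rows.append(row)
        if "age_months" in metrics.columns and metrics["age_months"].notna().any():
            median_age = metrics["age_months"].median()
            for label, sub in (
                ("young", metrics[metrics["age_months"] <= median_age]),
                ("old", metrics[metrics["age_months"] > median_age]),
            ):
                row = _corr_row(sub, col, "age", label)
                if row:
                    rows.append(row)
        else:
            bundle.skip("cortisol_speed/age", "age covariate missing")
    if rows:
        bundle.tables["cortisol_speed_correlations"] = pd.DataFrame(rows)


def run_study(config: StudyConfig) -> dict[str, ReportBundle]:
    """Run both analysis blocks and write everything under output_dir."""
    bundles = {}
    if config.events_csv is not None:
        bundles["laterality"] = run_laterality_study(config)
        bundles["laterality"].write(config.output_dir, config, "laterality")
    if config.pose_dir is not None:
        bundles["oft"] = run_oft_analysis(config)
        bundles["oft"].write(config.output_dir, config, "oft")
    if not bundles:
        raise ValidationError("config provides neither events_csv nor pose_dir")
    return bundles
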