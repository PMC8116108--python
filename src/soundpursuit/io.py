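"""Trial files, session manifests and the end-to-end pipeline.

On disk a trial is a CSV with header ``time_s,stimulus_deg,head_deg`` (one
row per sample, uniform grid) plus an optional JSON sidecar
(``<stem>.meta.json``) holding trial metadata and, for synthetic data, the
generating ground-truth parameters.  A session is a directory of trial files
tied together by ``manifest.json``.

`run_pipeline` chains the whole analysis: per-subject delay estimation,
per-trial model fits, pursuit-error metrics, effort, and the hierarchical
trends, producing a tidy per-trial results table, a trend-summary JSON and a
short human-readable report.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .identify import estimate_subject_delay, fit_session
from .lti import APSParameters, spectral_effort
from .metrics import error_regressions, optimal_alignment
from .simulate import SyntheticSubjectConfig, TrialRecord, simulate_session
from .stimulus import MotorDistortion, SumOfSinesSpec, TrajectoryTrace, trial_set
from .trends import effort_trend, hierarchical_trend

__all__ = [
    "write_trial",
    "read_trial",
    "SessionManifest",
    "PipelineConfig",
    "simulate_synthetic_session",
    "write_session",
    "read_session",
    "run_pipeline",
]

_HEADER = ["time_s", "stimulus_deg", "head_deg"]
_FLOAT_FMT = "%.9g"


def write_trial(path: str | Path, trial: TrialRecord) -> Path:
    """Write one trial to CSV (+ JSON sidecar with metadata/ground truth)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trial.stimulus.time,
            "stimulus_deg": trial.stimulus.position,
            "head_deg": trial.head.position,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta: dict = {
        "subject_id": trial.subject_id,
        "trial_number": trial.trial_number,
        "sample_rate_hz": trial.stimulus.sample_rate,
    }
    if trial.ground_truth is not None:
        meta["ground_truth"] = dataclasses.asdict(trial.ground_truth)
    if trial.spec is not None:
        meta["stimulus_spec"] = dataclasses.asdict(trial.spec)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def _parse_spec(d: dict) -> SumOfSinesSpec:
    d = dict(d)
    d["multipliers"] = tuple(d.get("multipliers", (2, 3, 7, 13, 21)))
    return SumOfSinesSpec(**d)


def read_trial(path: str | Path) -> TrialRecord:
    """Read a trial CSV back; validates the header, finiteness and grid uniformity."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in _HEADER:
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy(float)))
        if bad.size:
            raise ValueError(f"{path}: non-finite value in column {col!r} at row {bad[0]}")
    t = df["time_s"].to_numpy(float)
    if t.size >= 3:
        steps = np.diff(t)
        ref = float(np.median(steps))
        # 1% of a step tolerates round-tripped 9-digit timestamps; a missing
        # or duplicated row is off by a whole step
        off = np.flatnonzero(np.abs(steps - ref) > 0.01 * max(ref, 1e-12))
        if off.size:
            raise ValueError(f"{path}: non-uniform time grid at row {off[0] + 1}")
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    spec = _parse_spec(meta["stimulus_spec"]) if "stimulus_spec" in meta else None
    gt = APSParameters(**meta["ground_truth"]) if "ground_truth" in meta else None
    trial_number = int(meta.get("trial_number", 1))
    stim = TrajectoryTrace(
        t, df["stimulus_deg"].to_numpy(float), trial_id=trial_number, role="motor"
    )
    head = TrajectoryTrace(t, df["head_deg"].to_numpy(float), trial_id=trial_number, role="head")
    return TrialRecord(
        subject_id=str(meta.get("subject_id", "S?")),
        trial_number=trial_number,
        stimulus=stim,
        head=head,
        ground_truth=gt,
        spec=spec,
    )


@dataclass
class SessionManifest:
    """Index of a session directory: which trial files belong to which subject."""

    subjects: dict[str, list[str]]  # subject id -> relative trial paths
    sample_rate: float
    stimulus_spec: SumOfSinesSpec
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "subjects": self.subjects,
                "sample_rate": self.sample_rate,
                "stimulus_spec": dataclasses.asdict(self.stimulus_spec),
                "provenance": self.provenance,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SessionManifest":
        d = json.loads(text)
        return cls(
            subjects=d["subjects"],
            sample_rate=d["sample_rate"],
            stimulus_spec=_parse_spec(d["stimulus_spec"]),
            provenance=d.get("provenance", {}),
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of a full synthetic-session analysis.

    Defaults mirror the study conditions: 11 subjects, 30 trials of 20 s at
    110 Hz, 30 deg peak, harmonics [2,3,7,13,21] x 0.05 Hz, Q drifting
    1.5 -> 0.6 with lognormal jitter, 1 deg measurement noise.
    """

    n_subjects: int = 11
    n_trials: int = 30
    seed: int = 0
    spec: SumOfSinesSpec = SumOfSinesSpec()
    distortion: MotorDistortion | None = MotorDistortion()
    f_c: float = 0.6
    q_start: float = 1.5
    q_end: float = 0.6
    q_jitter_sd: float = 0.15
    noise_sd: float = 1.0
    effort_band: tuple[float, float] = (0.05, 1.05)
    alignment_search: tuple[float, float] = (0.0, 0.6)
    subsample_step: int = 15
    estimate_delay: bool = True
    mcmc_samples: int = 1500
    fit_grid_shape: tuple[int, int] = (40, 40)

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("need at least one subject and one trial")

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "spec" in d:
            d["spec"] = _parse_spec(d["spec"])
        if "distortion" in d:
            d["distortion"] = MotorDistortion(**d["distortion"]) if d["distortion"] else None
        for key in ("effort_band", "alignment_search", "fit_grid_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def simulate_synthetic_session(config: PipelineConfig) -> dict[str, list[TrialRecord]]:
    """Generate the full synthetic data set: per-subject stimuli and responses.

    Every subject hears an independent realisation of the stimulus ensemble
    (fresh random phases), as in the study.  Deterministic under the config
    seed.
    """
    root = np.random.default_rng(config.seed)
    sessions: dict[str, list[TrialRecord]] = {}
    for i in range(1, config.n_subjects + 1):
        sid = f"S{i}"
        stimuli = trial_set(config.n_trials, config.spec, seed=root, distortion=config.distortion)
        sub_cfg = SyntheticSubjectConfig(
            subject_id=sid,
            f_c=config.f_c,
            q_start=config.q_start,
            q_end=config.q_end,
            q_jitter_sd=config.q_jitter_sd,
            noise_sd=config.noise_sd,
        )
        sessions[sid] = simulate_session(sub_cfg, stimuli, seed=root, spec=config.spec)
    return sessions


def write_session(
    directory: str | Path, sessions: dict[str, list[TrialRecord]], config: PipelineConfig
) -> Path:
    """Write all trials plus a manifest into a session directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    subjects: dict[str, list[str]] = {}
    for sid, trials in sessions.items():
        paths = []
        for tr in trials:
            rel = f"{sid}_trial{tr.trial_number:02d}.csv"
            write_trial(directory / rel, tr)
            paths.append(rel)
        subjects[sid] = paths
    manifest = SessionManifest(
        subjects=subjects,
        sample_rate=config.spec.sample_rate,
        stimulus_spec=config.spec,
        provenance={
            "seed": config.seed,
            "software": f"soundpursuit {__version__}",
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    (directory / "manifest.json").write_text(manifest.to_json())
    return directory


def read_session(directory: str | Path) -> tuple[dict[str, list[TrialRecord]], SessionManifest]:
    """Load a session directory written by `write_session`."""
    directory = Path(directory)
    manifest = SessionManifest.from_json((directory / "manifest.json").read_text())
    sessions: dict[str, list[TrialRecord]] = {}
    for sid, rels in manifest.subjects.items():
        trials = []
        for rel in rels:
            f = directory / rel
            if not f.exists():
                raise FileNotFoundError(f"manifest references missing trial file {f}")
            tr = read_trial(f)
            if tr.spec is None:
                tr.spec = manifest.stimulus_spec
            if abs(tr.stimulus.sample_rate - manifest.sample_rate) > 1e-6:
                raise ValueError(f"{f}: sample rate differs from the manifest")
            trials.append(tr)
        sessions[sid] = sorted(trials, key=lambda t: t.trial_number)
    return sessions, manifest


def run_pipeline(
    sessions: dict[str, list[TrialRecord]],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis over per-subject trial lists.

    Stages: per-subject delay estimation (or clamping at ground truth when
    ``config.estimate_delay`` is false and truth is available) -> per-trial
    model fits -> pursuit-error metrics and effort -> error-dissociation
    regressions -> hierarchical trends of f_C and Q -> effort trend.

    Returns a dict with the tidy per-trial ``results`` DataFrame, the
    regression table, the two `TrendFit` objects and the effort trend; when
    ``out_dir`` is given, writes ``results.csv``, ``trends.json`` and
    ``report.txt`` there.
    """
    if not sessions:
        raise ValueError("no subjects to analyse")
    spec = config.spec
    rows = []
    all_trials: list[TrialRecord] = []
    alignments = []
    for sid, trials in sessions.items():
        if config.estimate_delay:
            t_d = estimate_subject_delay(trials)
        else:
            if trials[0].ground_truth is None:
                raise ValueError("estimate_delay=False requires ground-truth delays")
            t_d = trials[0].ground_truth.t_d
        fits = fit_session(trials, t_d, spec=spec, grid_shape=config.fit_grid_shape)
        for tr, fit in zip(trials, fits):
            align = optimal_alignment(tr, search=config.alignment_search)
            effort = spectral_effort(fit.params, config.effort_band)
            rows.append(
                {
                    "subject": sid,
                    "trial": tr.trial_number,
                    "t_d_s": t_d,
                    "f_c_hz": fit.params.f_c,
                    "zeta": fit.params.zeta,
                    "q": fit.params.q,
                    "r": fit.r,
                    "r2": fit.r2,
                    "mse_deg2": fit.mse,
                    "t_opt_s": align.t_opt,
                    "mae_deg": align.mae,
                    "effort": effort,
                    "at_boundary": fit.at_boundary,
                    "q_true": tr.ground_truth.q if tr.ground_truth else np.nan,
                    "f_c_true": tr.ground_truth.f_c if tr.ground_truth else np.nan,
                }
            )
            all_trials.append(tr)
            alignments.append(align)
    results = pd.DataFrame(rows).sort_values(["subject", "trial"], kind="stable")
    results = results.reset_index(drop=True)

    regressions = error_regressions(
        all_trials, subsample_step=config.subsample_step, alignments=alignments
    )

    sids = sorted(sessions, key=lambda s: (len(s), s))
    n_trials = max(results["trial"])

    def _matrix(col: str) -> np.ndarray:
        mat = np.full((len(sids), n_trials), np.nan)
        for i, sid in enumerate(sids):
            sub = results[results["subject"] == sid]
            mat[i, sub["trial"].to_numpy() - 1] = sub[col].to_numpy()
        return mat

    trend_seed = config.seed + 1
    if len(sids) >= 2 and n_trials >= 3:
        fc_trend = hierarchical_trend(
            _matrix("f_c_hz"), "f_c_hz", n_samples=config.mcmc_samples, seed=trend_seed
        )
        q_trend = hierarchical_trend(
            _matrix("q"), "q", n_samples=config.mcmc_samples, seed=trend_seed + 1
        )
    else:
        fc_trend = q_trend = None
    efforts, effort_mean, effort_r = effort_trend(_matrix("effort"))

    report = _format_report(results, regressions, fc_trend, q_trend, effort_r)
    out = {
        "results": results,
        "regressions": regressions,
        "fc_trend": fc_trend,
        "q_trend": q_trend,
        "effort_mean": effort_mean,
        "effort_r": effort_r,
        "report": report,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        results.to_csv(out_dir / "results.csv", index=False, float_format=_FLOAT_FMT)
        trends_json = {
            "effort_trend_r": effort_r,
            "regressions": regressions.reset_index().to_dict(orient="records"),
        }
        for name, tf in (("f_c_hz", fc_trend), ("q", q_trend)):
            if tf is not None:
                trends_json[name] = {
                    "slope_mean": tf.slope_mean,
                    "slope_hdi": list(tf.slope_hdi),
                    "intercept_mean": tf.intercept_mean,
                    "intercept_hdi": list(tf.intercept_hdi),
                    "rhat_max": tf.rhat_max,
                    "converged": tf.converged,
                }
        (out_dir / "trends.json").write_text(json.dumps(trends_json, indent=1))
        (out_dir / "report.txt").write_text(report)
    return out


def _format_report(results, regressions, fc_trend, q_trend, effort_r) -> str:
    lines = [
        "soundpursuit analysis report",
        "============================",
        f"subjects: {results['subject'].nunique()}, trials: {len(results)}",
        f"median r2 of per-trial model fits: {results['r2'].median():.3f}",
        f"mean MAE: {results['mae_deg'].mean():.2f} deg "
        f"(SD {results['mae_deg'].std(ddof=1):.2f})",
        f"mean optimal alignment delay: {1e3 * results['t_opt_s'].mean():.0f} ms",
        "",
        "hierarchical trends (per-trial slope, 95% HDI):",
    ]
    for tf in (fc_trend, q_trend):
        if tf is None:
            continue
        lo, hi = tf.slope_hdi
        verdict = "excludes 0" if tf.slope_excludes_zero() else "covers 0"
        flag = "" if tf.converged else "  [NOT CONVERGED]"
        lines.append(
            f"  {tf.parameter}: {tf.slope_mean:+.4f} [{lo:+.4f}, {hi:+.4f}] ({verdict}){flag}"
        )
    lines += [
        f"effort-vs-trial correlation of the group mean: r = {effort_r:.3f}",
        "",
        "error-dissociation regressions (offset, slope, correlation):",
    ]
    for name, row in regressions.iterrows():
        lines.append(
            f"  {name}: {row['offset']:+.3f}, {row['slope']:+.3f}, r = {row['correlation']:+.3f}"
        )
    return "\n".join(lines) + "\n"
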